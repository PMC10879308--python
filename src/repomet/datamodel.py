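"""Core domain types, labeled-matrix I/O, configuration and logging.

The pipeline moves three kinds of matrices around: square entity-entity
similarity matrices (drug-drug and disease-disease, values in [0, 1]),
a binary drug x disease association matrix, and its real-valued
"completed" counterpart produced by the graph-convolutional pre-training
step.  All of them are stored on disk as labeled TSV: one header row of
column identifiers and a first column of row identifiers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SYMMETRY_TOL = 1e-8

logger = logging.getLogger("repomet")


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a labeled matrix."""


class ConfigError(ValueError):
    """A configuration value is missing or out of range."""


class NumericalError(RuntimeError):
    """Training diverged or produced non-finite values."""


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to stderr (stage, epoch, loss lines)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class SimilarityMatrix:
    """Symmetric entity-entity similarity with values in [0, 1].

    ``ids`` keeps the entity order of the source file; ``values`` is the
    square similarity matrix aligned with it.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got shape {v.shape}")
        if len(self.ids) != v.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} ids but matrix of order {v.shape[0]}"
            )
        _check_unique(self.ids, "entity")
        if not np.all(np.isfinite(v)):
            raise ValidationError("similarity matrix contains non-finite values")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"similarity matrix asymmetric (max |S - S^T| = {asym:.3g})")
        if v.size and (v.min() < 0 or v.max() > 1 + 1e-12):
            raise ValidationError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationMatrix:
    """Drug x disease association matrix.

    Raw associations are strictly binary; after matrix completion the
    ``completed`` flag relaxes validation to non-negative reals (known
    positives stay pinned at 1, screened predictions keep their score).
    """

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray
    completed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValidationError("association matrix must be 2-D")
        if v.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValidationError(
                f"matrix shape {v.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")
        if not np.all(np.isfinite(v)):
            raise ValidationError("association matrix contains non-finite values")
        if self.completed:
            if v.size and v.min() < 0:
                raise ValidationError("completed association values must be non-negative")
        else:
            if v.size and not np.all((v == 0) | (v == 1)):
                bad = np.argwhere((v != 0) & (v != 1))[0]
                raise ValidationError(
                    f"raw association matrix must be binary; "
                    f"value {v[tuple(bad)]} at row {self.drug_ids[bad[0]]}, "
                    f"column {self.disease_ids[bad[1]]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def positive_pairs(self) -> np.ndarray:
        """Indices (i, j) of entries strictly greater than zero."""
        return np.argwhere(self.values > 0)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CompletionConfig:
    """Hyperparameters of the GCN encoder + bilinear decoder pre-training."""

    k: int = 64                 # GCN embedding dimension
    L: int = 3                  # number of graph-convolution layers
    lr1: float = 0.008          # Adam learning rate
    node_dropout: float = 0.6   # discard rate on node feature rows
    reg_dropout: float = 0.4    # discard rate on layer activations
    mu: float = 6.0             # similarity penalty factor
    theta: float = 0.8          # screening threshold on predicted scores
    epochs: int = 600           # upper bound; training stops at convergence
    tol: float = 1e-5           # relative loss-improvement convergence threshold
    score_window: int = 50      # trailing epochs averaged into the final scores
    seed: int = 0
    train_attention: bool = True   # learn the per-layer attention weights
    include_input_layer: bool = True  # include the projected input in the attention sum


@dataclass
class MetricConfig:
    """Hyperparameters of symmetric metric learning with adaptive margins."""

    n: int = 250                # latent dimension of the joint metric space
    lr2: float = 0.05           # AdaGrad learning rate
    batch_size: int = 512       # positives per update, per centric
    gamma: float = 1.0          # weight of the adaptive-margin term
    clip_bound_l: float = 1.0   # radius of the Euclidean ball / margin cap
    P: int | None = None        # negatives per positive; None -> min(M, N)
    epochs: int = 150
    seed: int = 0
    init_spread_is_variance: bool = True  # 0.03 read as variance (std ~ 0.173)
    val_fraction: float = 0.05
    patience: int = 15


@dataclass
class ColdStartConfig:
    h: int = 5                  # nearest neighbours used to embed a new entity
    weighted: bool = True       # similarity-weighted mean (vs unweighted)


@dataclass
class EvaluationConfig:
    folds: int = 10
    repeats: int = 10
    k_list: list[int] = field(default_factory=lambda: [5, 10, 20, 50])
    min_positive_degree: int = 1   # degree filter before leave-one-entity-out
    seed: int = 0


@dataclass
class RunConfig:
    completion: CompletionConfig = field(default_factory=CompletionConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    coldstart: ColdStartConfig = field(default_factory=ColdStartConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def validate(self) -> "RunConfig":
        c, m = self.completion, self.metric
        checks: list[tuple[bool, str]] = [
            (c.k >= 1, "completion.k"),
            (c.L >= 1, "completion.L"),
            (c.lr1 > 0, "completion.lr1"),
            (0 <= c.node_dropout < 1, "completion.node_dropout"),
            (0 <= c.reg_dropout < 1, "completion.reg_dropout"),
            (c.mu > 0, "completion.mu"),
            (0 <= c.theta <= 1, "completion.theta"),
            (c.epochs >= 0, "completion.epochs"),
            (m.n >= 1, "metric.n"),
            (m.lr2 > 0, "metric.lr2"),
            (m.batch_size >= 1, "metric.batch_size"),
            (m.gamma >= 0, "metric.gamma"),
            (m.clip_bound_l > 0, "metric.clip_bound_l"),
            (m.P is None or m.P >= 1, "metric.P"),
            (m.epochs >= 0, "metric.epochs"),
            (0 <= m.val_fraction < 1, "metric.val_fraction"),
            (self.coldstart.h >= 1, "coldstart.h"),
            (self.evaluation.folds >= 2, "evaluation.folds"),
            (self.evaluation.repeats >= 1, "evaluation.repeats"),
            (all(k >= 1 for k in self.evaluation.k_list), "evaluation.k_list"),
        ]
        for ok, key in checks:
            if not ok:
                raise ConfigError(f"configuration value out of range: {key}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "completion": CompletionConfig,
    "metric": MetricConfig,
    "coldstart": ColdStartConfig,
    "evaluation": EvaluationConfig,
}


def load_config(path: str | os.PathLike | None = None) -> RunConfig:
    """Load a YAML config, filling missing keys with the published defaults.

    An empty (or absent) file yields the default configuration.  Unknown
    keys and out-of-range values raise :class:`ConfigError` naming the key.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping of sections")
            raw = loaded
    kwargs = {}
    for section, cls in _SECTIONS.items():
        sub = raw.pop(section, {}) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - known
        if unknown:
            raise ConfigError(f"unknown key {section}.{sorted(unknown)[0]}")
        kwargs[section] = cls(**sub)
    if raw:
        raise ConfigError(f"unknown config section {sorted(raw)[0]!r}")
    return RunConfig(**kwargs).validate()


# ---------------------------------------------------------------------------
# Labeled matrix I/O
# ---------------------------------------------------------------------------

def read_labeled_matrix(
    path: str | os.PathLike,
    kind: str,
    *,
    delimiter: str = "\t",
    completed: bool = False,
) -> SimilarityMatrix | AssociationMatrix:
    """Read a labeled TSV matrix and validate it as the requested type.

    Parameters
    ----------
    path
        File with one header row of column IDs and a first column of row IDs.
    kind
        ``"similarity"`` or ``"association"``.
    delimiter
        Field separator; pass ``","`` for CSV input.
    completed
        For associations, accept non-negative reals instead of strict {0, 1}.
    """
    if kind not in ("similarity", "association"):
        raise ValueError(f"kind must be 'similarity' or 'association', got {kind!r}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read labeled matrix from {path}: {exc}") from exc
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().values & ~df.isna().values)
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    if body.isna().values.any():
        i, j = np.argwhere(body.isna().values)[0]
        raise ParseError(f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}")
    values = body.values.astype(float)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if kind == "similarity":
        if row_ids != col_ids:
            raise ValidationError("similarity matrix row and column identifiers differ")
        return SimilarityMatrix(ids=row_ids, values=values)
    return AssociationMatrix(
        drug_ids=row_ids, disease_ids=col_ids, values=values, completed=completed
    )


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temporary file and rename, so outputs are never partial."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_labeled_matrix(
    path: str | os.PathLike,
    matrix: SimilarityMatrix | AssociationMatrix,
    *,
    delimiter: str = "\t",
) -> None:
    """Write a labeled matrix as TSV (header row of column IDs, row-ID column)."""
    if isinstance(matrix, SimilarityMatrix):
        df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    else:
        df = pd.DataFrame(matrix.values, index=matrix.drug_ids, columns=matrix.disease_ids)
    _atomic_write_text(path, df.to_csv(sep=delimiter, lineterminator="\n", float_format="%.17g"))


@dataclass
class RankedPrediction:
    drug_id: str
    disease_id: str
    distance: float
    rank: int


def write_ranked_predictions(
    path: str | os.PathLike, rankings: Iterable[RankedPrediction]
) -> None:
    """Write ranked predictions as TSV sorted by (drug_id, rank).

    Distances must be non-negative and ranks start at 1 within each drug.
    Ties in distance are expected to have been broken upstream by
    disease_id, so the written order is deterministic.
    """
    records = list(rankings)
    for r in records:
        if r.distance < 0:
            raise ValidationError(
                f"negative distance {r.distance} for pair ({r.drug_id}, {r.disease_id})"
            )
        if r.rank < 1:
            raise ValidationError(f"rank must start at 1, got {r.rank}")
    records.sort(key=lambda r: (r.drug_id, r.rank))
    lines = ["drug_id\tdisease_id\tdistance\trank"]
    for r in records:
        lines.append(f"{r.drug_id}\t{r.disease_id}\t{r.distance:.17g}\t{r.rank}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def warn(message: str) -> None:
    """Emit a runtime warning through both warnings and the package logger."""
    warnings.warn(message, stacklevel=2)
    logger.warning(message)
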