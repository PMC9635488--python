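"""Representational dissimilarity matrices and their second-order comparison.

An RDM holds the pairwise correlation distance (1 - Pearson's r) between
stimulus feature vectors.  RDMs are compared by rank-based (Spearman)
correlation of their strictly-upper triangles, plain or partial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateDataError

log = logging.getLogger(__name__)

_ATOL = 1e-8


@dataclass(frozen=True)
class RDM:
    """Symmetric stimuli x stimuli dissimilarity matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.array(values, dtype=float)
        labels = tuple(labels)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"RDM shape {values.shape} != ({n}, {n})")
        if not np.isfinite(values).all():
            raise ValueError("RDM entries must be finite")
        if not np.allclose(values, values.T, atol=_ATOL):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=_ATOL):
            raise ValueError("RDM diagonal must be zero")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper(self) -> np.ndarray:
        """Strictly-upper-triangle vector (diagonal excluded), row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class RdmComparison:
    rho: float
    n_pairs: int
    method: str
    control: str | None = None


@dataclass(frozen=True)
class RdmCorrelationTable:
    labels: tuple[str, ...]
    values: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def zscore_features(features: np.ndarray) -> np.ndarray:
    """Column-standardize a feature matrix; constant columns are dropped.

    Uses the population (ddof=0) standard deviation.  Dropping constant
    columns is logged; they carry no pairwise information and would produce
    NaNs.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 stimuli")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d zero-variance feature column(s)",
                    int((~keep).sum()))
    return (X[:, keep] - mu[keep]) / sd[keep]


def compute_rdm(features: np.ndarray, labels: Sequence[str]) -> RDM:
    """Correlation-distance RDM: entry (i, j) = 1 - Pearson r of rows i, j."""
    X = np.asarray(features, dtype=float)
    labels = tuple(labels)
    if X.shape[0] != len(labels):
        raise ValueError("row count does not match labels")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 stimuli and 2 features")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise DegenerateDataError(
            f"stimulus {bad!r} has zero feature variance; "
            f"correlation distance undefined"
        )
    C = np.corrcoef(X)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return RDM(labels, np.clip(D, 0.0, 2.0))


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Elementwise mean of RDMs sharing labels and order."""
    if not rdms:
        raise ValueError("need at least one RDM")
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise ValueError("RDM labels/order differ; cannot average")
    mean = np.mean([r.values for r in rdms], axis=0)
    return RDM(labels, mean)


def _check_labels(a: RDM, b: RDM) -> None:
    if a.labels != b.labels:
        raise ValueError("RDM labels do not match")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateDataError("constant vector in correlation")
    return float(np.dot(x, y) / (nx * ny))


def rdm_spearman(a: RDM, b: RDM) -> RdmComparison:
    """Spearman rank correlation of two RDMs' upper triangles (average ranks)."""
    _check_labels(a, b)
    ra = rankdata(a.upper())
    rb = rankdata(b.upper())
    rho = _pearson(ra, rb)
    return RdmComparison(rho=rho, n_pairs=len(ra), method="spearman")


def rdm_partial_spearman(target: RDM, model: RDM, control: RDM,
                         control_label: str = "control") -> RdmComparison:
    """Rank-based partial correlation of target with model, controlling control.

    All three upper triangles are rank-transformed, then
    (r_tm - r_tc * r_mc) / sqrt((1 - r_tc^2)(1 - r_mc^2)).

    If the control exhausts the target's rank variance (|r_tc| = 1, e.g.
    target and control are rank-identical), no variance is left to explain
    and the partial correlation is 0 by convention.
    """
    _check_labels(target, model)
    _check_labels(target, control)
    rt = rankdata(target.upper())
    rm = rankdata(model.upper())
    rc = rankdata(control.upper())
    r_tm = _pearson(rt, rm)
    r_tc = _pearson(rt, rc)
    r_mc = _pearson(rm, rc)
    if abs(r_mc) >= 1.0 - 1e-12:
        raise DegenerateDataError(
            "model and control RDMs are rank-identical; partial correlation "
            "undefined"
        )
    if abs(r_tc) >= 1.0 - 1e-12:
        rho = 0.0
    else:
        rho = (r_tm - r_tc * r_mc) / np.sqrt((1 - r_tc**2) * (1 - r_mc**2))
    return RdmComparison(rho=float(rho), n_pairs=len(rt),
                         method="partial_spearman", control=control_label)


def build_correlation_table(rdms: Mapping[str, RDM],
                            method: str = "pearson") -> RdmCorrelationTable:
    """Pairwise correlation matrix over named RDMs' upper triangles.

    ``method`` is 'pearson' (default) or 'spearman'.
    """
    if len(rdms) < 2:
        raise ValueError("need at least two RDMs")
    names = list(rdms)
    vecs = []
    for name in names:
        v = rdms[name].upper()
        vecs.append(rankdata(v) if method == "spearman" else v)
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    k = len(names)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = _pearson(vecs[i], vecs[j])
    return RdmCorrelationTable(tuple(names), out, method)


def write_rdm_tsv(rdm: RDM, path) -> None:
    rdm.to_frame().to_csv(path, sep="\t", index_label="stimulus")


def read_rdm_tsv(path) -> RDM:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: RDM row/column labels differ")
    return RDM([str(c) for c in frame.columns], frame.to_numpy(dtype=float))
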