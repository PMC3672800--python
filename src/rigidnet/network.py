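"""Directed lag-1 network learning with FDR control, and strength estimation.

The structure stage is a PC-style constraint-based learner over the lagged
edge universe {i(t-1) -> j(t) : i != j}.  For growing conditioning-set sizes
it tests each surviving edge with a Fisher-z partial-correlation test against
subsets of the target's other surviving candidate parents, tracks each edge's
running *maximum* p-value, and after each sweep applies the
Benjamini–Hochberg procedure at level ``q`` to the running maxima, dropping
edges no longer rejected as independent.  Edges surviving every sweep form
the network; the contract is control of the false discovery rate of the
reported edge set at ``q``.

The strength stage is linear-Gaussian dynamic-Bayesian-network estimation:
for each target ROI, an ordinary least-squares regression of x_j(t) on its
learned parents {x_i(t-1)} gives one per-subject coefficient per edge.

Direction comes from temporal precedence only: with R ROIs the universe has
R*(R-1) directed connections (2,652 for the 52-ROI atlas used in the
motivating study).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rigidnet.preprocess import ROITimeSeries


class InsufficientDataError(ValueError):
    """Not enough samples for the requested test or regression."""


def edge_universe_size(n_rois: int) -> int:
    """Number of possible directed connections among ``n_rois`` regions."""
    return n_rois * (n_rois - 1)


@dataclass(frozen=True)
class Edge:
    """A directed lagged connection: ``source`` at t-1 influences ``target`` at t."""

    source: str
    target: str
    p_max: float

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class DirectedNetwork:
    """FDR-significant directed lagged edges among named ROIs."""

    roi_names: tuple[str, ...]
    edges: tuple[Edge, ...]
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        object.__setattr__(self, "edges", tuple(self.edges))
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-loop {e.label} not allowed in the edge set")
        if len(self.edges) > edge_universe_size(len(self.roi_names)):
            raise ValueError("more edges than the directed universe allows")

    @property
    def edge_labels(self) -> list[str]:
        return [e.label for e in self.edges]

    def parents_of(self, target: str) -> list[str]:
        return [e.source for e in self.edges if e.target == target]

    def to_json(self) -> str:
        return json.dumps(
            {
                "fdr_level": self.fdr_level,
                "roi_names": list(self.roi_names),
                "edges": [
                    {"source": e.source, "target": e.target, "p_max": e.p_max}
                    for e in self.edges
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DirectedNetwork":
        obj = json.loads(text)
        return cls(
            roi_names=tuple(obj["roi_names"]),
            edges=tuple(
                Edge(e["source"], e["target"], e["p_max"]) for e in obj["edges"]
            ),
            fdr_level=obj["fdr_level"],
        )


@dataclass(frozen=True)
class StrengthVector:
    """Per-subject connection strengths aligned to a network's edge list."""

    subject_id: str
    values: np.ndarray
    edge_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "edge_labels", tuple(self.edge_labels))
        if len(values) != len(self.edge_labels):
            raise ValueError("strength vector must align with the edge list")
        if not np.isfinite(values).all():
            raise ValueError("non-finite strength values")


def _as_matrix(series: ROITimeSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, ROITimeSeries):
        return series.data
    return np.asarray(series, dtype=float)


def lagged_design(
    series: ROITimeSeries | np.ndarray | Sequence[ROITimeSeries | np.ndarray],
    lag: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (past, present) sample pairs, never crossing a run boundary.

    Accepts one T x R matrix or a sequence of them (multiple runs/subjects);
    each run of length T contributes T - lag rows.
    """
    if isinstance(series, (ROITimeSeries, np.ndarray)):
        runs = [series]
    else:
        runs = list(series)
    past_blocks, present_blocks = [], []
    for run in runs:
        X = _as_matrix(run)
        if X.shape[0] < lag + 2:
            raise InsufficientDataError(
                f"run of length {X.shape[0]} too short for lag {lag}"
            )
        past_blocks.append(X[:-lag])
        present_blocks.append(X[lag:])
    return np.vstack(past_blocks), np.vstack(present_blocks)


def ci_test(
    past_i: np.ndarray,
    present_j: np.ndarray,
    conditioning: np.ndarray | None = None,
) -> float:
    """Fisher-z test of the partial correlation of x_i(t-1) and x_j(t) given
    a set of past variables; returns a two-sided p-value.

    A singular conditioning covariance yields p = 1 with a warning
    (conservative: the edge cannot be declared present on degenerate data).
    """
    past_i = np.asarray(past_i, dtype=float).ravel()
    present_j = np.asarray(present_j, dtype=float).ravel()
    n = len(past_i)
    S = (
        np.empty((n, 0))
        if conditioning is None
        else np.asarray(conditioning, dtype=float).reshape(n, -1)
    )
    k = S.shape[1]
    if n <= k + 3:
        raise InsufficientDataError(f"need more than |S|+3={k + 3} samples, got {n}")
    Z = np.column_stack([past_i, present_j, S])
    corr = np.corrcoef(Z, rowvar=False)
    return _fisher_z_p(corr, 0, 1, list(range(2, 2 + k)), n)


def _fisher_z_p(corr: np.ndarray, i: int, j: int, cond: list[int], n: int) -> float:
    """Partial-correlation p-value from a correlation matrix via the precision
    of the relevant submatrix."""
    idx = [i, j] + cond
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        warnings.warn("singular conditioning covariance; returning p = 1")
        return 1.0
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        warnings.warn("degenerate precision matrix; returning p = 1")
        return 1.0
    r = -prec[0, 1] / np.sqrt(denom)
    r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    dof = n - len(cond) - 3
    if dof <= 0:
        raise InsufficientDataError("not enough samples for the Fisher-z test")
    z = np.arctanh(r) * np.sqrt(dof)
    return float(2.0 * stats.norm.sf(abs(z)))


def _bh_keep(p_max: dict[tuple[int, int], float], q: float) -> set[tuple[int, int]]:
    """Edges whose running-max p is rejected-as-independent by BH at level q."""
    if not p_max:
        return set()
    items = sorted(p_max.items())  # lexicographic (source, target): deterministic ties
    pvals = np.array([p for _, p in items])
    keep, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return {e for (e, _), k in zip(items, keep) if k}


def pcfdr_learn(
    series: Sequence[ROITimeSeries | np.ndarray] | ROITimeSeries | np.ndarray,
    q: float = 0.05,
    max_cond_size: int = 3,
    roi_names: Sequence[str] | None = None,
    standardize_runs: bool = True,
) -> DirectedNetwork:
    """Learn the FDR-controlled directed lag-1 network from pooled series.

    Per-run series are standardized (columns to mean 0, sd 1) and pooled as
    lagged sample pairs with run-boundary exclusion.  Edges are eliminated in
    PC fashion with the running-max p-value rule and an embedded
    Benjamini–Hochberg screen after each conditioning-set-size sweep.
    """
    if isinstance(series, (ROITimeSeries, np.ndarray)):
        runs = [series]
    else:
        runs = list(series)
    if roi_names is None:
        first = runs[0]
        roi_names = (
            first.roi_names
            if isinstance(first, ROITimeSeries)
            else tuple(f"roi{j:03d}" for j in range(_as_matrix(first).shape[1]))
        )
    roi_names = tuple(roi_names)
    R = len(roi_names)
    for run in runs:
        if _as_matrix(run).shape[1] != R:
            raise ValueError("all runs must share the ROI set")
    if R <= 1:
        return DirectedNetwork(roi_names=roi_names, edges=(), fdr_level=q)

    mats = []
    for run in runs:
        X = _as_matrix(run)
        if standardize_runs:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        mats.append(X)
    past, present = lagged_design(mats)
    n = past.shape[0]
    if n <= max_cond_size + 4:
        raise InsufficientDataError(
            f"{n} pooled samples cannot support conditioning sets of size "
            f"{max_cond_size}; reduce max_cond_size or provide more data"
        )
    corr = np.corrcoef(np.column_stack([past, present]), rowvar=False)
    # variable index: past i -> i, present j -> R + j

    surviving: set[tuple[int, int]] = {
        (i, j) for i in range(R) for j in range(R) if i != j
    }
    p_max: dict[tuple[int, int], float] = {e: 0.0 for e in surviving}

    for size in range(max_cond_size + 1):
        parents: dict[int, list[int]] = {j: [] for j in range(R)}
        for (i, j) in surviving:
            parents[j].append(i)
        for j in parents:
            parents[j].sort()
        tested_any = False
        for (i, j) in sorted(surviving):
            others = [k for k in parents[j] if k != i]
            if len(others) < size:
                continue
            for S in combinations(others, size):
                tested_any = True
                p = _fisher_z_p(corr, i, R + j, list(S), n)
                if p > p_max[(i, j)]:
                    p_max[(i, j)] = p
                # BH critical values never exceed q: this edge is already lost
                if p_max[(i, j)] > q:
                    break
        surviving = _bh_keep({e: p_max[e] for e in surviving}, q)
        if not tested_any:
            break

    edges = tuple(
        Edge(roi_names[i], roi_names[j], p_max[(i, j)]) for (i, j) in sorted(surviving)
    )
    return DirectedNetwork(roi_names=roi_names, edges=edges, fdr_level=q)


def dbn_strengths(
    series: ROITimeSeries | np.ndarray,
    network: DirectedNetwork,
    subject_id: str | None = None,
) -> StrengthVector:
    """Per-subject linear-Gaussian DBN strengths for the group edge list.

    For each target ROI, regresses x_j(t) on its network parents
    {x_i(t-1)} (with intercept) by ordinary least squares; the coefficients
    are the subject's strengths for the edges into j.
    """
    X = _as_matrix(series)
    if isinstance(series, ROITimeSeries):
        name_to_col = {nm: c for c, nm in enumerate(series.roi_names)}
        missing = [nm for nm in network.roi_names if nm not in name_to_col]
        if missing:
            raise ValueError(f"series lacks network ROIs: {missing}")
        if subject_id is None:
            subject_id = series.subject_id
    else:
        if X.shape[1] < len(network.roi_names):
            raise ValueError("series has fewer columns than network ROIs")
        name_to_col = {nm: c for c, nm in enumerate(network.roi_names)}
    past, present = lagged_design(X)
    n = past.shape[0]
    values: dict[str, float] = {}
    for target in network.roi_names:
        parent_names = network.parents_of(target)
        if not parent_names:
            continue
        if len(parent_names) + 1 > n:
            raise InsufficientDataError(
                f"target {target}: {len(parent_names)} parents exceed {n} samples"
            )
        cols = [name_to_col[p] for p in parent_names]
        design = np.column_stack([np.ones(n), past[:, cols]])
        coef, *_ = np.linalg.lstsq(design, present[:, name_to_col[target]], rcond=None)
        for pname, b in zip(parent_names, coef[1:]):
            values[f"{pname}->{target}"] = float(b)
    labels = tuple(e.label for e in network.edges)
    return StrengthVector(
        subject_id=subject_id or "unknown",
        values=np.array([values[lab] for lab in labels]),
        edge_labels=labels,
    )
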