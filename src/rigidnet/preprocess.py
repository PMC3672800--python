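"""ROI time-series preprocessing: detrend, average, drift removal, scaling.

Raw region-of-interest (ROI) series — or voxel-level matrices with an ROI
assignment — are reduced to the detrended, standardized T x R matrices
consumed by network inference.  Drift removal projects out a discrete-cosine
basis up to a cutoff period (128 s by default), the convention used by
standard fMRI drift-removal implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

DEFAULT_TR = 1.985  # seconds per volume
DEFAULT_CUTOFF = 128.0  # seconds; slower fluctuations are treated as drift


@dataclass(frozen=True)
class ROITimeSeries:
    """A T x R matrix of ROI time courses sampled every ``tr`` seconds."""

    data: np.ndarray
    tr: float = DEFAULT_TR
    roi_names: tuple[str, ...] = ()
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a T x R matrix")
        object.__setattr__(self, "data", data)
        names = tuple(self.roi_names) if self.roi_names else tuple(
            f"roi{j:03d}" for j in range(data.shape[1])
        )
        object.__setattr__(self, "roi_names", names)
        if len(names) != data.shape[1]:
            raise ValueError("roi_names length must match number of columns")
        if len(set(names)) != len(names):
            raise ValueError("roi_names must be unique")
        if not np.isfinite(data).all():
            raise ValueError("missing or non-finite values in ROI data")
        if data.shape[0] < 30:
            raise ValueError(f"need at least 30 timepoints, got {data.shape[0]}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def roi_average(
    voxel_matrix: np.ndarray,
    roi_assignment: Sequence[str],
    tr: float = DEFAULT_TR,
    subject_id: str | None = None,
    group: str | None = None,
) -> ROITimeSeries:
    """Linear-detrend each voxel, then average voxels within each ROI.

    ROI order follows first appearance in ``roi_assignment``.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    labels = list(roi_assignment)
    if voxel_matrix.ndim != 2 or voxel_matrix.shape[1] != len(labels):
        raise ValueError("roi_assignment must label every voxel column")
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    detrended = signal.detrend(voxel_matrix, axis=0, type="linear")
    cols = []
    for lab in order:
        idx = [v for v, l in enumerate(labels) if l == lab]
        if not idx:
            raise ValueError(f"ROI {lab!r} has no voxels")
        cols.append(detrended[:, idx].mean(axis=1))
    return ROITimeSeries(
        data=np.column_stack(cols),
        tr=tr,
        roi_names=tuple(order),
        subject_id=subject_id,
        group=group,
    )


def dct_basis(n_timepoints: int, tr: float, cutoff_period: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Discrete-cosine drift basis: K = floor(2*T*tr/cutoff) + 1 regressors.

    Column k is cos(pi * k * (2t+1) / (2T)); k = 0 is the constant.  Column
    k has period 2*T*tr/k, so the basis spans all fluctuations slower than
    the cutoff period.
    """
    T = n_timepoints
    K = int(math.floor(2.0 * T * tr / cutoff_period)) + 1
    t = np.arange(T)
    return np.column_stack(
        [np.cos(math.pi * k * (2 * t + 1) / (2.0 * T)) for k in range(K)]
    )


def dct_highpass(series: ROITimeSeries, cutoff_period: float = DEFAULT_CUTOFF) -> ROITimeSeries:
    """Remove low-frequency drift by projecting out the DCT basis.

    The output is the residual of the least-squares projection of each
    column onto the span of the drift regressors (constant included); the
    operation is a linear projection and hence idempotent.
    """
    T, tr = series.n_timepoints, series.tr
    if T * tr <= cutoff_period:
        raise ValueError(
            f"series duration {T * tr:.1f}s must exceed the cutoff period "
            f"{cutoff_period:.1f}s"
        )
    basis = dct_basis(T, tr, cutoff_period)
    coefs, *_ = np.linalg.lstsq(basis, series.data, rcond=None)
    return replace(series, data=series.data - basis @ coefs)


def standardize(series: ROITimeSeries, ddof: int = 1) -> ROITimeSeries:
    """Scale each ROI column to mean 0, sd 1."""
    data = series.data
    sd = data.std(axis=0, ddof=ddof)
    zero = np.nonzero(sd == 0)[0]
    if len(zero):
        names = ", ".join(series.roi_names[j] for j in zero)
        raise ValueError(f"constant ROI column(s): {names}")
    return replace(series, data=(data - data.mean(axis=0)) / sd)
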