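"""Temporal preprocessing: volume discard, band-pass filter, nuisance regression.

Stage order is fixed: discard -> filter -> regress. Nuisance regressors
(the global mean series and the motion parameters) are band-pass filtered
with the same filter before regression so their frequency content matches
the data; otherwise regression would re-introduce out-of-band variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .timeseries import RegionalTimeSeries

__all__ = [
    "NuisanceDesign",
    "discard_initial_volumes",
    "bandpass",
    "bandpass_array",
    "compute_global_mean",
    "regress_nuisance",
    "run_preprocessing",
]

DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.08
DEFAULT_ORDER = 4
DEFAULT_RIPPLE_DB = 0.5


@dataclass
class NuisanceDesign:
    """Volumes x q nuisance regressor matrix (intercept added at fit time)."""

    regressors: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a volumes x q matrix")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("regressors contain non-finite values")
        if not self.names:
            self.names = tuple(
                f"reg{k + 1}" for k in range(self.regressors.shape[1])
            )
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("name count does not match regressor columns")

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]


def discard_initial_volumes(ts: RegionalTimeSeries, k: int) -> RegionalTimeSeries:
    """Drop the first ``k`` volumes (magnetic-saturation discard)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {k} of {ts.n_volumes} volumes: series unusable"
        )
    return ts.with_data(ts.data[:, k:])


def _design_filter(
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    order: int,
    ripple_db: float,
) -> tuple[np.ndarray, np.ndarray]:
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, {nyquist}) Hz"
        )
    return signal.cheby1(
        order, ripple_db, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds
    )


def bandpass_array(
    data: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
) -> np.ndarray:
    """Zero-phase Chebyshev type-I band-pass along the last axis."""
    b, a = _design_filter(tr_seconds, low_hz, high_hz, order, ripple_db)
    return signal.filtfilt(b, a, np.asarray(data, dtype=float), axis=-1)


def bandpass(
    ts: RegionalTimeSeries,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
) -> RegionalTimeSeries:
    """Band-pass every region's series identically, forward-backward.

    The forward-backward application makes the net filter zero-phase;
    output length equals input length.
    """
    return ts.with_data(
        bandpass_array(ts.data, ts.tr_seconds, low_hz, high_hz, order, ripple_db)
    )


def compute_global_mean(ts: RegionalTimeSeries) -> np.ndarray:
    """Per-volume mean over all regions (the global mean signal)."""
    return ts.data.mean(axis=0)


def regress_nuisance(
    ts: RegionalTimeSeries, design: NuisanceDesign
) -> RegionalTimeSeries:
    """OLS residuals of each region's series on the nuisance design.

    An intercept is always included. Residuals are orthogonal to every
    design column. A rank-deficient design raises, naming the collinear
    columns.
    """
    if design.n_volumes != ts.n_volumes:
        raise ValueError(
            f"design has {design.n_volumes} rows but series has "
            f"{ts.n_volumes} volumes"
        )
    x = np.column_stack([np.ones(ts.n_volumes), design.regressors])
    names = ("intercept",) + design.names
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # locate columns that add no rank beyond their predecessors
        bad = []
        for c in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : c + 1]) == np.linalg.matrix_rank(x[:, :c]):
                bad.append(names[c])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, ts.data.T, rcond=None)
    resid = ts.data.T - x @ beta
    return ts.with_data(resid.T)


def run_preprocessing(
    ts: RegionalTimeSeries,
    motion: np.ndarray | None = None,
    discard: int = 0,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    ripple_db: float = DEFAULT_RIPPLE_DB,
    regress_global: bool = True,
) -> RegionalTimeSeries:
    """Full temporal pipeline: discard -> band-pass -> nuisance regression.

    ``motion`` is a volumes x q table aligned with the *raw* series; its
    first ``discard`` rows are dropped alongside, and it is band-pass
    filtered with the same filter before regression. The global mean is
    computed from the filtered data.
    """
    out = discard_initial_volumes(ts, discard) if discard else ts
    out = bandpass(out, low_hz, high_hz, order, ripple_db)

    columns: list[np.ndarray] = []
    names: list[str] = []
    if regress_global:
        columns.append(compute_global_mean(out))
        names.append("global_mean")
    if motion is not None and motion.size:
        m = np.asarray(motion, dtype=float)[discard:, :]
        if m.shape[0] != out.n_volumes:
            raise ValueError("motion table does not align with the series")
        m = bandpass_array(m.T, ts.tr_seconds, low_hz, high_hz, order, ripple_db).T
        columns.append(m)
        names.extend(f"motion{k + 1}" for k in range(m.shape[1]))
    if not columns:
        return out
    design = NuisanceDesign(
        regressors=np.column_stack(columns), names=tuple(names)
    )
    return regress_nuisance(out, design)
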