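"""Core container for regional BOLD time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = ["RegionalTimeSeries", "default_region_labels"]


def default_region_labels(n_regions: int) -> tuple[str, ...]:
    """Region names for an ``n_regions`` parcellation.

    For 116 regions the packaged anatomical template labels are used;
    otherwise generic ``R001 .. Rnnn`` names are generated.
    """
    if n_regions == 116:
        text = (
            resources.files("connsig.data").joinpath("aal116_labels.txt").read_text()
        )
        labels = tuple(line.strip() for line in text.splitlines() if line.strip())
        assert len(labels) == 116
        return labels
    return tuple(f"R{i + 1:03d}" for i in range(n_regions))


@dataclass
class RegionalTimeSeries:
    """One subject's regions x volumes matrix with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_volumes)
        Regional mean time series, one row per region.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    region_labels : tuple of str
        Ordered region names; must match the row count of ``data``.
    subject_id : str
        Subject identifier used in file names and reports.
    """

    data: np.ndarray
    tr_seconds: float
    region_labels: tuple[str, ...] = field(default=())
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D regions x volumes matrix")
        if self.data.shape[1] < 2:
            raise ValueError("time series needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_labels:
            self.region_labels = default_region_labels(self.data.shape[0])
        self.region_labels = tuple(self.region_labels)
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} region labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("duplicate region labels")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RegionalTimeSeries":
        """Copy of this series with ``data`` replaced (metadata preserved)."""
        return replace(self, data=data)
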