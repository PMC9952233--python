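"""Histogram threshold selection for bone / metal segmentation.

Bone is segmented from CT by minimum-error thresholding
(Kittler–Illingworth): the histogram is modelled as a two-Gaussian
mixture and the threshold minimises the average classification-error
criterion.  Metal prostheses saturate CT intensities, so they are
isolated separately with a narrow high-intensity band, for which the
quantile helper provides a default lower edge.

Surface extraction from a thresholded volume is ordinary marching cubes
(``skimage.measure.marching_cubes``); only threshold *selection* is
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityHistogram",
    "kittler_illingworth_threshold",
    "high_intensity_threshold",
]


@dataclass
class IntensityHistogram:
    """Binned intensity counts (e.g. Hounsfield units from a CT volume)."""

    bin_edges: np.ndarray  # B + 1, strictly increasing
    counts: np.ndarray  # B, non-negative

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1-D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if not (np.diff(self.bin_edges) > 0).all():
            raise ValueError("bin_edges must be strictly increasing")
        if (self.counts < 0).any() or not np.isfinite(self.counts).all():
            raise ValueError("counts must be finite and non-negative")
        if self.counts.sum() < 2:
            raise ValueError("histogram needs total count >= 2")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_samples(
        cls, values: np.ndarray, bins: int = 256, range_=None
    ) -> "IntensityHistogram":
        counts, edges = np.histogram(values, bins=bins, range=range_)
        return cls(edges, counts)

    @classmethod
    def from_csv(cls, path) -> "IntensityHistogram":
        """Two-column CSV (bin_edge, count); the final row carries the
        closing edge with an empty/zero count."""
        data = np.genfromtxt(path, delimiter=",", names=True)
        edges = np.atleast_1d(data["bin_edge"])
        counts = np.atleast_1d(data["count"])[:-1]
        return cls(edges, counts)

    def to_csv(self, path) -> None:
        rows = ["bin_edge,count"]
        for e, c in zip(self.bin_edges[:-1], self.counts):
            rows.append(f"{e:.10g},{c:.10g}")
        rows.append(f"{self.bin_edges[-1]:.10g},0")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def _criterion(h: IntensityHistogram) -> np.ndarray:
    """Minimum-error criterion J(t) for every bin-edge threshold index.

    Threshold index T means class 1 = bins [0, T) and class 2 = bins
    [T, B); J(T) = 1 + 2 [P1 ln s1 + P2 ln s2] - 2 [P1 ln P1 + P2 ln P2].
    Indices where either class is empty or has zero variance are NaN.
    """
    c = h.centers
    w = h.counts / h.counts.sum()
    # cumulative moments below each threshold index T = 0..B
    P1 = np.concatenate([[0.0], np.cumsum(w)])
    m1 = np.concatenate([[0.0], np.cumsum(w * c)])
    s1 = np.concatenate([[0.0], np.cumsum(w * c**2)])
    P2 = P1[-1] - P1
    m2 = m1[-1] - m1
    s2 = s1[-1] - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = m1 / P1
        mu2 = m2 / P2
        var1 = s1 / P1 - mu1**2
        var2 = s2 / P2 - mu2**2
        J = 1.0 + 2.0 * (
            0.5 * P1 * np.log(var1) + 0.5 * P2 * np.log(var2)
        ) - 2.0 * (P1 * np.log(P1) + P2 * np.log(P2))
    bad = (
        (P1 <= 0)
        | (P2 <= 0)
        | ~np.isfinite(var1)
        | ~np.isfinite(var2)
        | (var1 <= 0)
        | (var2 <= 0)
    )
    J[bad] = np.nan
    return J


def kittler_illingworth_threshold(h: IntensityHistogram) -> float:
    """Minimum-error threshold (bin edge) for a bimodal histogram.

    Both classes are modelled as Gaussians; the returned edge minimises
    the Kittler–Illingworth criterion.  Thresholds leaving a class empty
    or with zero variance are excluded from the argmin domain rather than
    clamped.
    """
    if (h.counts > 0).sum() < 2:
        raise ValueError("histogram has mass in fewer than 2 bins")
    J = _criterion(h)
    if np.isnan(J).all():
        raise ValueError(
            "no valid threshold: every split leaves an empty or "
            "zero-variance class"
        )
    t_idx = int(np.nanargmin(J))
    return float(h.bin_edges[t_idx])


def high_intensity_threshold(h: IntensityHistogram, quantile: float) -> float:
    """Smallest bin edge at which cumulative mass reaches ``quantile``.

    Intended for isolating the highest-intensity (metal) voxels: use the
    returned value as the lower edge of a narrow metal band.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    total = h.counts.sum()
    if total <= 0 or (h.counts > 0).sum() < 1:
        raise ValueError("degenerate histogram")
    # cumulative mass strictly below each bin edge
    cum_below = np.concatenate([[0.0], np.cumsum(h.counts) / total])
    idx = int(np.searchsorted(cum_below, quantile, side="left"))
    # never return an edge above the last occupied bin: the band must
    # keep at least that bin
    idx = min(idx, int(np.flatnonzero(h.counts > 0)[-1]))
    return float(h.bin_edges[idx])
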