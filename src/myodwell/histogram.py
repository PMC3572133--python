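"""Area-normalized dwell-time histograms.

Histograms are the currency of the gating fit: experimental dwell
distributions are published as binned, area-normalized densities, and
the RMSD objective compares model and data bin by bin on *identical*
edges.  Bins are uniform and anchored at t = 0; density units are 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Histogram", "HistogramError"]


class HistogramError(ValueError):
    """Non-uniform bins, empty data, or mismatched edges."""


@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray          # length n_bins + 1, uniform, starting at 0
    density: np.ndarray        # 1/s, area-normalized
    n_samples: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "density", density)
        if edges.ndim != 1 or len(edges) < 2:
            raise HistogramError("need at least one bin")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise HistogramError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-8, atol=1e-12):
            raise HistogramError("bins must be uniform")
        if len(density) != len(edges) - 1:
            raise HistogramError("density length must equal bin count")
        if np.any(density < 0):
            raise HistogramError("density must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_bins(self) -> int:
        return len(self.density)

    @property
    def area(self) -> float:
        return float(np.sum(self.density) * self.bin_width)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def matches_edges(self, other: "Histogram") -> bool:
        return (self.n_bins == other.n_bins
                and np.allclose(self.edges, other.edges,
                                rtol=1e-9, atol=1e-12))

    @classmethod
    def from_dwells(cls, dwells, bin_width: float | None = None,
                    dead_time: float = 0.0,
                    edges: np.ndarray | None = None) -> "Histogram":
        """Bin raw dwell times into an area-normalized density.

        Either ``bin_width`` (bins from 0 covering the largest dwell) or
        explicit ``edges`` must be given.  Dwells below ``dead_time``
        are discarded before binning, emulating finite experimental
        resolution; with explicit edges, dwells beyond the last edge are
        likewise discarded and the density is renormalized over the
        retained range.
        """
        dwells = np.asarray(dwells, dtype=float)
        dwells = dwells[dwells >= dead_time]
        if dwells.size == 0:
            raise HistogramError(
                "no dwells left after dead-time filtering")
        if edges is None:
            if bin_width is None or bin_width <= 0:
                raise HistogramError("bin_width must be > 0")
            n = max(1, int(np.ceil(dwells.max() / bin_width + 1e-12)))
            edges = bin_width * np.arange(n + 1)
        else:
            edges = np.asarray(edges, dtype=float)
            dwells = dwells[dwells <= edges[-1]]
            if dwells.size == 0:
                raise HistogramError("no dwells inside the given edges")
        counts, _ = np.histogram(dwells, bins=edges)
        width = edges[1] - edges[0]
        density = counts / (counts.sum() * width)
        return cls(edges, density, n_samples=int(dwells.size))
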