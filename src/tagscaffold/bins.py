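"""Minor-allele-frequency bin schemes for stratified reporting.

Bins are half-open intervals (lo, hi] over the folded frequency, contiguous
and ending at 0.5.  The fine default is the ten-bin scheme used for
array-performance reporting; the broad default merges it into rare
(≤1%), low-frequency (1–5%) and common (5–50%) classes.  Sites at or below
the lowest edge fall outside the scheme and are tallied as excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_FINE_EDGES = [0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
_BROAD_EDGES = [0.005, 0.01, 0.05, 0.5]
_BROAD_LABELS = ["rare", "low", "common"]


@dataclass(frozen=True)
class MAFBinScheme:
    edges: tuple[float, ...]  # bin i is (edges[i], edges[i+1]]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if abs(e[-1] - 0.5) > 1e-12:
            raise ValueError("bins must end at 0.5")
        if len(self.labels) != len(e) - 1:
            raise ValueError("one label per bin required")

    @classmethod
    def fine(cls) -> "MAFBinScheme":
        labels = tuple(f"({lo:g},{hi:g}]" for lo, hi in zip(_FINE_EDGES, _FINE_EDGES[1:]))
        return cls(edges=tuple(_FINE_EDGES), labels=labels)

    @classmethod
    def broad(cls) -> "MAFBinScheme":
        return cls(edges=tuple(_BROAD_EDGES), labels=tuple(_BROAD_LABELS))

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    def assign(self, maf: np.ndarray) -> np.ndarray:
        """Bin index per site; -1 where MAF ≤ lowest edge (excluded)."""
        maf = np.asarray(maf, dtype=np.float64)
        idx = np.searchsorted(self.edges, maf, side="left") - 1
        idx[maf <= self.edges[0]] = -1
        idx[maf > self.edges[-1]] = -1  # folded MAF cannot exceed 0.5
        return idx
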