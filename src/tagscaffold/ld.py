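"""Pairwise linkage disequilibrium on phased haplotypes.

r² here is the gametic (haplotype) r²: with two-locus haplotype frequency
p_ab and marginal alt frequencies p_a, p_b,

    D  = p_ab - p_a * p_b
    r² = D² / (p_a (1-p_a) p_b (1-p_b))

computed within one population's haplotypes.  The engine emits, per
population, every pair of within-population-polymorphic sites on the same
chromosome with position distance ≤ ``window_bp`` and r² ≥ ``floor_r2``
(both bounds inclusive).  The defaults — 1 Mb window, 0.2 floor — are the
standard settings for array-design LD scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel


class MonomorphicSiteError(ValueError):
    """r² is undefined when a site has no variation in the population."""


def r_squared(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Gametic r² between two equal-length phased {0,1} allele columns."""
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be equal-length 1-D arrays")
    pa = a.mean()
    pb = b.mean()
    denom = pa * (1.0 - pa) * pb * (1.0 - pb)
    if denom == 0.0:
        raise MonomorphicSiteError("r^2 undefined for a monomorphic column")
    d = (a * b).mean() - pa * pb
    return float(min(1.0, max(0.0, d * d / denom)))


@dataclass
class LDStore:
    """Sparse within-population LD graph: site pairs with r² ≥ floor.

    ``a_idx``/``b_idx`` are panel-wide site indices with pos(a) < pos(b);
    adjacency is symmetric and built lazily.
    """

    population: str
    window_bp: int
    floor_r2: float
    n_sites: int
    a_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    b_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    r2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    _adj: dict[int, list[tuple[int, float]]] | None = field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return int(self.a_idx.size)

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.a_idx.tolist(), self.b_idx.tolist()))

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        if self._adj is None:
            adj: dict[int, list[tuple[int, float]]] = {}
            for a, b, r in zip(self.a_idx.tolist(), self.b_idx.tolist(), self.r2.tolist()):
                adj.setdefault(a, []).append((b, r))
                adj.setdefault(b, []).append((a, r))
            self._adj = adj
        return self._adj

    def neighbors(self, site: int) -> list[tuple[int, float]]:
        return self.adjacency().get(site, [])

    def max_r2_per_site(self) -> np.ndarray:
        """Max stored r² per site (0 where the site has no stored pair)."""
        out = np.zeros(self.n_sites)
        np.maximum.at(out, self.a_idx, self.r2)
        np.maximum.at(out, self.b_idx, self.r2)
        return out


def compute_ld(
    panel: HaplotypePanel,
    population: str,
    window_bp: int = 1_000_000,
    floor_r2: float = 0.2,
    block: int = 512,
) -> LDStore:
    """All within-window pairwise r² ≥ floor among one population's sites.

    Only sites polymorphic within the population enter; pairs never cross
    chromosomes.  Blockwise matrix products keep this fast on panels with
    thousands of sites.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    rows = panel.haplotype_rows(population)
    X = panel.haplotypes[rows].astype(np.float64)
    n_hap = X.shape[0]
    p = X.mean(axis=0)
    poly = (p > 0.0) & (p < 1.0)
    positions = panel.positions
    chroms = panel.chroms

    out_a: list[np.ndarray] = []
    out_b: list[np.ndarray] = []
    out_r: list[np.ndarray] = []
    for chrom in dict.fromkeys(chroms.tolist()):
        sites = np.flatnonzero((chroms == chrom) & poly)
        if sites.size < 2:
            continue
        pos = positions[sites]
        Xc = X[:, sites]
        pc = p[sites]
        var = pc * (1.0 - pc)
        m = sites.size
        for start in range(0, m, block):
            stop = min(start + block, m)
            # rightmost site within the window of the block's last site
            jmax = int(np.searchsorted(pos, pos[stop - 1] + window_bp, side="right"))
            A = Xc[:, start:stop]
            B = Xc[:, start:jmax]
            co = (A.T @ B) / n_hap
            d = co - np.outer(pc[start:stop], pc[start:jmax])
            r2 = np.clip(d * d / np.outer(var[start:stop], var[start:jmax]), 0.0, 1.0)
            ii, jj = np.nonzero(r2 >= floor_r2)
            gi = start + ii
            gj = start + jj
            keep = (gj > gi) & (pos[gj] - pos[gi] <= window_bp)
            gi, gj = gi[keep], gj[keep]
            out_a.append(sites[gi])
            out_b.append(sites[gj])
            out_r.append(r2[ii[keep], jj[keep]])

    if out_a:
        a = np.concatenate(out_a)
        b = np.concatenate(out_b)
        r = np.concatenate(out_r)
        order = np.lexsort((b, a))
        a, b, r = a[order], b[order], r[order]
    else:
        a = np.empty(0, dtype=np.int64)
        b = np.empty(0, dtype=np.int64)
        r = np.empty(0, dtype=np.float64)
    return LDStore(
        population=population,
        window_bp=window_bp,
        floor_r2=floor_r2,
        n_sites=panel.n_sites,
        a_idx=a,
        b_idx=b,
        r2=r,
    )


def write_ld_tsv(store: LDStore, panel: HaplotypePanel, path: str) -> None:
    """Plink-style pairwise output: ``chrom pos_a pos_b r2``."""
    chroms = panel.chroms
    positions = panel.positions
    with open(path, "w") as fh:
        fh.write("chrom\tpos_a\tpos_b\tr2\n")
        for a, b, r in zip(store.a_idx, store.b_idx, store.r2):
            fh.write(f"{chroms[a]}\t{positions[a]}\t{positions[b]}\t{r:.10g}\n")


def read_ld_tsv(
    path: str, panel: HaplotypePanel, population: str, window_bp: int, floor_r2: float
) -> LDStore:
    """Rebuild an LDStore from its TSV export, mapping positions to site indices."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    index = {(v.chrom, v.pos): i for i, v in enumerate(panel.variants)}
    a = np.array([index[(c, int(pa))] for c, pa in zip(df["chrom"], df["pos_a"])], dtype=np.int64)
    b = np.array([index[(c, int(pb))] for c, pb in zip(df["chrom"], df["pos_b"])], dtype=np.int64)
    return LDStore(
        population=population,
        window_bp=window_bp,
        floor_r2=floor_r2,
        n_sites=panel.n_sites,
        a_idx=a,
        b_idx=b,
        r2=df["r2"].to_numpy(dtype=np.float64),
    )
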