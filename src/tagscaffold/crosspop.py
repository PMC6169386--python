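"""Cross-population merging, ranking, and allocation of tag SNP candidates.

Two published ranking schemes are implemented.  The *naive* scheme orders
candidate tags by the absolute number of unique sites they tag across all
populations (union over populations of each tag's newly-tagged sets).  The
*cross-population prioritization* scheme first orders by the number of
populations in which the tag is informative (tags at least one site), and
only within those categories by the unique-tag count — down-weighting tags
whose yield comes from a single LD-rich population.  A genome-wide
allocation is split per chromosome proportionally to physical length
(largest-remainder integerization) and the scaffold is cut from the top of
the ranked list per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel
from .tagger import TagRun


@dataclass
class CrossPopTagRecord:
    site: int
    newly_tagged: dict[str, frozenset[int]]  # population -> sites tagged there

    @property
    def informative_in(self) -> dict[str, bool]:
        return {pop: bool(s) for pop, s in self.newly_tagged.items()}

    @property
    def n_pops_informative(self) -> int:
        return sum(1 for s in self.newly_tagged.values() if s)

    @property
    def total_unique_tagged(self) -> int:
        union: set[int] = set()
        for s in self.newly_tagged.values():
            union |= s
        return len(union)


@dataclass
class ScaffoldDesign:
    """An ordered tag list with its selection provenance."""

    method: str  # "naive" | "crosspop" | "single-population"
    sites: list[int]  # rank order
    min_maf: float
    min_r2: float
    allocation: dict[str, int]  # chromosome -> requested count
    shortfall: dict[str, int] = field(default_factory=dict)

    @property
    def site_set(self) -> frozenset[int]:
        return frozenset(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def merge_population_runs(runs: dict[str, TagRun]) -> list[CrossPopTagRecord]:
    """One record per site selected as a tag in at least one population run."""
    if not runs:
        raise ValueError("no runs to merge")
    spaces = {run.n_sites for run in runs.values()}
    if len(spaces) != 1:
        raise ValueError(f"runs have mismatched variant spaces: {sorted(spaces)}")
    pops = list(runs)
    selected: dict[int, dict[str, frozenset[int]]] = {}
    for pop in pops:
        for tag in runs[pop].tags:
            selected.setdefault(tag.site, {})[pop] = tag.newly_tagged
    records = []
    for site in sorted(selected):
        per_pop = {pop: selected[site].get(pop, frozenset()) for pop in pops}
        records.append(CrossPopTagRecord(site=site, newly_tagged=per_pop))
    return records


def rank_naive(records: list[CrossPopTagRecord]) -> list[int]:
    """Descending unique-tagged count; ties to the smaller (chrom, pos)."""
    return [r.site for r in sorted(records, key=lambda r: (-r.total_unique_tagged, r.site))]


def rank_crosspop(records: list[CrossPopTagRecord]) -> list[int]:
    """Population breadth first, then unique-tagged count, then position."""
    return [
        r.site
        for r in sorted(
            records,
            key=lambda r: (-r.n_pops_informative, -r.total_unique_tagged, r.site),
        )
    ]


def allocate_per_chromosome(genome_n: int, chrom_lengths: dict[str, int]) -> dict[str, int]:
    """Split a genome-wide budget proportionally to chromosome length.

    Largest-remainder integerization: counts floor the exact quotas, and the
    leftover units go to the largest fractional remainders (ties to the
    chromosome listed first).  The result sums exactly to ``genome_n``.
    """
    if not chrom_lengths:
        raise ValueError("empty chromosome length table")
    if genome_n < 0:
        raise ValueError("allocation must be non-negative")
    lengths = np.array(list(chrom_lengths.values()), dtype=np.float64)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    quota = genome_n * lengths / lengths.sum()
    base = np.floor(quota).astype(np.int64)
    remainder = quota - base
    short = genome_n - int(base.sum())
    order = sorted(range(len(lengths)), key=lambda i: (-remainder[i], i))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(chrom_lengths, base.tolist()))


def build_scaffold(
    ranked: list[int],
    allocation: dict[str, int],
    panel: HaplotypePanel,
    method: str,
    min_maf: float,
    min_r2: float,
) -> ScaffoldDesign:
    """Cut the top of the ranked list per chromosome to the allocated counts."""
    chroms = panel.chroms
    taken: dict[str, int] = {c: 0 for c in allocation}
    sites: list[int] = []
    for site in ranked:
        c = str(chroms[site])
        if c in taken and taken[c] < allocation[c]:
            sites.append(site)
            taken[c] += 1
    shortfall = {c: allocation[c] - taken[c] for c in allocation if allocation[c] > taken[c]}
    return ScaffoldDesign(
        method=method,
        sites=sites,
        min_maf=min_maf,
        min_r2=min_r2,
        allocation=dict(allocation),
        shortfall=shortfall,
    )


def write_scaffold_tsv(
    design: ScaffoldDesign,
    panel: HaplotypePanel,
    path: str,
    records: list[CrossPopTagRecord] | None = None,
) -> None:
    chroms = panel.chroms
    positions = panel.positions
    by_site = {r.site: r for r in records} if records else {}
    pops = list(next(iter(by_site.values())).newly_tagged) if by_site else []
    with open(path, "w") as fh:
        header = "rank\tchrom\tpos\tn_pops_informative\ttotal_unique_tagged\tmethod"
        header += "".join(f"\tinformative_{p}" for p in pops)
        fh.write(header + "\n")
        for rank, site in enumerate(design.sites, start=1):
            rec = by_site.get(site)
            npops = rec.n_pops_informative if rec else 0
            uniq = rec.total_unique_tagged if rec else 0
            row = f"{rank}\t{chroms[site]}\t{positions[site]}\t{npops}\t{uniq}\t{design.method}"
            if rec:
                row += "".join(f"\t{int(rec.informative_in[p])}" for p in pops)
            fh.write(row + "\n")
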