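"""Greedy tag SNP selection on a per-population LD graph.

At each step the unmasked, MAF-eligible site with the most unmasked LD
partners at r² ≥ ``min_r2`` is selected as a tag; the tag and all of its
partners are then masked and removed from every future degree count.  The
loop repeats until the budget is spent or no eligible site has an unmasked
partner left; remaining budget is then filled with zero-partner eligible
sites in position order.  Ties in degree break to the smaller (chrom, pos)
— i.e. the smaller panel site index, since panels are coordinate-sorted.

Degree counting deliberately uses *residual* degree (unmasked partners
only), so each successive tag is scored against what is still untagged.
Partner sites need not themselves pass the MAF filter: a rare site can be
tagged even though it could never be a tag.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .ld import LDStore
from .panel import FrequencyTable


@dataclass(frozen=True)
class TagCandidateResult:
    site: int
    n_partners: int
    newly_tagged: frozenset[int]
    selection_rank: int  # 1-based


@dataclass
class TagRun:
    population: str
    min_maf: float
    min_r2: float
    n_sites: int
    tags: list[TagCandidateResult] = field(default_factory=list)
    masked: set[int] = field(default_factory=set)

    @property
    def tag_sites(self) -> list[int]:
        return [t.site for t in self.tags]

    def newly_tagged_of(self) -> dict[int, frozenset[int]]:
        return {t.site: t.newly_tagged for t in self.tags}


def greedy_select(
    ld: LDStore,
    freqs: FrequencyTable,
    min_maf: float,
    min_r2: float,
    max_tags: int | None = None,
) -> TagRun:
    """Run the greedy tagging loop for one population.

    ``min_r2`` must be at or above the LD store's floor — pairs below the
    floor were never computed and cannot be resurrected here.
    """
    if min_r2 < ld.floor_r2:
        raise ValueError(
            f"min_r2={min_r2} is below the LD store floor {ld.floor_r2}; "
            "recompute LD with a lower floor"
        )
    maf = freqs.maf(ld.population)
    if len(maf) != ld.n_sites:
        raise ValueError("frequency table does not match the LD store's site space")
    eligible = maf >= min_maf

    # adjacency restricted to edges at or above the selection threshold
    adj: dict[int, set[int]] = {}
    for a, b, r in zip(ld.a_idx.tolist(), ld.b_idx.tolist(), ld.r2.tolist()):
        if r >= min_r2:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)

    degree = {s: len(nb) for s, nb in adj.items()}
    masked: set[int] = set()
    # lazy max-heap keyed by (-degree, site); stale entries re-validated on pop
    heap = [(-d, s) for s, d in degree.items() if eligible[s]]
    heapq.heapify(heap)

    run = TagRun(
        population=ld.population, min_maf=min_maf, min_r2=min_r2, n_sites=ld.n_sites
    )
    budget = np.inf if max_tags is None else max_tags
    while heap and len(run.tags) < budget:
        neg_d, site = heapq.heappop(heap)
        if site in masked:
            continue
        d = degree[site]
        if d != -neg_d:  # stale; reinsert with current degree
            if d > 0:
                heapq.heappush(heap, (-d, site))
            continue
        if d == 0:
            break
        newly = frozenset(adj[site] - masked)
        to_mask = newly | {site}
        masked |= to_mask
        for m in to_mask:
            for u in adj.get(m, ()):
                if u not in masked:
                    degree[u] -= 1
        run.tags.append(
            TagCandidateResult(
                site=site,
                n_partners=d,
                newly_tagged=newly,
                selection_rank=len(run.tags) + 1,
            )
        )

    # fill a finite remaining budget with zero-partner eligible sites, in
    # position order, so a requested allocation is met whenever possible
    if max_tags is not None and len(run.tags) < max_tags:
        for site in np.flatnonzero(eligible):
            site = int(site)
            if site in masked:
                continue
            run.tags.append(
                TagCandidateResult(
                    site=site,
                    n_partners=0,
                    newly_tagged=frozenset(),
                    selection_rank=len(run.tags) + 1,
                )
            )
            masked.add(site)
            if len(run.tags) >= max_tags:
                break

    run.masked = masked
    return run


def write_tags_tsv(run: TagRun, panel, path: str) -> None:
    """Per-population tag output: rank, locus, degree, newly-tagged sites."""
    chroms = panel.chroms
    positions = panel.positions
    with open(path, "w") as fh:
        fh.write("rank\tchrom\tpos\tn_partners\tn_newly_tagged\tnewly_tagged_positions\n")
        for t in run.tags:
            newpos = ",".join(str(positions[s]) for s in sorted(t.newly_tagged))
            fh.write(
                f"{t.selection_rank}\t{chroms[t.site]}\t{positions[t.site]}\t"
                f"{t.n_partners}\t{len(t.newly_tagged)}\t{newpos or '.'}\n"
            )
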