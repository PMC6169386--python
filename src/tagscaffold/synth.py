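"""Seeded synthetic haplotype panels for end-to-end testing at desk scale.

Two generators are provided.  :func:`simulate_panel` runs a coalescent-
with-recombination simulation (msprime) under a configurable population
tree — the default emulates the continental contrasts that drive array-
design trade-offs: a high-diversity, low-LD population of constant size
(African-like), a population with a tight out-of-Africa bottleneck
followed by rapid growth and hence an excess of rare variants (East-
Asian-like), and an intermediate bottleneck-and-growth population
(European-like), using Gravel-style demographic parameters.  An admixed
population is built as a tract mosaic over extra donor haplotypes drawn
from the source populations, with ancestry switch points laid down as a
Poisson process at ``generations_ago`` per Morgan, so the true local-
ancestry tracts are known exactly and tile each admixed haplotype.

:func:`deterministic_fixture` returns tiny hand-constructed panels with
exactly known LD values for exact-value tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import AncestryTract
from .panel import HaplotypePanel, Variant


@dataclass(frozen=True)
class PopulationConfig:
    """One population in the demographic tree.

    ``initial_size`` is the present-day effective size; an optional
    exponential ``growth_rate`` (per generation, backwards-decaying) and a
    step change to ``bottleneck_size`` at ``bottleneck_time`` describe the
    trajectory.  Non-root populations merge into ``parent`` at
    ``split_time`` (generations ago).
    """

    name: str
    n_samples: int
    initial_size: float
    growth_rate: float = 0.0
    bottleneck_time: float | None = None
    bottleneck_size: float | None = None
    parent: str | None = None
    split_time: float | None = None


@dataclass(frozen=True)
class AdmixtureConfig:
    """Admixed population formed ``generations_ago`` from ``sources``."""

    name: str
    n_samples: int
    sources: tuple[str, ...]
    proportions: tuple[float, ...]
    generations_ago: float = 8.0
    n_donors_per_source: int = 30


@dataclass(frozen=True)
class DemographyConfig:
    populations: tuple[PopulationConfig, ...]
    admixture: AdmixtureConfig | None = None
    sequence_length: float = 2_000_000.0
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None or self.seed <= 0:
            raise ValueError("a positive random seed is mandatory")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p.split_time is not None and p.split_time <= 0:
                raise ValueError(f"{p.name}: split_time must be positive")
            if (p.split_time is None) != (p.parent is None):
                raise ValueError(f"{p.name}: parent and split_time go together")
        if self.admixture is not None:
            a = self.admixture
            if abs(sum(a.proportions) - 1.0) > 1e-9:
                raise ValueError("admixture proportions must sum to 1")
            if len(a.proportions) != len(a.sources):
                raise ValueError("one proportion per source required")
            for s in a.sources:
                if s not in names:
                    raise ValueError(f"admixture source {s!r} not a configured population")
            if a.generations_ago <= 0:
                raise ValueError("admixture time must be positive")


def default_config(seed: int, scale: float = 1.0) -> DemographyConfig:
    """Desk-scale three-population + admixed default (Gravel-style history).

    POPA: constant-size, high-diversity, low-LD (African-like).
    POPB: tight bottleneck then fast growth — excess rare variants
          (East-Asian-like).
    POPC: moderate bottleneck then growth (European-like).
    ADMIX: 80/20 POPA/POPC admixture 8 generations ago (Afro-Caribbean-like).

    ``scale`` < 1 shrinks sample sizes and sequence length together for
    quick smoke runs.
    """

    def n(x: int) -> int:
        return max(3, int(round(x * scale)))

    pops = (
        PopulationConfig(
            name="POPA",
            n_samples=n(60),
            initial_size=14474,
            bottleneck_time=5920,
            bottleneck_size=7310,
        ),
        PopulationConfig(name="OOA", n_samples=0, initial_size=1861, parent="POPA", split_time=2040),
        PopulationConfig(
            name="POPB",
            n_samples=n(60),
            initial_size=45800,
            growth_rate=0.0048,
            parent="OOA",
            split_time=920,
        ),
        PopulationConfig(
            name="POPC",
            n_samples=n(60),
            initial_size=34000,
            growth_rate=0.0038,
            parent="OOA",
            split_time=920,
        ),
    )
    admix = AdmixtureConfig(
        name="ADMIX",
        n_samples=n(40),
        sources=("POPA", "POPC"),
        proportions=(0.8, 0.2),
        generations_ago=8.0,
        n_donors_per_source=n(30),
    )
    return DemographyConfig(
        populations=pops,
        admixture=admix,
        sequence_length=2_000_000.0 * max(scale, 0.05),
        seed=seed,
    )


def simulate_panel(config: DemographyConfig) -> tuple[HaplotypePanel, list[AncestryTract]]:
    """Simulate a phased biallelic multi-population panel (+ true tracts).

    Identical config and seed give bitwise-identical output.  Sites
    monomorphic in the emitted panel (e.g. segregating only among the
    discarded admixture donors) are dropped.
    """
    import msprime

    dem = msprime.Demography()
    for p in config.populations:
        dem.add_population(name=p.name, initial_size=p.initial_size, growth_rate=p.growth_rate)
        if p.bottleneck_time is not None:
            dem.add_population_parameters_change(
                time=p.bottleneck_time,
                population=p.name,
                initial_size=p.bottleneck_size,
                growth_rate=0.0,
            )
    splits: dict[tuple[float, str], list[str]] = {}
    for p in config.populations:
        if p.parent is not None:
            splits.setdefault((p.split_time, p.parent), []).append(p.name)
    for (time, parent), derived in sorted(splits.items()):
        dem.add_population_split(time=time, derived=derived, ancestral=parent)
    dem.sort_events()

    samples = []
    donor_counts: dict[str, int] = {}
    for p in config.populations:
        if p.n_samples > 0:
            samples.append(msprime.SampleSet(p.n_samples, population=p.name, ploidy=2))
    if config.admixture is not None:
        for s in config.admixture.sources:
            samples.append(
                msprime.SampleSet(
                    config.admixture.n_donors_per_source, population=s, ploidy=2
                )
            )
            donor_counts[s] = config.admixture.n_donors_per_source

    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        random_seed=config.seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        random_seed=config.seed + 1,
        model=msprime.BinaryMutationModel(),
    )

    G = ts.genotype_matrix().T.astype(np.uint8)  # (n_haps, n_sites), {0,1}
    positions = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)

    # haplotype row bookkeeping: sample sets appear in request order
    row = 0
    pop_rows: dict[str, tuple[int, int]] = {}
    for p in config.populations:
        if p.n_samples > 0:
            pop_rows[p.name] = (row, row + 2 * p.n_samples)
            row += 2 * p.n_samples
    donor_rows: dict[str, tuple[int, int]] = {}
    if config.admixture is not None:
        for s in config.admixture.sources:
            donor_rows[s] = (row, row + 2 * donor_counts[s])
            row += 2 * donor_counts[s]

    sample_ids: list[str] = []
    population_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for p in config.populations:
        if p.n_samples > 0:
            lo, hi = pop_rows[p.name]
            blocks.append(G[lo:hi])
            for i in range(p.n_samples):
                sid = f"{p.name}_{i:03d}"
                sample_ids.append(sid)
                population_of[sid] = p.name

    tracts: list[AncestryTract] = []
    if config.admixture is not None:
        adm = config.admixture
        rng = np.random.default_rng(config.seed + 2)
        morgan_per_bp = config.recombination_rate
        total_morgan = config.sequence_length * morgan_per_bp
        adm_block = np.empty((2 * adm.n_samples, G.shape[1]), dtype=np.uint8)
        for i in range(adm.n_samples):
            sid = f"{adm.name}_{i:03d}"
            sample_ids.append(sid)
            population_of[sid] = adm.name
            for h in (0, 1):
                hap_row = 2 * i + h
                n_breaks = rng.poisson(adm.generations_ago * total_morgan)
                breaks_bp = np.sort(rng.uniform(1.0, config.sequence_length, size=n_breaks))
                bounds = np.concatenate(([1.0], breaks_bp, [config.sequence_length + 1.0]))
                seg_anc = rng.choice(len(adm.sources), size=len(bounds) - 1, p=adm.proportions)
                hap = np.empty(G.shape[1], dtype=np.uint8)
                merged: list[tuple[int, int, str]] = []
                for k in range(len(seg_anc)):
                    src = adm.sources[seg_anc[k]]
                    lo, hi = donor_rows[src]
                    donor = rng.integers(lo, hi)
                    start, end = int(np.ceil(bounds[k])), int(np.ceil(bounds[k + 1]))
                    sel = (positions >= start) & (positions < end)
                    hap[sel] = G[donor, sel]
                    if merged and merged[-1][2] == src:
                        merged[-1] = (merged[-1][0], end, src)
                    else:
                        merged.append((start, end, src))
                adm_block[hap_row] = hap
                for start, end, src in merged:
                    tracts.append(
                        AncestryTract(
                            individual=sid,
                            haplotype=h,
                            chrom=config.chrom,
                            start_bp=start,
                            end_bp=end,
                            start_cm=start * morgan_per_bp * 100.0,
                            end_cm=end * morgan_per_bp * 100.0,
                            ancestry=src,
                        )
                    )
        blocks.append(adm_block)

    H = np.concatenate(blocks, axis=0)
    # drop duplicated positions (possible under a finite-sites model) and
    # sites monomorphic in the retained panel
    _, first = np.unique(positions, return_index=True)
    keep_u = np.zeros(positions.size, dtype=bool)
    keep_u[first] = True
    counts = H.sum(axis=0)
    keep = keep_u & (counts > 0) & (counts < H.shape[0])
    H = H[:, keep]
    positions = positions[keep]

    variants = [
        Variant(chrom=config.chrom, pos=int(p), id=None, ref="A", alt="C") for p in positions
    ]
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=H,
        sample_ids=sample_ids,
        population_of=population_of,
    )
    return panel, tracts


# ---------------------------------------------------------------------------
# Hand-constructed exact fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("chain", "star", "two-pop-shared", "lone-site", "admixed-toy")


def _panel(columns: list[tuple[int, str]], rows_pop: list[str], chrom: str = "1") -> HaplotypePanel:
    """Build a panel from (pos, "0101..." allele string) columns.

    ``rows_pop`` gives the population of each *diploid* sample; haplotype
    strings must be 2x that length.
    """
    columns = sorted(columns)
    H = np.array([[int(c) for c in col] for _, col in columns], dtype=np.uint8).T
    sample_ids = [f"S{i:02d}" for i in range(len(rows_pop))]
    return HaplotypePanel(
        variants=[Variant(chrom, pos, None, "A", "C") for pos, _ in columns],
        haplotypes=H,
        sample_ids=sample_ids,
        population_of=dict(zip(sample_ids, rows_pop)),
    )


def deterministic_fixture(name: str) -> HaplotypePanel:
    """Tiny panels with exactly known LD structure.

    chain          : sites 1–2 and 2–3 in strong LD (r² 0.6, 0.5556), 1–3
                     weak (0.3333) — the middle site is the unique best tag.
    star           : a centre site with r² ≈ 0.714 to five leaves that share
                     only r² ≈ 0.432 with each other.
    two-pop-shared : site at pos 100 informative in both populations; site
                     at pos 300 informative only in POP1.
    lone-site      : exactly one site (pos 400) with max pairwise r² = 0.
    admixed-toy    : two source populations plus six admixed samples whose
                     tract truth comes from :func:`fixture_tracts`.
    """
    if name == "chain":
        return _panel(
            [(100, "11110000"), (200, "11100000"), (300, "11000000")],
            rows_pop=["POP1"] * 4,
        )
    if name == "star":
        centre = "111111000000"
        cols = [(1000, centre)]
        for i in range(5):
            leaf = list(centre)
            leaf[6 + i] = "1"
            cols.append((2000 + 1000 * i, "".join(leaf)))
        return _panel(cols, rows_pop=["POP1"] * 6)
    if name == "two-pop-shared":
        # rows: 10 POP1 haplotypes then 10 POP2 haplotypes
        a = "1111100000" + "1110000000"  # pos 100
        b = "1111100000" + "1110000000"  # pos 200: duplicate of a -> r²=1 in both pops
        c = "1100000000" + "0000000000"  # pos 300: monomorphic in POP2
        d = "1100000000" + "1111100000"  # pos 400: r²=1 with c in POP1 only
        return _panel(
            [(100, a), (200, b), (300, c), (400, d)],
            rows_pop=["POP1"] * 5 + ["POP2"] * 5,
        )
    if name == "lone-site":
        x = "1111111111" + "0000000000"
        lone = "1111100000" + "0000011111"  # p11 = 0.25 = px*pl -> D = 0
        return _panel(
            [(100, x), (200, x), (300, x), (400, lone)],
            rows_pop=["POP1"] * 10,
        )
    if name == "admixed-toy":
        return _admixed_toy()[0]
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def fixture_tracts(name: str) -> list[AncestryTract]:
    """True local-ancestry tracts for the 'admixed-toy' fixture."""
    if name != "admixed-toy":
        raise ValueError("only the 'admixed-toy' fixture has tracts")
    return _admixed_toy()[1]


def _admixed_toy() -> tuple[HaplotypePanel, list[AncestryTract]]:
    """Two source populations over 80 Mb (~80 cM) + 6 admixed diploids.

    Sites sit at 5,15,...,75 Mb.  Source ANCA haplotypes carry the alt
    allele on the left half, ANCB on the right half (with within-pop
    variation so every site is polymorphic in its source).  The admixed
    samples copy whole donor haplotypes per tract; tract truth includes one
    tract just below the default 20 cM filter on ADM2's haplotype 0.
    """
    n_sites = 8
    pos = [5_000_000 + 10_000_000 * i for i in range(n_sites)]

    # two donor variants per ancestry so truth varies *within* a diplotype
    # category (otherwise per-site accuracy would be undefined everywhere)
    flip = np.array([1, 1, 1, 0, 0, 1, 0, 1], dtype=np.uint8)
    a0 = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.uint8)
    b0 = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.uint8)
    donors = {("ANCA", 0): a0, ("ANCA", 1): a0 ^ flip, ("ANCB", 0): b0, ("ANCB", 1): b0 ^ flip}

    def pop_block(base: np.ndarray) -> np.ndarray:
        rows = [base.copy() for _ in range(8)]
        rows[0] = base ^ flip
        rows[1] = base ^ flip
        return np.array(rows, dtype=np.uint8)

    src_a = pop_block(a0)  # 8 haps = 4 diploids
    src_b = pop_block(b0)

    # admixed haplotypes: segments of (end_bp_exclusive, ancestry, donor variant)
    region_end = 80_000_001
    plans = {
        ("ADM0", 0): [(40_000_000, "ANCA", 0), (region_end, "ANCB", 0)],
        ("ADM0", 1): [(region_end, "ANCA", 0)],
        ("ADM1", 0): [(region_end, "ANCA", 1)],
        ("ADM1", 1): [(region_end, "ANCB", 1)],
        ("ADM2", 0): [(20_000_000, "ANCA", 0), (region_end, "ANCB", 0)],  # ~20 cM, sub-threshold
        ("ADM2", 1): [(region_end, "ANCB", 1)],
        ("ADM3", 0): [(region_end, "ANCA", 1)],
        ("ADM3", 1): [(region_end, "ANCA", 1)],
        ("ADM4", 0): [(region_end, "ANCA", 0)],
        ("ADM4", 1): [(60_000_000, "ANCB", 0), (region_end, "ANCA", 1)],
        ("ADM5", 0): [(region_end, "ANCB", 1)],
        ("ADM5", 1): [(region_end, "ANCA", 0)],
    }
    pos_arr = np.array(pos)
    adm_rows = []
    tracts: list[AncestryTract] = []
    for (ind, h), segs in plans.items():
        hap = np.zeros(n_sites, dtype=np.uint8)
        start = 1
        for end, anc, var in segs:
            sel = (pos_arr >= start) & (pos_arr < end)
            hap[sel] = donors[(anc, var)][sel]
            tracts.append(
                AncestryTract(
                    individual=ind,
                    haplotype=h,
                    chrom="1",
                    start_bp=start,
                    end_bp=end,
                    start_cm=start * 1e-6,
                    end_cm=end * 1e-6,
                    ancestry=anc,
                )
            )
            start = end
        adm_rows.append(hap)
    adm = np.array(adm_rows, dtype=np.uint8)

    H = np.concatenate([src_a, src_b, adm], axis=0)
    sample_ids = (
        [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)] + [f"ADM{i}" for i in range(6)]
    )
    population_of = {s: "SRCA" for s in sample_ids[:4]}
    population_of.update({s: "SRCB" for s in sample_ids[4:8]})
    population_of.update({s: "ADMIX" for s in sample_ids[8:]})
    panel = HaplotypePanel(
        variants=[Variant("1", p, None, "A", "C") for p in pos],
        haplotypes=H,
        sample_ids=sample_ids,
        population_of=population_of,
    )
    return panel, tracts
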