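"""Non-imputation scaffold metrics.

Pairwise coverage, tag informativeness and cross-population sharing,
tagging potential, lone/dark sites, and local-ancestry-stratified
imputation accuracy.  Conventions:

* "polymorphic" at floor t means MAF **strictly** greater than t
  (default t = 0.005, i.e. MAF > 0.5%);
* coverage and informativeness use inclusive r² thresholds (≥), matching
  the rest of the package;
* lone-site detection asks for the *absence* of any pair with r²
  strictly above 0.2 — the one place a strict inequality is used, kept
  local to that operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import MAFBinScheme
from .crosspop import ScaffoldDesign
from .imputer import AccuracyReport, DosageMatrix, _columnwise_r2
from .ld import LDStore, compute_ld
from .panel import FrequencyTable, HaplotypePanel

POLYMORPHISM_FLOOR = 0.005
LONE_SITE_R2 = 0.2
INFORMATIVE_R2 = 0.5


# ---------------------------------------------------------------------------
# Pairwise coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageReport:
    population: str
    r2_threshold: float
    table: pd.DataFrame  # bin, n_sites, n_covered, proportion

    @property
    def overall(self) -> float:
        n = self.table["n_sites"].sum()
        return float(self.table["n_covered"].sum() / n) if n else float("nan")


def pairwise_coverage(
    ld_full: LDStore,
    scaffold: ScaffoldDesign | frozenset[int],
    r2_threshold: float,
    freqs: FrequencyTable,
    scheme: MAFBinScheme | None = None,
    polymorphism_floor: float = POLYMORPHISM_FLOOR,
) -> CoverageReport:
    """Proportion of untyped polymorphic sites with ≥1 tag partner at r² ≥ t.

    The denominator is the population's polymorphic (MAF > floor) sites that
    are *not* on the scaffold; scaffold sites are neither covered nor
    uncovered.  ``ld_full`` must have been computed with a floor at or below
    the threshold.
    """
    if r2_threshold < ld_full.floor_r2:
        raise ValueError(
            f"threshold {r2_threshold} below LD store floor {ld_full.floor_r2}"
        )
    scheme = scheme or MAFBinScheme.fine()
    tag_set = scaffold.site_set if isinstance(scaffold, ScaffoldDesign) else frozenset(scaffold)
    maf = freqs.maf(ld_full.population)
    in_scaffold = np.zeros(ld_full.n_sites, dtype=bool)
    if tag_set:
        in_scaffold[sorted(tag_set)] = True
    denom = (maf > polymorphism_floor) & ~in_scaffold

    covered = np.zeros(ld_full.n_sites, dtype=bool)
    strong = ld_full.r2 >= r2_threshold
    a, b = ld_full.a_idx[strong], ld_full.b_idx[strong]
    covered[a[in_scaffold[b]]] = True
    covered[b[in_scaffold[a]]] = True

    bin_idx = scheme.assign(maf)
    rows = []
    for i, label in enumerate(scheme.labels):
        sel = denom & (bin_idx == i)
        n = int(sel.sum())
        c = int((sel & covered).sum())
        rows.append(
            {
                "bin": label,
                "n_sites": n,
                "n_covered": c,
                "proportion": c / n if n else np.nan,
            }
        )
    return CoverageReport(
        population=ld_full.population, r2_threshold=r2_threshold, table=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# Informativeness and sharing
# ---------------------------------------------------------------------------


def informativeness(
    scaffold: ScaffoldDesign | frozenset[int],
    ld_by_pop: dict[str, LDStore],
    freqs: FrequencyTable,
    polymorphism_floor: float = POLYMORPHISM_FLOOR,
    r2_informative: float = INFORMATIVE_R2,
) -> pd.DataFrame:
    """Per-tag, per-population informativeness (bool table, tags as rows).

    A tag is informative in a population iff it segregates there
    (MAF > floor) and has at least one *non-scaffold* partner with
    r² ≥ ``r2_informative`` in that population's LD.
    """
    tag_set = scaffold.site_set if isinstance(scaffold, ScaffoldDesign) else frozenset(scaffold)
    tags = (
        list(scaffold.sites)
        if isinstance(scaffold, ScaffoldDesign)
        else sorted(tag_set)
    )
    data = {}
    for pop, ld in ld_by_pop.items():
        maf = freqs.maf(pop)
        col = []
        for s in tags:
            ok = maf[s] > polymorphism_floor and any(
                r >= r2_informative and p not in tag_set for p, r in ld.neighbors(s)
            )
            col.append(ok)
        data[pop] = col
    return pd.DataFrame(data, index=tags)


@dataclass
class SharingProfile:
    distribution: pd.DataFrame  # index pop x n-pops (1..P): proportions
    conditional: pd.DataFrame  # P(informative in col | informative in row)
    undefined_rows: list[str] = field(default_factory=list)


def sharing_profiles(inf_table: pd.DataFrame) -> SharingProfile:
    """Cross-population sharing of informative tags.

    Row A of the conditional matrix is computed over the tags informative
    in A (diagonal 1 by construction); the distribution gives, for each
    index population, the share of its informative tags that are
    informative in exactly n populations overall.
    """
    pops = list(inf_table.columns)
    if len(pops) < 2:
        raise ValueError("sharing requires at least two populations")
    counts = inf_table.sum(axis=1)  # n populations informative per tag
    dist_rows = {}
    cond = pd.DataFrame(np.nan, index=pops, columns=pops)
    undefined = []
    for a in pops:
        mask = inf_table[a].to_numpy(dtype=bool)
        total = int(mask.sum())
        if total == 0:
            undefined.append(a)
            dist_rows[a] = {n: np.nan for n in range(1, len(pops) + 1)}
            continue
        dist_rows[a] = {
            n: float((counts[mask] == n).sum() / total) for n in range(1, len(pops) + 1)
        }
        for b in pops:
            cond.loc[a, b] = float(inf_table[b].to_numpy(dtype=bool)[mask].sum() / total)
    dist = pd.DataFrame(dist_rows).T
    dist.index.name = "index_population"
    return SharingProfile(distribution=dist, conditional=cond, undefined_rows=undefined)


# ---------------------------------------------------------------------------
# Tagging potential
# ---------------------------------------------------------------------------


def tagging_potential(
    ld: LDStore,
    freqs: FrequencyTable,
    min_maf: float,
    min_r2: float,
) -> tuple[int, float]:
    """Tags needed to capture every pairwise relationship, and mean yield.

    Runs the greedy tagger unbounded; returns the number of tags with at
    least one partner and the mean number of sites captured per such tag
    (NaN when the graph is empty — saturation then needs no tags).
    """
    from .tagger import greedy_select

    run = greedy_select(ld, freqs, min_maf=min_maf, min_r2=min_r2, max_tags=None)
    informative = [t for t in run.tags if t.n_partners > 0]
    n = len(informative)
    if n == 0:
        return 0, float("nan")
    total = sum(len(t.newly_tagged) for t in informative)
    return n, total / n


# ---------------------------------------------------------------------------
# Lone and dark sites
# ---------------------------------------------------------------------------


def lone_sites(
    panel: HaplotypePanel,
    population: str,
    window_bp: int = 1_000_000,
    freqs: FrequencyTable | None = None,
    polymorphism_floor: float = POLYMORPHISM_FLOOR,
    ld: LDStore | None = None,
) -> list[int]:
    """Polymorphic sites with no pairwise r² > 0.2 within the window.

    A precomputed LD store (floor ≤ 0.2, same window) can be passed to
    avoid recomputation.
    """
    if freqs is None:
        from .panel import allele_frequencies

        freqs = allele_frequencies(panel, [population])
    if ld is None:
        ld = compute_ld(panel, population, window_bp=window_bp, floor_r2=LONE_SITE_R2)
    elif ld.floor_r2 > LONE_SITE_R2 or ld.window_bp != window_bp:
        raise ValueError("LD store floor/window incompatible with lone-site detection")
    maf = freqs.maf(population)
    max_r2 = ld.max_r2_per_site()
    lone = (maf > polymorphism_floor) & (max_r2 <= LONE_SITE_R2)
    return np.flatnonzero(lone).tolist()


def dark_sites(
    lone: list[int],
    report: AccuracyReport,
    population: str,
    r2_acc_floor: float = 0.2,
    scaffold: ScaffoldDesign | frozenset[int] | None = None,
) -> list[int]:
    """Lone sites not recoverable by imputation either.

    A lone site is dark when its imputed-accuracy r² is below
    ``r2_acc_floor`` or undefined.  Lone sites that sit on the scaffold
    itself are genotyped directly and are excluded from consideration.
    """
    tag_set: frozenset[int] = frozenset()
    if scaffold is not None:
        tag_set = (
            scaffold.site_set if isinstance(scaffold, ScaffoldDesign) else frozenset(scaffold)
        )
    r2 = report.site_r2[population]
    out = []
    for s in lone:
        if s in tag_set:
            continue
        if np.isnan(r2[s]) or r2[s] < r2_acc_floor:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Ancestry-stratified accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncestryTract:
    """A haploid local-ancestry interval ([start, end) in bp and cM)."""

    individual: str
    haplotype: int  # 0 or 1
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    ancestry: str

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp or self.end_cm <= self.start_cm:
            raise ValueError("tract end must exceed start")
        if self.haplotype not in (0, 1):
            raise ValueError("haplotype index must be 0 or 1")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def read_tracts(path: str) -> list[AncestryTract]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual": str})
    return [
        AncestryTract(
            individual=r.individual,
            haplotype=int(r.hap),
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            start_cm=float(r.start_cm),
            end_cm=float(r.end_cm),
            ancestry=str(r.ancestry),
        )
        for r in df.itertuples()
    ]


def write_tracts(tracts: list[AncestryTract], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("individual\thap\tchrom\tstart_bp\tend_bp\tstart_cm\tend_cm\tancestry\n")
        for t in tracts:
            fh.write(
                f"{t.individual}\t{t.haplotype}\t{t.chrom}\t{t.start_bp}\t{t.end_bp}\t"
                f"{t.start_cm:.6g}\t{t.end_cm:.6g}\t{t.ancestry}\n"
            )


@dataclass
class AncestryAccuracy:
    site_r2: dict[tuple[str, str], np.ndarray]  # unordered diplotype -> per-site r²
    n_individuals: dict[tuple[str, str], int]
    bin_table: pd.DataFrame | None  # category, bin, mean_r2, n_sites
    dropped_categories: list[tuple[str, str]] = field(default_factory=list)


def ancestry_stratified_accuracy(
    dosages: DosageMatrix,
    panel: HaplotypePanel,
    tracts: list[AncestryTract],
    min_tract_cm: float = 20.0,
    min_individuals: int = 5,
    freqs: FrequencyTable | None = None,
    scheme: MAFBinScheme | None = None,
    population: str | None = None,
) -> AncestryAccuracy:
    """Imputation accuracy stratified by local-ancestry diplotype.

    Tracts shorter than ``min_tract_cm`` are dropped before assignment;
    an (individual, site) cell belongs to the unordered pair of ancestries
    of the two haploid tracts overlapping it, and is masked if either
    haplotype lacks a retained tract there.  Diplotype categories observed
    in fewer than ``min_individuals`` individuals are removed.  Per-site r²
    is computed within each category over its unmasked individuals; bin
    means use the stratified population's own MAF (``population`` defaults
    to the population of the tract-bearing individuals).
    """
    kept = [t for t in tracts if t.length_cm >= min_tract_cm]
    individuals = sorted({t.individual for t in tracts})
    sample_pos = {s: i for i, s in enumerate(dosages.sample_ids)}
    missing = [s for s in individuals if s not in sample_pos]
    if missing:
        raise ValueError(f"tract individuals absent from panel: {missing[:5]}")

    chroms = panel.chroms
    positions = panel.positions
    # per (individual, haplotype): ancestry label per site, None where uncovered
    labels: dict[tuple[str, int], np.ndarray] = {
        (s, h): np.full(panel.n_sites, None, dtype=object) for s in individuals for h in (0, 1)
    }
    for t in kept:
        sel = (chroms == t.chrom) & (positions >= t.start_bp) & (positions < t.end_bp)
        labels[(t.individual, t.haplotype)][sel] = t.ancestry

    # assign cells to unordered diplotype categories
    cat_cells: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for s in individuals:
        l0, l1 = labels[(s, 0)], labels[(s, 1)]
        both = (l0 != None) & (l1 != None)  # noqa: E711  (elementwise object compare)
        for j in np.flatnonzero(both):
            cat = tuple(sorted((l0[j], l1[j])))
            cat_cells.setdefault(cat, {}).setdefault(s, np.zeros(panel.n_sites, dtype=bool))[
                j
            ] = True

    truth = panel.genotypes().astype(np.float64)
    site_r2: dict[tuple[str, str], np.ndarray] = {}
    n_by_cat: dict[tuple[str, str], int] = {}
    dropped = []
    for cat in sorted(cat_cells):
        members = cat_cells[cat]
        n_by_cat[cat] = len(members)
        if len(members) < min_individuals:
            dropped.append(cat)
            continue
        r2 = np.full(panel.n_sites, np.nan)
        idx = np.array([sample_pos[s] for s in members], dtype=np.int64)
        mask = np.stack([members[s] for s in members])  # (n_members, n_sites)
        mask &= dosages.untyped[None, :]
        for j in np.flatnonzero(mask.any(axis=0)):
            rows = idx[mask[:, j]]
            if rows.size < 2:
                continue
            t_col = truth[rows, j][:, None]
            d_col = dosages.values[rows, j][:, None]
            r2[j] = _columnwise_r2(t_col, d_col)[0]
        site_r2[cat] = r2

    bin_table = None
    if freqs is not None:
        scheme = scheme or MAFBinScheme.fine()
        if population is None:
            pops = {panel.population_of[s] for s in individuals}
            if len(pops) != 1:
                raise ValueError("tract individuals span several populations; pass population=")
            population = pops.pop()
        bin_idx = scheme.assign(freqs.maf(population))
        rows = []
        for cat, r2 in site_r2.items():
            defined = ~np.isnan(r2)
            for b, label in enumerate(scheme.labels):
                sel = defined & (bin_idx == b)
                rows.append(
                    {
                        "category": "-".join(cat),
                        "bin": label,
                        "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
                        "n_sites": int(sel.sum()),
                    }
                )
        bin_table = pd.DataFrame(rows)

    return AncestryAccuracy(
        site_r2=site_r2,
        n_individuals={c: n for c, n in n_by_cat.items() if c not in dropped},
        bin_table=bin_table,
        dropped_categories=dropped,
    )
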