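"""Li–Stephens haploid imputation and leave-one-out scaffold evaluation.

Each phased study haplotype is modelled as an imperfect mosaic of the K
reference haplotypes.  The hidden state at every site is the reference
haplotype being copied; between adjacent sites separated by genetic
distance g (Morgans) the copying process switches to a uniformly chosen
haplotype with probability

    rho = 1 - exp(-4 * Ne * g / K),

and at genotyped (tag) sites the copied allele is observed with per-site
error ``mismatch_prob``.  Untyped sites emit nothing.  Because the
transition kernel is ``a*I + (1-a)/K * 11'`` and that family is closed
under products, chains of untyped sites collapse exactly: the forward–
backward recursion runs over tag sites only, and the *exact* marginal
posterior at any untyped site is recovered in closed form from the
flanking tag-site forward and backward vectors.  The expected alt-allele
dosage is the posterior-weighted mean of the reference alleles.

Scaffold evaluation is leave-one-out: each diploid individual is removed
from the panel, both of its haplotypes are imputed from the remainder
using only the scaffold sites as observations, and the summed haploid
dosages (in [0, 2]) are correlated with the true 0/1/2 genotypes per site
across individuals within each population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import MAFBinScheme
from .crosspop import ScaffoldDesign
from .panel import FrequencyTable, HaplotypePanel


@dataclass(frozen=True)
class HMMParams:
    """Copying-model parameters.

    mismatch_prob : allele-copying error per genotyped site, in (0, 0.5).
    ne            : effective population size scaling the switch rate.
    cm_per_mb     : constant recombination map used when no genetic map is
                    supplied (1 cM/Mb is the genome-wide human average).
    """

    mismatch_prob: float = 0.01
    ne: float = 1000.0
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.mismatch_prob < 0.5):
            raise ValueError("mismatch_prob must be in (0, 0.5)")
        if self.ne <= 0 or self.cm_per_mb <= 0:
            raise ValueError("ne and cm_per_mb must be positive")


def switch_probability(params: HMMParams, dist_morgan: float, k: int) -> float:
    """Probability of at least one copying switch across ``dist_morgan``."""
    return 1.0 - float(np.exp(-4.0 * params.ne * dist_morgan / k))


def genetic_positions_morgan(positions_bp: np.ndarray, params: HMMParams) -> np.ndarray:
    """Constant-rate map: bp → Morgans at ``cm_per_mb``."""
    return np.asarray(positions_bp, dtype=np.float64) * params.cm_per_mb * 1e-8


def haploid_posterior_dosage(
    tag_sites: np.ndarray,
    study_alleles: np.ndarray,
    ref_haps: np.ndarray,
    genetic_pos: np.ndarray,
    params: HMMParams,
    return_tag_posteriors: bool = False,
):
    """Expected alt allele in [0,1] at every site of one chromosome.

    Parameters
    ----------
    tag_sites : sorted indices (into the site axis) of genotyped sites.
    study_alleles : the study haplotype's {0,1} alleles at ``tag_sites``.
    ref_haps : (K, T) reference haplotype matrix over all T sites.
    genetic_pos : genetic position in Morgans for each of the T sites.

    Returns the length-T dosage vector (entries at tag sites are the
    model's reconstruction there); with ``return_tag_posteriors`` also the
    (m, K) state posteriors at the tag sites, each row summing to 1.
    """
    H = np.asarray(ref_haps, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("reference panel must be a non-empty (K, T) matrix")
    k, t = H.shape
    g = np.asarray(genetic_pos, dtype=np.float64)
    tag_sites = np.asarray(tag_sites, dtype=np.int64)
    m = tag_sites.size

    if m == 0:  # no observations: uniform posterior, dosage = panel frequency
        dosage = H.mean(axis=0)
        if return_tag_posteriors:
            return dosage, np.empty((0, k))
        return dosage

    mu = params.mismatch_prob
    c = 4.0 * params.ne / k  # switch-rate scale per Morgan
    gt = g[tag_sites]
    # emission matrix at tag sites: match -> 1-mu, mismatch -> mu
    E = np.where(H[:, tag_sites].T == np.asarray(study_alleles)[:, None], 1.0 - mu, mu)
    # no-switch probabilities across each inter-tag gap (exactly collapsed)
    A = np.exp(-c * np.diff(gt))

    # forward, normalized each step (constants cancel in every posterior)
    F = np.empty((m, k))
    f = E[0] / k
    F[0] = f / f.sum()
    for i in range(1, m):
        f = E[i] * (A[i - 1] * F[i - 1] + (1.0 - A[i - 1]) / k)
        F[i] = f / f.sum()

    # backward; Beta[i] = E[i] * b[i], normalized
    Beta = np.empty((m, k))
    Beta[m - 1] = E[m - 1] / E[m - 1].sum()
    for i in range(m - 2, -1, -1):
        bb = A[i] * Beta[i + 1] + (1.0 - A[i]) * Beta[i + 1].mean()
        bb = E[i] * bb
        Beta[i] = bb / bb.sum()

    dosage = np.empty(t)
    post_tags = np.empty((m, k)) if return_tag_posteriors else None
    for i in range(m):
        # posterior at tag i: F[i] already includes E[i]; Beta[i]/E[i] is b[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = F[i] * Beta[i] / E[i]
        p /= p.sum()
        dosage[tag_sites[i]] = p @ H[:, tag_sites[i]]
        if post_tags is not None:
            post_tags[i] = p

    # untyped sites: exact closed-form marginal from flanking tag vectors
    boundaries = np.concatenate(([-1], tag_sites, [t]))
    for gap in range(m + 1):
        lo = boundaries[gap] + 1
        hi = boundaries[gap + 1]
        if lo >= hi:
            continue
        sites = np.arange(lo, hi)
        Hb = H[:, sites]  # (K, n_gap)
        if gap == 0:
            # before the first tag: uniform prior on the left
            beta = Beta[0]
            ar = np.exp(-c * (gt[0] - g[sites]))
            num = ar * (beta @ Hb) + (1.0 - ar) * (beta.sum() / k) * Hb.sum(axis=0)
            den = np.full(sites.size, beta.sum())
        elif gap == m:
            # after the last tag: flat backward on the right
            f = F[m - 1]
            al = np.exp(-c * (g[sites] - gt[m - 1]))
            num = al * (f @ Hb) + (1.0 - al) * (f.sum() / k) * Hb.sum(axis=0)
            den = np.full(sites.size, f.sum())
        else:
            f = F[gap - 1]
            beta = Beta[gap]
            al = np.exp(-c * (g[sites] - gt[gap - 1]))
            ar = np.exp(-c * (gt[gap] - g[sites]))
            fb = f * beta
            S = f.sum()
            B = beta.sum()
            num = (
                al * ar * (fb @ Hb)
                + al * (1.0 - ar) * (B / k) * (f @ Hb)
                + (1.0 - al) * ar * (S / k) * (beta @ Hb)
                + (1.0 - al) * (1.0 - ar) * (S * B / k**2) * Hb.sum(axis=0)
            )
            den = (
                al * ar * fb.sum()
                + al * (1.0 - ar) * S * B / k
                + (1.0 - al) * ar * S * B / k
                + (1.0 - al) * (1.0 - ar) * S * B / k
            )
        dosage[sites] = num / den

    dosage = np.clip(dosage, 0.0, 1.0)
    if return_tag_posteriors:
        return dosage, post_tags
    return dosage


# ---------------------------------------------------------------------------
# Leave-one-out evaluation
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Imputed diploid dosages in [0, 2], one row per individual."""

    values: np.ndarray  # (n_samples, n_sites)
    untyped: np.ndarray  # bool per site: True where the site is not on the scaffold
    sample_ids: list[str]


@dataclass
class AccuracyReport:
    """Per-site squared dosage/truth correlation, per population."""

    site_r2: dict[str, np.ndarray]  # population -> (n_sites,), NaN where undefined
    n_individuals: dict[str, int]
    undefined_populations: list[str] = field(default_factory=list)


def _columnwise_r2(truth: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per column; NaN where either side is constant."""
    tc = truth - truth.mean(axis=0)
    dc = dosage - dosage.mean(axis=0)
    stt = (tc * tc).sum(axis=0)
    sdd = (dc * dc).sum(axis=0)
    std = (tc * dc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (std * std) / (stt * sdd)
    r2 = np.where((stt <= 0) | (sdd <= 0), np.nan, r2)
    return np.clip(r2, 0.0, 1.0)


def leave_one_out_evaluate(
    panel: HaplotypePanel,
    scaffold: ScaffoldDesign | frozenset[int],
    params: HMMParams | None = None,
    populations: list[str] | None = None,
    genetic_pos_morgan: np.ndarray | None = None,
) -> tuple[DosageMatrix, AccuracyReport]:
    """Impute every individual from the rest of the panel and score per site.

    Both haplotypes of the held-out individual are removed from the
    reference.  Accuracy is the per-site squared Pearson correlation of
    diploid dosage with the true genotype across a population's individuals;
    sites with zero truth or dosage variance are undefined (NaN), never 0.
    """
    params = params or HMMParams()
    tag_set = scaffold.site_set if isinstance(scaffold, ScaffoldDesign) else frozenset(scaffold)
    if populations is None:
        populations = panel.populations
    if genetic_pos_morgan is None:
        genetic_pos_morgan = genetic_positions_morgan(panel.positions, params)
    chroms = panel.chroms
    n = panel.n_samples
    dosage = np.empty((n, panel.n_sites))

    chrom_slices: list[tuple[np.ndarray, np.ndarray]] = []
    for chrom in dict.fromkeys(chroms.tolist()):
        sites = np.flatnonzero(chroms == chrom)
        local_tags = np.flatnonzero(np.isin(sites, sorted(tag_set)))
        chrom_slices.append((sites, local_tags))

    H_all = panel.haplotypes
    for i in range(n):
        keep = np.ones(2 * n, dtype=bool)
        keep[2 * i] = keep[2 * i + 1] = False
        ref = H_all[keep]
        if ref.shape[0] == 0:
            raise ValueError("leave-one-out needs at least two individuals")
        for sites, local_tags in chrom_slices:
            ref_c = ref[:, sites].astype(np.float64)  # convert once for both haplotypes
            g_c = genetic_pos_morgan[sites]
            d0 = haploid_posterior_dosage(
                local_tags, H_all[2 * i, sites[local_tags]], ref_c, g_c, params
            )
            d1 = haploid_posterior_dosage(
                local_tags, H_all[2 * i + 1, sites[local_tags]], ref_c, g_c, params
            )
            dosage[i, sites] = d0 + d1

    untyped = np.ones(panel.n_sites, dtype=bool)
    untyped[sorted(tag_set)] = False

    site_r2: dict[str, np.ndarray] = {}
    n_ind: dict[str, int] = {}
    undefined: list[str] = []
    truth_all = panel.genotypes()
    for pop in populations:
        idx = panel.sample_indices(pop)
        n_ind[pop] = idx.size
        if idx.size < 2:
            undefined.append(pop)
            site_r2[pop] = np.full(panel.n_sites, np.nan)
            continue
        r2 = _columnwise_r2(truth_all[idx].astype(np.float64), dosage[idx])
        r2[~untyped] = np.nan  # typed sites are not evaluated
        site_r2[pop] = r2

    return (
        DosageMatrix(values=dosage, untyped=untyped, sample_ids=list(panel.sample_ids)),
        AccuracyReport(site_r2=site_r2, n_individuals=n_ind, undefined_populations=undefined),
    )


@dataclass
class BinSummary:
    table: pd.DataFrame  # population, bin, mean_r2, n_sites
    n_excluded: dict[str, int]  # sites below the lowest bin edge, per population

    def mean_r2(self, population: str, bin_label: str) -> float:
        rows = self.table[
            (self.table["population"] == population) & (self.table["bin"] == bin_label)
        ]
        return float(rows["mean_r2"].iloc[0]) if len(rows) else float("nan")


def aggregate_by_bin(
    report: AccuracyReport,
    freqs: FrequencyTable,
    scheme: MAFBinScheme | None = None,
) -> BinSummary:
    """Unweighted mean of defined per-site r² within each population's MAF bins.

    Each site uses the population's *own* folded frequency; empty bins are
    reported with ``n_sites`` 0 and NaN mean rather than 0.
    """
    scheme = scheme or MAFBinScheme.fine()
    rows = []
    excluded: dict[str, int] = {}
    for pop, r2 in report.site_r2.items():
        maf = freqs.maf(pop)
        bin_idx = scheme.assign(maf)
        defined = ~np.isnan(r2)
        excluded[pop] = int((defined & (bin_idx < 0)).sum())
        for b, label in enumerate(scheme.labels):
            sel = defined & (bin_idx == b)
            rows.append(
                {
                    "population": pop,
                    "bin": label,
                    "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
                    "n_sites": int(sel.sum()),
                }
            )
    return BinSummary(table=pd.DataFrame(rows), n_excluded=excluded)
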