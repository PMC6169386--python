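"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (all-pairs
loops, recompute-everything greedy, exhaustive hidden-path enumeration) so
they stay independent of the vectorized implementations they check.
"""

from itertools import product

import numpy as np
import pytest

import tagscaffold as tsf
from tagscaffold.imputer import HMMParams, switch_probability

# conditions of the seeded end-to-end study: a three-way continental
# contrast plus an admixed group, all four treated as index populations
STUDY_SEED = 1
STUDY_POPS = ["POPA", "POPB", "POPC", "ADMIX"]
STUDY_MIN_MAF = 0.01
STUDY_MIN_R2 = 0.5
STUDY_N_TAGS = 400  # per 2 Mb ~ a 600k genome-wide array
STUDY_N_TAGS_DENSE = 800


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_ld(panel, population, window_bp, floor_r2):
    """All-pairs r² by the direct 2x2 haplotype-table formula."""
    rows = panel.haplotype_rows(population)
    H = panel.haplotypes[rows]
    pos = panel.positions
    chrom = panel.chroms
    pairs = {}
    for i in range(panel.n_sites):
        for j in range(i + 1, panel.n_sites):
            if chrom[i] != chrom[j] or pos[j] - pos[i] > window_bp:
                continue
            a, b = H[:, i], H[:, j]
            pa, pb = a.mean(), b.mean()
            denom = pa * (1 - pa) * pb * (1 - pb)
            if denom == 0:
                continue
            d = (a * b).mean() - pa * pb
            r2 = min(1.0, max(0.0, d * d / denom))
            if r2 >= floor_r2:
                pairs[(i, j)] = r2
    return pairs


def brute_force_greedy(edges, eligible, n_sites, max_tags=None):
    """Naive greedy: recompute every degree from scratch each step.

    ``edges`` is a set of (a, b) index pairs at or above the selection
    threshold; ``eligible`` a boolean per site.  Ties break to the smaller
    site index.  Returns [(site, n_partners, newly_tagged_set), ...].
    """
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    masked = set()
    out = []
    budget = float("inf") if max_tags is None else max_tags
    while len(out) < budget:
        best = None
        for s in range(n_sites):
            if s in masked or not eligible[s]:
                continue
            deg = len(adj.get(s, set()) - masked)
            if deg > 0 and (best is None or deg > best[1]):
                best = (s, deg)
        if best is None:
            break
        s, deg = best
        newly = adj[s] - masked
        out.append((s, deg, set(newly)))
        masked |= newly | {s}
    if max_tags is not None:
        for s in range(n_sites):
            if len(out) >= max_tags:
                break
            if eligible[s] and s not in masked:
                out.append((s, 0, set()))
                masked.add(s)
    return out


def enumerate_posterior_dosage(tag_sites, study, ref, genetic_pos, params: HMMParams):
    """Exhaustive hidden-path marginalization of the copying model."""
    H = np.asarray(ref, dtype=float)
    k, t = H.shape
    g = np.asarray(genetic_pos, dtype=float)
    tagpos = {int(s): i for i, s in enumerate(tag_sites)}
    mu = params.mismatch_prob
    post = np.zeros((t, k))
    total = 0.0
    for path in product(range(k), repeat=t):
        w = 1.0 / k
        for site in range(t):
            if site > 0:
                rho = switch_probability(params, g[site] - g[site - 1], k)
                w *= (1 - rho) + rho / k if path[site] == path[site - 1] else rho / k
            if site in tagpos:
                match = H[path[site], site] == study[tagpos[site]]
                w *= (1 - mu) if match else mu
        total += w
        for site in range(t):
            post[site, path[site]] += w
    post /= total
    return np.einsum("tk,kt->t", post, H), post


def pearson_r2(x, y):
    """Plain Pearson correlation squared, NaN when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x - x.mean()
    vy = y - y.mean()
    if (vx == 0).all() or (vy == 0).all():
        return float("nan")
    r = (vx * vy).sum() / np.sqrt((vx**2).sum() * (vy**2).sum())
    return r * r


def random_panel(rng, n_sites=30, n_samples=20, span_bp=2_000_000, populations=("POP1",)):
    """A random unstructured panel for oracle-equivalence tests."""
    from tagscaffold.panel import HaplotypePanel, Variant

    pos = np.sort(rng.choice(np.arange(1, span_bp), size=n_sites, replace=False))
    H = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.uint8)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    pop_of = {s: populations[i % len(populations)] for i, s in enumerate(sample_ids)}
    return HaplotypePanel(
        variants=[Variant("1", int(p), None, "A", "C") for p in pos],
        haplotypes=H,
        sample_ids=sample_ids,
        population_of=pop_of,
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study_panel():
    panel, tracts = tsf.simulate_panel(tsf.default_config(seed=STUDY_SEED))
    return panel, tracts


@pytest.fixture(scope="session")
def study_state(study_panel):
    """LD, frequencies, tag runs and both scaffold designs for the study panel."""
    panel, tracts = study_panel
    freqs = tsf.allele_frequencies(panel)
    ld = {p: tsf.compute_ld(panel, p) for p in STUDY_POPS}
    runs = {
        p: tsf.greedy_select(ld[p], freqs, min_maf=STUDY_MIN_MAF, min_r2=STUDY_MIN_R2)
        for p in STUDY_POPS
    }
    records = tsf.merge_population_runs(runs)
    alloc = tsf.allocate_per_chromosome(STUDY_N_TAGS, {"1": 2_000_000})
    alloc_dense = tsf.allocate_per_chromosome(STUDY_N_TAGS_DENSE, {"1": 2_000_000})
    designs = {
        "naive": tsf.build_scaffold(
            tsf.rank_naive(records), alloc, panel, "naive", STUDY_MIN_MAF, STUDY_MIN_R2
        ),
        "crosspop": tsf.build_scaffold(
            tsf.rank_crosspop(records), alloc, panel, "crosspop", STUDY_MIN_MAF, STUDY_MIN_R2
        ),
        "crosspop_dense": tsf.build_scaffold(
            tsf.rank_crosspop(records),
            alloc_dense,
            panel,
            "crosspop",
            STUDY_MIN_MAF,
            STUDY_MIN_R2,
        ),
    }
    return {
        "panel": panel,
        "tracts": tracts,
        "freqs": freqs,
        "ld": ld,
        "runs": runs,
        "records": records,
        "designs": designs,
    }


@pytest.fixture(scope="session")
def study_evaluations(study_state):
    """Leave-one-out accuracy for both designs plus the dense design.

    This is the expensive part of the suite (a few minutes); everything
    downstream shares it.
    """
    panel = study_state["panel"]
    params = tsf.HMMParams()
    out = {}
    for name in ("naive", "crosspop", "crosspop_dense"):
        dosages, report = tsf.leave_one_out_evaluate(
            panel, study_state["designs"][name], params, STUDY_POPS
        )
        out[name] = (dosages, report)
    return out
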