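# Methods

## Problem and overall procedure

`tagscaffold` designs and evaluates GWAS genotyping-array scaffolds for
multi-ethnic studies.  Arrays genotype a fixed budget of tag SNPs; every
other variant must be recovered by imputation against a sequenced
reference panel.  The package implements the full loop:

1. **Panel ingestion** — phased, complete, biallelic-SNP VCF into a
   haplotype matrix with per-population allele frequencies.
2. **LD scan** — per-population pairwise haplotype r² within a 1 Mb
   window, floored at 0.2.
3. **Greedy tagging** — per population, repeatedly select the site with
   the most not-yet-tagged LD partners at r² ≥ the selection threshold,
   masking the tag and its partners.
4. **Cross-population ranking** — merge per-population runs and rank
   candidates either naively (total unique sites tagged) or by
   cross-population prioritization (number of populations in which the
   tag is informative first, unique count second).
5. **Evaluation** — pairwise coverage *and* leave-one-out imputation
   accuracy under a Li–Stephens copying model, because pairwise metrics
   systematically misstate performance in low-LD, high-diversity
   populations.

## LD and tagging conventions

* r² is the gametic (phased-haplotype) r²: `D² / (p_a q_a p_b q_b)`.
  The input is phased, so no genotype-composite estimator is needed.
* Inclusive bounds everywhere: a pair at exactly the floor or exactly
  the window distance is kept; a tag needs MAF ≥ the tag floor.  The
  single deliberate exception is lone-site detection, which asks for the
  absence of any pair with r² **strictly** above 0.2, so a site whose
  best partner is exactly 0.2 is lone.
* Degree ties in the greedy loop break to the smaller (chrom, pos).  No
  published tie rule exists for this algorithm family; position order is
  deterministic and reproducible, which matters more than the choice
  itself.
* Degrees count only unmasked partners (residual degree), so each tag is
  scored against the variation still untagged.  Partners need not pass
  the tag MAF filter — a rare site can be tagged but never be a tag.
* When a finite budget outlives the LD graph, remaining slots are filled
  with zero-partner MAF-eligible sites in position order, so a requested
  allocation is met whenever the pool allows.
* Genome-wide budgets are split per chromosome proportionally to
  physical length with largest-remainder integerization (ties to the
  first-listed chromosome); counts sum exactly to the budget.
* `total_unique_tagged` is the size of the **union** of per-population
  newly-tagged sets, not their sum.

## The imputation model

Each phased study haplotype is a hidden mosaic of the K reference
haplotypes.  Between adjacent sites at genetic distance g Morgans the
copying process switches to a uniformly drawn haplotype with probability
`rho = 1 - exp(-4 Ne g / K)`; at genotyped sites the copied allele is
read with error `mismatch_prob`; untyped sites emit nothing.  Posterior
state probabilities give the expected alt dosage per site (haploid in
[0, 1]; the two haploid dosages sum to the diploid dosage in [0, 2]).

Because the transition kernel `a·I + (1-a)/K·11ᵀ` is closed under
products (`a` multiplies across gaps), runs of untyped sites collapse
exactly: forward–backward runs over tag sites only, and the marginal
posterior at any untyped site is recovered in closed form from the
flanking tag-site vectors.  This is an *exact* marginalization, not an
interpolation; it agrees with exhaustive hidden-path enumeration to
1e-9 in the test suite, and costs O(K) per site.

Parameters (all overridable):

| parameter       | default | meaning |
|-----------------|---------|---------|
| `mismatch_prob` | 0.01    | allele-copying error per genotyped site; must lie in (0, 0.5) |
| `ne`            | 1000    | effective-size scale of the switch rate, the conventional order for sequence-panel imputation |
| `cm_per_mb`     | 1.0     | constant map used when no genetic map is supplied (genome-wide human average) |

Doubling all physical distances while halving the map rate leaves every
posterior unchanged (tested), so only genetic distance matters.

## Scoring

* Leave-one-out: each diploid is removed from the reference (both
  haplotypes), its scaffold genotypes are kept, and everything else is
  imputed from the remaining panel.
* Accuracy is the squared Pearson correlation between diploid dosage and
  true 0/1/2 genotype per site across a population's individuals, then
  the unweighted mean over sites within a MAF bin.  Sites with zero
  truth or dosage variance are undefined (never 0) and excluded from bin
  means; populations with fewer than two individuals are flagged.
* MAF bins are population-specific, half-open (lo, hi]: ten fine bins
  from 0.005 to 0.5 (the (0.02, 0.03] bin is included; published listings
  of this scheme sometimes omit it while calling it ten bins, which we
  treat as a typo) and broad rare (≤1%) / low (1–5%) / common (5–50%)
  merges.  Sites at or below MAF 0.005 are excluded and tallied.
* Coverage: fraction of untyped polymorphic (MAF > 0.5%) sites with at
  least one scaffold partner at r² ≥ threshold.  Scaffold sites are
  neither covered nor uncovered.
* Informativeness: a tag segregates (MAF > 0.5%) and has ≥ 1 untyped
  partner at r² ≥ 0.5 in the population.
* Dark sites: lone sites whose imputed accuracy is below 0.2 or
  undefined.  Lone sites that sit on the scaffold are excluded — they
  are genotyped directly, hence trivially recovered.
* Ancestry stratification: cells (individual, site) take the unordered
  pair of the two haploid local-ancestry labels.  Tracts shorter than
  20 cM are dropped (their cells masked, never reassigned), and
  diplotype categories seen in fewer than 5 individuals are removed —
  both thresholds are tuned to genome-scale tract inference and should
  be relaxed on small simulated regions (the bundled 2 Mb study uses
  1 cM; truth tracts need no inference-accuracy guard).

## The synthetic panel

`simulate_panel` runs msprime under a Gravel-style out-of-Africa
history: POPA constant-size and high-diversity (African-like, Ne 14474
with an ancestral change to 7310), POPB a tight bottleneck (Ne 550 at
the split) followed by fast exponential growth (East-Asian-like, the
rare-variant-excess regime), POPC a moderate bottleneck plus growth
(European-like), and an 80/20 POPA/POPC admixed population formed 8
generations ago.  Defaults: 60 diploids per source population, 40
admixed, 2 Mb at mutation rate 1.25e-8 and recombination 1e-8 —
roughly 9k segregating sites, small enough that a full leave-one-out
evaluation of a design finishes in well under a minute per scaffold.

The admixed haplotypes are built as tract mosaics over extra donor
haplotypes simulated in the source populations (donors are excluded from
the emitted panel): switch points follow a Poisson process at
`generations_ago` per Morgan, each segment copies one donor, and
adjacent same-ancestry segments are merged so the recorded tract truth
tiles every admixed haplotype exactly.  This gives exact, deterministic
tract truth without local-ancestry inference.

Scaffold budgets for the bundled study are 400 tags per 2 Mb
(≈ 600k genome-wide equivalent) and 800 for the density comparison —
inside the 250k–2M range spanned by commercial arrays.

What the generator does **not** emulate: genotyping error and
missingness, strand/ascertainment artifacts, gene conversion, selection,
X/Y ploidy, multi-chromosome structure, and reference panels much larger
than the study sample.  Passing tests therefore demonstrate correctness
of the algorithms and the direction of demography-driven contrasts, not
calibrated accuracy percentages for any real array.

Hand-built `deterministic_fixture` panels (chain, star, two-pop-shared,
lone-site, admixed-toy) carry exactly known LD values for exact-value
tests; the admixed toy fabricates an 80 cM region so the 20 cM tract
filter and 5-individual category filter are exercisable.

## Numerical choices and degenerate inputs

* r² is clamped to [0, 1] after computation; monomorphic columns raise
  rather than return a value.
* Forward and backward vectors are renormalized every tag step;
  normalization constants cancel in all posteriors.
* With zero tag sites the posterior is uniform and dosage equals the
  reference allele frequency.
* Empty bins are reported as empty (NaN mean, n = 0), never as 0.
* All stages are deterministic given config + seed; report files are
  byte-identical across reruns (tested).

## Known limitations

* The greedy tagger is the classic masking heuristic, not an optimal
  set-cover solver; its output is the algorithm's, not the optimum.
* The copying model has no reference-haplotype clustering, so cost grows
  linearly in panel size; it is meant for panels of hundreds to a few
  thousand haplotypes per run, with per-chromosome parallelism handled
  outside the CLI.
* Per-site accuracy across individuals is the chosen aggregation; a
  per-individual aggregation would weight sites differently and is not
  provided.
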