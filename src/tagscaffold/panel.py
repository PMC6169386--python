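"""Phased haplotype panels: VCF input, sample/variant filters, allele frequencies.

The in-memory substrate for the whole package is a :class:`HaplotypePanel` —
a dense {0,1} matrix with two rows per diploid sample (phased haplotypes in
sample order) and one column per biallelic SNP, plus per-site metadata and a
sample→population map.  Input must be phased and complete: the intended data
source is a sequenced reference panel (e.g. 1000 Genomes Phase 3 style VCFs),
not array genotypes with missingness.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np


class PanelError(ValueError):
    """Malformed or contract-violating panel input."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.  ``pos`` is 1-based, as in VCF."""

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise PanelError(
                f"{self.chrom}:{self.pos} is not a SNP (ref={self.ref!r}, alt={self.alt!r})"
            )
        if self.pos < 1:
            raise PanelError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class HaplotypePanel:
    """Phased biallelic panel: (2 * n_samples) x n_sites allele matrix.

    Rows ``2*i`` and ``2*i + 1`` are the two haplotypes of ``sample_ids[i]``.
    Sites are sorted by (chrom, pos); every sample carries a population label.
    """

    variants: list[Variant]
    haplotypes: np.ndarray  # uint8, shape (2 * n_samples, n_sites)
    sample_ids: list[str]
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotype matrix must be 2-D")
        n_rows, n_sites = self.haplotypes.shape
        if n_rows != 2 * len(self.sample_ids):
            raise PanelError(
                f"matrix has {n_rows} rows for {len(self.sample_ids)} samples "
                "(need exactly two haplotypes per sample)"
            )
        if n_sites != len(self.variants):
            raise PanelError("matrix columns do not match variant count")
        if self.haplotypes.size and self.haplotypes.max(initial=0) > 1:
            raise PanelError("alleles must be 0/1")
        missing = [s for s in self.sample_ids if s not in self.population_of]
        if missing:
            raise PanelError(f"samples without population label: {missing[:5]}")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise PanelError("duplicate (chrom, pos, ref, alt) records in panel")
        order = sorted(range(len(keys)), key=lambda i: (keys[i][0], keys[i][1]))
        if order != list(range(len(keys))):
            raise PanelError("variants must be sorted by (chrom, pos)")

    # -- basic views ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        """Diploid sample indices belonging to ``population``."""
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of[s] == population]
        if not idx:
            raise PanelError(f"unknown or empty population {population!r}")
        return np.array(idx, dtype=np.int64)

    def haplotype_rows(self, population: str) -> np.ndarray:
        """Haplotype row indices (2 per sample) for ``population``."""
        samples = self.sample_indices(population)
        return np.stack([2 * samples, 2 * samples + 1], axis=1).reshape(-1)

    def genotypes(self, samples: np.ndarray | None = None) -> np.ndarray:
        """Diploid 0/1/2 genotype matrix (n_samples x n_sites)."""
        h = self.haplotypes
        g = h[0::2].astype(np.int16) + h[1::2]
        return g if samples is None else g[samples]


@dataclass
class FrequencyTable:
    """Per-population alternate-allele frequencies and folded MAF per site."""

    alt_freq: dict[str, np.ndarray] = field(default_factory=dict)

    def populations(self) -> list[str]:
        return list(self.alt_freq)

    def freq(self, population: str) -> np.ndarray:
        try:
            return self.alt_freq[population]
        except KeyError:
            raise PanelError(f"no frequencies for population {population!r}") from None

    def maf(self, population: str) -> np.ndarray:
        f = self.freq(population)
        return np.minimum(f, 1.0 - f)


def allele_frequencies(panel: HaplotypePanel, populations: list[str] | None = None) -> FrequencyTable:
    """Alt-allele frequency per site within each population's haplotypes."""
    if populations is None:
        populations = panel.populations
    table = FrequencyTable()
    for pop in populations:
        rows = panel.haplotype_rows(pop)  # raises on unknown population
        table.alt_freq[pop] = panel.haplotypes[rows].mean(axis=0)
    return table


# ---------------------------------------------------------------------------
# VCF / manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str) -> dict[str, str]:
    """Read a sample→population TSV with header ``sample_id<TAB>population``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise PanelError(
            f"manifest must have header 'sample_id\\tpopulation', got {list(df.columns)}"
        )
    return dict(zip(df["sample_id"], df["population"]))


def read_exclusions(path: str | None) -> set[str]:
    if path is None:
        return set()
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def load_phased_vcf(
    vcf_path: str,
    manifest: str | dict[str, str],
    exclusions: str | set[str] | None = None,
) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a :class:`HaplotypePanel`.

    Multiallelic and non-SNP records are dropped.  Samples on the exclusion
    list are removed; every retained sample must appear in the manifest.
    Unphased or missing genotypes are an error — the contract is a complete,
    phased reference panel.
    """
    from cyvcf2 import VCF

    pop_of = manifest if isinstance(manifest, dict) else read_manifest(manifest)
    excl = exclusions if isinstance(exclusions, set) else read_exclusions(exclusions)

    vcf = VCF(vcf_path)
    retained = [s for s in vcf.samples if s not in excl]
    unknown = [s for s in retained if s not in pop_of]
    if unknown:
        raise PanelError(f"samples in VCF but not in manifest: {unknown[:5]}")
    if not retained:
        raise PanelError("no samples retained after exclusions")
    vcf.set_samples(retained)

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    seen: set[tuple[str, int, str, str]] = set()
    last: tuple[str, int] | None = None
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # multiallelic or non-SNP: dropped, not split
        v = Variant(rec.CHROM, rec.POS, rec.ID, rec.REF, rec.ALT[0])
        if v.key in seen:
            raise PanelError(f"duplicate record {v.chrom}:{v.pos} {v.ref}>{v.alt}")
        seen.add(v.key)
        if last is not None and last[0] == v.chrom and v.pos < last[1]:
            raise PanelError(f"VCF not coordinate-sorted at {v.chrom}:{v.pos}")
        last = (v.chrom, v.pos)
        gt = rec.genotype.array()  # (n_samples, 3): allele_a, allele_b, phased flag
        if (gt[:, :2] < 0).any():
            raise PanelError(f"missing genotype at {v.chrom}:{v.pos}")
        if not gt[:, 2].all():
            bad = retained[int(np.flatnonzero(~gt[:, 2].astype(bool))[0])]
            raise PanelError(f"unphased genotype for sample {bad} at {v.chrom}:{v.pos}")
        variants.append(v)
        columns.append(gt[:, :2].astype(np.uint8).reshape(-1))
    vcf.close()

    hap = (
        np.array(columns, dtype=np.uint8).T
        if columns
        else np.zeros((2 * len(retained), 0), dtype=np.uint8)
    )
    return HaplotypePanel(
        variants=variants,
        haplotypes=hap,
        sample_ids=list(retained),
        population_of={s: pop_of[s] for s in retained},
    )


def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Export a panel as a minimal phased VCF v4.1 text file."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.1\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(panel.sample_ids) + "\n")
    h = panel.haplotypes
    for j, v in enumerate(panel.variants):
        gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(panel.n_samples))
        buf.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_manifest(panel: HaplotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in panel.sample_ids:
            fh.write(f"{s}\t{panel.population_of[s]}\n")
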