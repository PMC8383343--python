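"""Synthetic cohort generator with known truth.

Builds every input the pipeline consumes — reference FASTA, GTF gene
models, multi-sample case VCFs, control allele-count tables, genotype-count
tables and an ortholog map — from a single seeded random generator, with a
truth record for every planted variant.  The generator emulates the shape
of the study data this kind of analysis runs on: multi-exon transcripts
with a pure 3'UTR exon (so splice variants in non-coding exons are
plantable), PTVs of every category, Hardy-Weinberg case genotypes at a
configurable odds ratio against control allele frequencies, and
EVS-style control tables with large allele numbers.

Case genotypes at frequency f are Binomial(2, f) per sample — exactly the
Hardy-Weinberg genotype distribution.  Planted case frequencies derive from
the control frequency through the odds transform, so the configured odds
ratio is the true allelic odds ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_models import (
    GenomeReference,
    Transcript,
    reverse_complement,
    write_transcripts,
)

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults describe a scaled cohort: 12 genes (one gene family), 200
    cases, controls published as allele counts with an EVS-scale allele
    number, planted PTVs at 0.5% control frequency (rare under the 1%
    filter) and an allelic odds ratio of 5.
    """

    seed: int = 0
    n_genes: int = 12
    codons_per_gene: int = 60  # incl. start and stop codons
    utr5_len: int = 30
    utr3_tail_len: int = 40  # 3'UTR bases on the last coding exon (c.*1..*40)
    utr3_exon_len: int = 60  # the pure non-coding 3'UTR exon
    intron_len: int = 90
    pad_len: int = 50
    n_case_samples: int = 200
    control_allele_number: dict = field(default_factory=lambda: {"EA": 8600, "AA": 4406})
    control_freq: float = 0.005
    odds_ratio: float = 5.0
    categories: tuple = (
        "stop_gain",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
        "splice_noncoding_exon",
    )
    ortholog_fraction: float = 1 / 3  # genes given a target-species ortholog
    n_shared: int = 0  # variants forced present in every case (pedigree mode)

    def __post_init__(self) -> None:
        if not 0.0 <= self.control_freq < 1.0:
            raise SimulationError("control_freq must lie in [0, 1)")
        if self.odds_ratio <= 0:
            raise SimulationError("odds_ratio must be positive")
        if self.codons_per_gene < 12:
            raise SimulationError("codons_per_gene too small to plant variants")
        if self.intron_len < 10 or self.utr3_tail_len < 3 or self.utr5_len < 1:
            raise SimulationError("exon/intron layout too small for planting")


def expected_case_frequency(f_control: float, odds_ratio: float) -> float:
    """Case allele frequency implied by a control frequency and an allelic
    odds ratio: odds_case = OR * f/(1-f), f_case = odds/(1+odds)."""
    if not 0.0 < f_control < 1.0:
        raise SimulationError("f_control must lie in (0, 1)")
    if odds_ratio <= 0:
        raise SimulationError("odds_ratio must be positive")
    odds = odds_ratio * f_control / (1.0 - f_control)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted variant."""

    key: str  # contig:pos:ref:alt (genomic, VCF-style)
    gene: str
    category: str
    hgvs_c: str
    hgvs_p: str | None
    f_control: float
    f_case: float
    shared: bool = False


@dataclass
class PlantedSite:
    """A plantable variant position designed into a gene."""

    category: str
    gpos: int  # 1-based
    ref: str  # genomic-strand alleles
    alt: str
    hgvs_c: str
    hgvs_p: str | None = None


# ---------------------------------------------------------------------------
# gene models


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, codons: int) -> str:
    body = rng.choice(_NON_STOP_CODONS, size=codons - 2)
    return "ATG" + "".join(body) + "TAA"


def simulate_gene_models(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeReference, list[Transcript], dict[str, list[PlantedSite]]]:
    """Generate one four-exon gene per contig, alternating strands.

    Exon layout in transcript order: [5'UTR + CDS part 1] [CDS part 2]
    [CDS part 3 + 3'UTR tail] [pure 3'UTR exon].  Introns carry canonical
    GT..AG splice dinucleotides.  Each gene carries one designed plantable
    site per configured PTV category, reported as genomic-strand alleles.
    """
    contigs: dict[str, str] = {}
    transcripts: list[Transcript] = []
    sites: dict[str, list[PlantedSite]] = {}

    for k in range(cfg.n_genes):
        gene = f"GENE{k + 1}"
        contig = f"ctg{k + 1}"
        strand = "+" if k % 2 == 0 else "-"
        cds = _random_cds(rng, cfg.codons_per_gene)
        L = len(cds)

        # reserve a TAC (Tyr) codon for the stop-gain plant
        q = int(rng.integers(3, cfg.codons_per_gene - 2))  # 1-based codon index
        cds = cds[: 3 * (q - 1)] + "TAC" + cds[3 * q :]

        utr5 = _random_seq(rng, cfg.utr5_len)
        utr3a = _random_seq(rng, cfg.utr3_tail_len)
        utr3b = _random_seq(rng, cfg.utr3_exon_len)
        c1, c2 = L // 3, L // 3
        c3 = L - c1 - c2

        exon_ts = [utr5 + cds[:c1], cds[c1 : c1 + c2], cds[c1 + c2 :] + utr3a, utr3b]
        introns = [
            "GT" + _random_seq(rng, cfg.intron_len - 4) + "AG" for _ in range(3)
        ]
        pad5, pad3 = _random_seq(rng, cfg.pad_len), _random_seq(rng, cfg.pad_len)

        locus = pad5
        exon_locus: list[tuple[int, int]] = []  # 0-based half-open, transcript order
        for i, ex in enumerate(exon_ts):
            exon_locus.append((len(locus), len(locus) + len(ex)))
            locus += ex
            if i < len(introns):
                locus += introns[i]
        locus += pad3
        cds_lo_t = exon_locus[0][0] + cfg.utr5_len  # locus coord of CDS start
        # locus coords of CDS end: last CDS base is in exon 3
        cds_hi_t = exon_locus[2][0] + c3  # half-open end within locus

        M = len(locus)
        if strand == "+":
            contigs[contig] = locus
            exons = exon_locus
            cds_start, cds_end = cds_lo_t, cds_hi_t
        else:
            contigs[contig] = reverse_complement(locus)
            exons = [(M - e, M - s) for s, e in exon_locus]  # transcript order kept
            cds_start, cds_end = M - cds_hi_t, M - cds_lo_t

        transcripts.append(
            Transcript(
                id=f"TX{k + 1}",
                gene=gene,
                contig=contig,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )

        # ---- plantable sites (locus coords first, then mirrored if minus)
        gene_sites: list[PlantedSite] = []

        def locus_to_gpos(t: int) -> int:
            """1-based genomic position of locus index t."""
            return t + 1 if strand == "+" else M - t

        def strand_allele(b: str) -> str:
            return b if strand == "+" else reverse_complement(b)

        def add_snv(category, t_locus, ref_t, alt_t, hgvs_c, hgvs_p=None):
            assert locus[t_locus] == ref_t, (gene, category, locus[t_locus], ref_t)
            gene_sites.append(
                PlantedSite(
                    category=category,
                    gpos=locus_to_gpos(t_locus),
                    ref=strand_allele(ref_t),
                    alt=strand_allele(alt_t),
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                )
            )

        if "stop_gain" in cfg.categories:
            # third base of the reserved TAC codon: TAC -> TAA
            t = _locus_coding_index(exon_locus, cfg.utr5_len, c1, c2, 3 * q - 1)
            add_snv("stop_gain", t, "C", "A", f"c.{3 * q}C>A", f"p.(Tyr{q}*)")

        if "frameshift" in cfg.categories:
            cb = _find_dup_site(cds, lo=4, hi=L - 4)
            t = _locus_coding_index(exon_locus, cfg.utr5_len, c1, c2, cb - 1)
            base = cds[cb - 1]
            # anchored single-base duplication in transcript orientation; the
            # next transcript base differs, so the placement is already 3'-most
            if strand == "+":
                gpos, ref, alt = t + 1, base, base + base
            else:
                g0 = M - 2 - t  # genomic base just below the insertion point
                anchor_base = contigs[contig][g0]
                gpos, ref, alt = g0 + 1, anchor_base, anchor_base + reverse_complement(base)
            gene_sites.append(
                PlantedSite(
                    category="frameshift",
                    gpos=gpos,
                    ref=ref,
                    alt=alt,
                    hgvs_c=f"c.{cb}dup{base}",
                    hgvs_p=None,
                )
            )

        if "splice_donor" in cfg.categories:
            # +2 of the intron after exon 2 (fully coding): anchor c.(c1+c2)
            t = exon_locus[1][1] + 1  # second intron base, the T of GT
            add_snv("splice_donor", t, "T", "G", f"c.{c1 + c2}+2T>G")

        if "splice_acceptor" in cfg.categories:
            # -2 before exon 3 (first base coding): anchor c.(c1+c2+1)
            t = exon_locus[2][0] - 2  # the A of AG
            add_snv("splice_acceptor", t, "A", "C", f"c.{c1 + c2 + 1}-2A>C")

        if "splice_noncoding_exon" in cfg.categories:
            # +2 of the intron after exon 3, anchored at the 3'UTR tail base
            t = exon_locus[2][1] + 1
            add_snv(
                "splice_noncoding_exon", t, "T", "G", f"c.*{cfg.utr3_tail_len}+2T>G"
            )

        sites[gene] = gene_sites

    return GenomeReference(contigs), transcripts, sites


def _locus_coding_index(exon_locus, utr5_len: int, c1: int, c2: int, ci: int) -> int:
    """Locus coordinate of 0-based coding index ci (transcript orientation)."""
    if ci < c1:
        return exon_locus[0][0] + utr5_len + ci
    if ci < c1 + c2:
        return exon_locus[1][0] + (ci - c1)
    return exon_locus[2][0] + (ci - c1 - c2)


def _find_dup_site(cds: str, lo: int, hi: int) -> int:
    """A 1-based coding base whose following base differs (so its single-base
    duplication is already 3'-most) strictly inside (lo, hi)."""
    for cb in range(lo, hi):
        if cds[cb - 1] != cds[cb]:
            return cb
    raise SimulationError("no duplication site found (homopolymer CDS?)")


# ---------------------------------------------------------------------------
# cohorts


def draw_case_genotypes(
    f: float, n_samples: int, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Hardy-Weinberg genotype dosages: Binomial(2, f) per sample.

    Returns an array of shape (size, n_samples) with entries 0/1/2.
    """
    return rng.binomial(2, f, size=(size, n_samples))


def simulate_cohort(
    truth_sites: dict[str, list[PlantedSite]],
    transcripts: list[Transcript],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TruthRecord], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw case genotypes and control allele counts for every planted site.

    Returns ``(truth, case_genotypes, control_table, genotype_counts)``:
    ``case_genotypes`` has one row per variant with per-sample dosages in
    order; ``control_table`` is the EVS-style per-population allele-count
    table; ``genotype_counts`` tallies case and (simulated) control cohorts
    per variant in the genotype-count report shape.
    """
    contig_of = {tx.gene: tx.contig for tx in transcripts}
    f_case = expected_case_frequency(cfg.control_freq, cfg.odds_ratio)

    truth: list[TruthRecord] = []
    geno_rows = []
    control_rows = []
    count_rows = []
    shared_budget = cfg.n_shared

    for gene in sorted(truth_sites, key=lambda g: int(g.replace("GENE", ""))):
        for site in truth_sites[gene]:
            key = f"{contig_of[gene]}:{site.gpos}:{site.ref}:{site.alt}"
            shared = shared_budget > 0
            if shared:
                shared_budget -= 1
                # forced carrier in every case (pedigree-style shared variant)
                g = 1 + rng.binomial(1, f_case, size=cfg.n_case_samples)
            else:
                g = draw_case_genotypes(f_case, cfg.n_case_samples, rng)[0]
            truth.append(
                TruthRecord(
                    key=key,
                    gene=gene,
                    category=site.category,
                    hgvs_c=site.hgvs_c,
                    hgvs_p=site.hgvs_p,
                    f_control=cfg.control_freq,
                    f_case=f_case,
                    shared=shared,
                )
            )
            geno_rows.append({"variant": key, "gene": gene, "genotypes": g})
            for pop, an in cfg.control_allele_number.items():
                alt = int(rng.binomial(an, cfg.control_freq))
                control_rows.append(
                    {
                        "variant": key,
                        "population": pop,
                        "alt_count": alt,
                        "allele_number": an,
                    }
                )
            count_rows.append(
                {
                    "variant": key,
                    "cohort": "cases",
                    "label": "cases",
                    "n": cfg.n_case_samples,
                    "hom_alt": int((g == 2).sum()),
                    "het": int((g == 1).sum()),
                }
            )

    case_genotypes = pd.DataFrame(geno_rows)
    control_table = pd.DataFrame(control_rows)
    genotype_counts = pd.DataFrame(count_rows)
    return truth, case_genotypes, control_table, genotype_counts


# ---------------------------------------------------------------------------
# writers


def write_vcf(
    path,
    reference: GenomeReference,
    case_genotypes: pd.DataFrame,
    seed: int,
    sample_prefix: str = "case",
) -> None:
    """Write a VCF 4.2 with GT genotypes, deterministically ordered."""
    n_samples = len(case_genotypes.iloc[0]["genotypes"]) if len(case_genotypes) else 0
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}

    def sort_key(row):
        contig, pos, _, _ = row["variant"].split(":", 3)
        return (contig, int(pos))

    rows = sorted((r for _, r in case_genotypes.iterrows()), key=sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ptvburden-simulator\n##ptvburden_seed={seed}\n")
        for name, seq in reference.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for row in rows:
            contig, pos, ref, alt = row["variant"].split(":", 3)
            gts = "\t".join(gt_str[int(g)] for g in row["genotypes"])
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_truth(path, truth: list[TruthRecord], cfg: SimulationConfig) -> None:
    payload = {
        "config": {**asdict(cfg), "categories": list(cfg.categories)},
        "variants": [asdict(t) for t in truth],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> tuple[dict, list[TruthRecord]]:
    with open(path) as fh:
        payload = json.load(fh)
    return payload["config"], [TruthRecord(**v) for v in payload["variants"]]


def write_ortholog_map(path, genes: list[str], fraction: float) -> None:
    """First ``fraction`` of the gene list gets a target-species ortholog."""
    n_mapped = int(round(fraction * len(genes)))
    with open(path, "w") as fh:
        for i, g in enumerate(genes):
            tgt = f"HS_{g}" if i < n_mapped else "NONE"
            fh.write(f"{g}\t{tgt}\n")


def simulate_bundle(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the full input bundle; returns the file paths.

    All randomness flows through one generator seeded with ``cfg.seed``;
    rerunning with the same config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    reference, transcripts, sites = simulate_gene_models(cfg, rng)
    truth, case_geno, controls, counts = simulate_cohort(sites, transcripts, cfg, rng)

    paths = {
        "reference": outdir / "reference.fa",
        "transcripts": outdir / "transcripts.gtf",
        "vcf": outdir / "cases.vcf",
        "controls": outdir / "controls.tsv",
        "genotype_counts": outdir / "genotype_counts.tsv",
        "ortholog_map": outdir / "ortholog_map.tsv",
        "truth": outdir / "truth.json",
    }
    reference.to_fasta(paths["reference"])
    write_transcripts(transcripts, paths["transcripts"])
    write_vcf(paths["vcf"], reference, case_geno, cfg.seed)
    controls.to_csv(paths["controls"], sep="\t", index=False)
    counts.to_csv(paths["genotype_counts"], sep="\t", index=False)
    write_ortholog_map(paths["ortholog_map"], [tx.gene for tx in transcripts],
                       cfg.ortholog_fraction)
    write_truth(paths["truth"], truth, cfg)
    return paths
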