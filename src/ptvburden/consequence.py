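"""Protein-truncating-variant classification and HGVS naming.

A PTV here is a stop-gain SNV, a frameshifting indel, or a variant that
abrogates a splice site (the two essential intronic bases, +1/+2 donor or
-1/-2 acceptor).  Splice variants whose anchored exon-edge base lies in the
UTR are reported as their own category (``splice_noncoding_exon``): they do
not truncate the protein but are counted among PTVs in burden tallies.

HGVS cDNA names are emitted for every classified variant; protein-level
names only for stop gains and frameshifts, where the effect is recomputed
from the coding sequence (first changed residue and the new-frame stop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pysam
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_models import (
    CdnaCoord,
    GenomeReference,
    OutOfRangeError,
    STOP_CODONS,
    Transcript,
    _exonic_coord,
    map_genomic_to_cdna,
    reverse_complement,
    spliced_sequence,
)

logger = logging.getLogger(__name__)

PTV_CATEGORIES = frozenset(
    {"stop_gain", "frameshift", "splice_donor", "splice_acceptor", "splice_noncoding_exon"}
)

_SPLICE_REACH = 2  # essential splice bases only: +-1/+-2


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """A normalized small variant in reference coordinates (VCF-style).

    ``pos`` is the 1-based position of the first reference base; indels are
    anchored (ref and alt share their first base).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VariantError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise VariantError("ref and alt are identical")
        if any(c not in "ACGTN" for c in self.ref + self.alt):
            raise VariantError(f"non-nucleotide allele in {self.ref}>{self.alt}")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def check_reference(self, ref: GenomeReference) -> None:
        obs = ref.fetch(self.contig, self.pos - 1, self.pos - 1 + len(self.ref))
        if obs != self.ref:
            raise VariantError(
                f"{self.key}: REF does not match reference ({obs!r} observed)"
            )


@dataclass(frozen=True)
class Consequence:
    """Classification of one variant against one transcript."""

    category: str
    transcript_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str | None = None

    @property
    def is_ptv(self) -> bool:
        return self.category in PTV_CATEGORIES


def is_ptv(c: Consequence) -> bool:
    """True iff the consequence belongs to one of the five PTV categories."""
    return c.is_ptv


# ---------------------------------------------------------------------------
# 3' normalization


def normalize_3prime(v: VariantRecord, tx: Transcript, ref: GenomeReference) -> VariantRecord:
    """Shift an anchored insertion/deletion to its 3'-most equivalent
    placement in *transcript* orientation; SNVs and non-shiftable variants
    are returned unchanged.  Idempotent."""
    if v.is_snv or v.contig != tx.contig:
        return v
    if len(v.ref) == 1 and v.alt[0] == v.ref[0]:
        seq, is_ins = v.alt[1:], True
    elif len(v.alt) == 1 and v.ref[0] == v.alt[0]:
        seq, is_ins = v.ref[1:], False
    else:
        return v  # complex substitution: not shiftable by rotation

    contig = ref.contigs[v.contig]
    anchor = v.pos - 1  # 0-based anchor base

    if tx.strand == "+":
        while True:
            nxt = anchor + 1 if is_ins else anchor + 1 + len(seq)
            if nxt >= len(contig) or contig[nxt] != seq[0]:
                break
            seq = seq[1:] + seq[0]
            anchor += 1
    else:
        # 3'-most in transcript orientation = leftmost genomic placement
        while True:
            if anchor - 1 < 0 or contig[anchor] != seq[-1]:
                break
            seq = seq[-1] + seq[:-1]
            anchor -= 1

    base = contig[anchor]
    if is_ins:
        return replace(v, pos=anchor + 1, ref=base, alt=base + seq)
    return replace(v, pos=anchor + 1, ref=base + seq, alt=base)


# ---------------------------------------------------------------------------
# translation helpers


def _translate(seq: str) -> str:
    """Translate up to (and excluding) the first stop; '*' appended if a
    stop was reached."""
    prot = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            prot.append("*")
            break
        prot.append(str(Seq(codon).translate()))
    return "".join(prot)


def _aa_name(aa: str, style: str) -> str:
    if aa == "*":
        return "*" if style == "three" else "X"
    return seq3(aa) if style == "three" else aa


def frameshift_protein_effect(
    cds: str, cpos: int, ref_allele: str, alt_allele: str, style: str = "three"
) -> str:
    """HGVS protein change for a frame-disrupting indel in the CDS.

    ``cds`` is the coding sequence in transcript orientation (it may extend
    past the stop codon into the 3'UTR, as translation of a shifted frame
    can); ``cpos`` is the 1-based coding position of the first ref base of
    the anchored indel (``ref_allele`` -> ``alt_allele``).

    Returns ``p.(<Wt><pos><New>fs*<n>)`` where ``n`` counts the new-frame
    stop with the first changed residue as 1; ``p.(<Wt><pos>*)`` when the
    first changed residue is itself a stop; ``fs*?`` when no new-frame stop
    is reached before the sequence ends.
    """
    if abs(len(ref_allele) - len(alt_allele)) % 3 == 0:
        raise VariantError("not a frame-disrupting indel")
    mutated = cds[: cpos - 1] + alt_allele + cds[cpos - 1 + len(ref_allele) :]
    wt_prot = _translate(cds)
    mut_prot = _translate(mutated)

    i = 0
    while i < min(len(wt_prot), len(mut_prot)) and wt_prot[i] == mut_prot[i]:
        i += 1
    if i >= len(wt_prot):
        # change begins at/after the wild-type stop: no truncation call
        return "p.(=)" if style == "three" else "p.(=)"
    wt_aa = wt_prot[i]
    pos = i + 1
    new_aa = mut_prot[i] if i < len(mut_prot) else None

    paren = style == "three"
    def wrap(s: str) -> str:
        return f"p.({s})" if paren else f"p.{s}"

    if new_aa == "*":
        stop_sym = "*" if style == "three" else "X"
        return wrap(f"{_aa_name(wt_aa, style)}{pos}{stop_sym}")
    if new_aa is None or "*" not in mut_prot[i:]:
        stop = "?"
    else:
        stop = str(mut_prot.index("*", i) - i + 1)
    return wrap(f"{_aa_name(wt_aa, style)}{pos}{_aa_name(new_aa, style)}fs*{stop}")


# ---------------------------------------------------------------------------
# classification


def _transcript_alleles(v: VariantRecord, tx: Transcript) -> tuple[str, str]:
    if tx.strand == "+":
        return v.ref, v.alt
    return reverse_complement(v.ref), reverse_complement(v.alt)


def classify_variant(
    v: VariantRecord, tx: Transcript, ref: GenomeReference, style: str = "three"
) -> Consequence:
    """Classify a variant against a transcript into PTV categories.

    Rules, in order: (a) intronic offset +-1/+-2 anchored at a coding base ->
    splice_donor (positive offset) / splice_acceptor (negative); (b) the same
    offsets anchored at a UTR base (splice site of a non-protein-coding
    region) -> splice_noncoding_exon; (c) coding SNV creating a stop codon ->
    stop_gain; (d) coding indel with a length change not divisible by 3 ->
    frameshift; (e) everything else -> other.
    """
    v.check_reference(ref)
    v = normalize_3prime(v, tx, ref)
    ref_t, alt_t = _transcript_alleles(v, tx)

    if v.is_snv:
        coord = map_genomic_to_cdna(tx, v.pos)
        hgvs_c = f"{coord.format()}{ref_t}>{alt_t}"
        if coord.offset != 0:
            category = _splice_category(tx, coord)
        elif tx.is_coding and coord.region == "coding":
            category, hgvs_p = _snv_coding_effect(tx, ref, coord.base, alt_t, style)
            return Consequence(category, tx.id, tx.gene, hgvs_c, hgvs_p)
        else:
            category = "other"
        return Consequence(category, tx.id, tx.gene, hgvs_c)

    return _classify_indel(v, tx, ref, ref_t, alt_t, style)


def _splice_category(tx: Transcript, coord: CdnaCoord) -> str:
    if abs(coord.offset) > _SPLICE_REACH:
        return "other"
    if coord.region in ("utr3", "utr5") or not tx.is_coding:
        return "splice_noncoding_exon"
    return "splice_donor" if coord.offset > 0 else "splice_acceptor"


def _snv_coding_effect(
    tx: Transcript, ref: GenomeReference, cbase: int, alt_t: str, style: str
) -> tuple[str, str | None]:
    mrna, (t0, t1) = spliced_sequence(tx, ref)
    cds = mrna[t0 : t1 + 1]
    ci = cbase - 1
    codon_idx = ci // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mutated = codon[: ci % 3] + alt_t + codon[ci % 3 + 1 :]
    if mutated in STOP_CODONS and codon not in STOP_CODONS:
        wt_aa = str(Seq(codon).translate())
        name = f"{_aa_name(wt_aa, style)}{codon_idx + 1}"
        hgvs_p = f"p.({name}*)" if style == "three" else f"p.{name}X"
        return "stop_gain", hgvs_p
    return "other", None


def _classify_indel(
    v: VariantRecord, tx: Transcript, ref: GenomeReference,
    ref_t: str, alt_t: str, style: str,
) -> Consequence:
    """Anchored indel: name in cDNA coordinates and call frame effect.

    Indels spanning an exon/intron boundary or lying outside the CDS are
    classified ``other`` (splice categories here are reserved for the
    essential-site SNVs the simulator and the study's tallies use).
    """
    mrna, (t0, t1) = spliced_sequence(tx, ref)
    is_ins = len(v.ref) == 1 and v.alt.startswith(v.ref)
    changed = v.alt[1:] if is_ins else v.ref[1:]
    changed_t = changed if tx.strand == "+" else reverse_complement(changed)

    # transcript indices of the affected bases
    if is_ins:
        if tx.strand == "+":
            t_left = tx._mrna_index(v.pos - 1)  # 0-based anchor base
            t_right = tx._mrna_index(v.pos)  # base after the insertion
        else:
            t_left = tx._mrna_index(v.pos)  # genomic anchor+1 is transcript-left
            t_right = tx._mrna_index(v.pos - 1)
        exonic = t_left is not None and t_right is not None and t_right == t_left + 1
        affected_t = [t_right] if exonic else []
    else:
        gs = list(range(v.pos, v.pos + len(changed)))  # 1-based deleted positions
        ts = [tx._mrna_index(g - 1) for g in gs]
        exonic = all(t is not None for t in ts)
        affected_t = sorted(t for t in ts if t is not None)

    if not exonic:
        coord = _safe_coord(tx, v.pos)
        hgvs_c = f"{coord.format() if coord else '?'}{'ins' if is_ins else 'del'}{changed_t}"
        return Consequence("other", tx.id, tx.gene, hgvs_c)

    hgvs_c = _indel_name(tx, mrna, is_ins, affected_t, changed_t)

    frame_disrupting = len(changed) % 3 != 0
    if is_ins:
        # an insertion disrupts the frame only if it lands strictly inside
        # the CDS: after some coding base before the last stop-codon base
        in_cds = tx.is_coding and t0 <= t_left < t1
    else:
        in_cds = tx.is_coding and any(t0 <= t <= t1 for t in affected_t)
    if in_cds and frame_disrupting:
        # coding sequence extended through the 3'UTR: a shifted frame reads on
        cds_ext = mrna[t0:]
        # re-anchor the indel at the transcript base preceding the change
        t_anchor = (t_left if is_ins else min(affected_t) - 1)
        cpos_anchor = t_anchor - t0 + 1
        if cpos_anchor < 1:
            return Consequence("other", tx.id, tx.gene, hgvs_c)
        anchor_base = mrna[t_anchor]
        if is_ins:
            r_allele, a_allele = anchor_base, anchor_base + changed_t
        else:
            r_allele, a_allele = anchor_base + changed_t, anchor_base
        hgvs_p = frameshift_protein_effect(cds_ext, cpos_anchor, r_allele, a_allele, style)
        return Consequence("frameshift", tx.id, tx.gene, hgvs_c, hgvs_p)
    return Consequence("other", tx.id, tx.gene, hgvs_c)


def _safe_coord(tx: Transcript, gpos: int) -> CdnaCoord | None:
    try:
        return map_genomic_to_cdna(tx, gpos)
    except OutOfRangeError:
        return None


def _indel_name(tx: Transcript, mrna: str, is_ins: bool, affected_t: list[int],
                changed_t: str) -> str:
    """HGVS cDNA name for an exonic anchored indel (3'-shifted upstream).

    Duplications are detected against the transcript sequence immediately
    5' of the insertion point (``c.247dupG`` style); other insertions use
    ``ins``, deletions ``del``.
    """
    def cc(t: int) -> CdnaCoord:
        return _exonic_coord(tx, t)

    if is_ins:
        t_ins = affected_t[0]  # transcript index of the base after the insertion
        n = len(changed_t)
        if t_ins - n >= 0 and mrna[t_ins - n : t_ins] == changed_t:
            # duplication of the n bases ending just before the insertion point
            start, end = t_ins - n, t_ins - 1
            if n == 1:
                return f"{cc(start).format()}dup{changed_t}"
            return f"{cc(start).format()}_{_bare(cc(end))}dup{changed_t}"
        left, right = t_ins - 1, t_ins
        return f"{cc(left).format()}_{_bare(cc(right))}ins{changed_t}"
    start, end = affected_t[0], affected_t[-1]
    if start == end:
        return f"{cc(start).format()}del{changed_t}"
    return f"{cc(start).format()}_{_bare(cc(end))}del{changed_t}"


def _bare(coord: CdnaCoord) -> str:
    return coord.format()[2:]  # strip the "c." prefix for range ends


# ---------------------------------------------------------------------------
# VCF reading and consequence reports


def read_vcf(path) -> tuple[list[VariantRecord], list[str], list[list[int]]]:
    """Read a (possibly multi-sample) VCF.

    Returns ``(variants, sample_names, genotypes)`` where ``genotypes[i][s]``
    is the alt-allele dosage (0/1/2, -1 for missing) of sample ``s`` at
    variant ``i``.  Multi-allelic records are skipped with a warning.
    """
    variants: list[VariantRecord] = []
    genotypes: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning("skipping non-biallelic record at %s:%s", rec.chrom, rec.pos)
                continue
            variants.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0], rec.id)
            )
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                if gt is None or any(a is None for a in gt):
                    row.append(-1)
                else:
                    row.append(sum(1 for a in gt if a == 1))
            genotypes.append(row)
    return variants, samples, genotypes


def consequence_table(rows: list[tuple[VariantRecord, Consequence]]):
    """Consequence report as a DataFrame (variant, gene, category, HGVS)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "variant": v.key,
                "gene": c.gene,
                "transcript": c.transcript_id,
                "category": c.category,
                "is_ptv": c.is_ptv,
                "hgvs_c": c.hgvs_c,
                "hgvs_p": c.hgvs_p if c.hgvs_p else "-",
            }
            for v, c in rows
        ]
    )
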