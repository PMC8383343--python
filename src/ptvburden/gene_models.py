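"""Reference sequences, transcript models and cDNA coordinate arithmetic.

The coordinate substrate for consequence calling: FASTA references, GTF
transcript models (exon + CDS features), and HGVS-style cDNA coordinates
including intronic offsets (``c.50+1``) and 3'UTR star positions
(``c.*40+2``).

Conventions
-----------
External surfaces (FASTA, GTF, VCF, HGVS strings) are 1-based; all internal
arithmetic uses 0-based half-open intervals.  Exons are stored in
transcription order, so for a minus-strand transcript the first exon is the
one with the highest genomic coordinates.  The CDS interval includes both
the start and the stop codon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_IUPAC_NT = set("ACGTNRYSWKMBDHV")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GeneModelError(ValueError):
    """Malformed reference or transcript model."""


class OutOfRangeError(GeneModelError):
    """Genomic position outside a transcript's span."""


# ---------------------------------------------------------------------------
# Reference


@dataclass
class GenomeReference:
    """In-memory nucleotide reference: contig name -> uppercase sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise GeneModelError("reference contains no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise GeneModelError(f"contig {name!r} is empty")
            bad = set(seq) - _IUPAC_NT
            if bad:
                raise GeneModelError(
                    f"contig {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path) -> "GenomeReference":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise GeneModelError(f"duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq).upper()
        return cls(contigs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice [start, end) 0-based from a contig."""
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise GeneModelError(
                f"slice [{start}, {end}) exceeds contig {contig!r} of length {len(seq)}"
            )
        return seq[start:end]


def read_reference(path) -> GenomeReference:
    """Load a FASTA reference; lowercase is normalized to uppercase."""
    return GenomeReference.from_fasta(path)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# cDNA coordinates


@dataclass(frozen=True, order=True)
class CdnaCoord:
    """HGVS-style cDNA coordinate.

    ``region`` locates the anchored exonic base: ``coding`` (c.n, n >= 1),
    ``utr5`` (c.-n) or ``utr3`` (c.*n); ``base`` is always positive.  A
    non-zero ``offset`` marks an intronic position relative to that anchor
    (``c.50+1``, ``c.*40+2``).
    """

    region: str  # coding | utr5 | utr3
    base: int
    offset: int = 0

    _FMT = {"coding": "{}", "utr5": "-{}", "utr3": "*{}"}
    _RE = re.compile(r"^c\.(-|\*)?(\d+)([+-]\d+)?$")

    def __post_init__(self) -> None:
        if self.region not in self._FMT:
            raise ValueError(f"unknown region {self.region!r}")
        if self.base < 1:
            raise ValueError("cDNA base index must be >= 1")

    @property
    def kind(self) -> str:
        return "intronic" if self.offset else self.region

    def format(self) -> str:
        s = "c." + self._FMT[self.region].format(self.base)
        if self.offset:
            s += f"{self.offset:+d}"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    @classmethod
    def parse(cls, text: str) -> "CdnaCoord":
        m = cls._RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse cDNA coordinate {text!r}")
        sigil, base, offset = m.groups()
        region = {None: "coding", "-": "utr5", "*": "utr3"}[sigil]
        return cls(region, int(base), int(offset) if offset else 0)


# ---------------------------------------------------------------------------
# Transcripts


@dataclass
class Transcript:
    """A transcript model on a genomic contig.

    ``exons`` are 0-based half-open intervals in transcription order.
    ``cds_start``/``cds_end`` bound the coding region (incl. start and stop
    codons) as a 0-based half-open genomic interval; both ``None`` for a
    non-coding transcript.
    """

    id: str
    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.id}: transcript has no exons")
        for s, e in self.exons:
            if s >= e:
                raise GeneModelError(f"{self.id}: empty or inverted exon ({s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise GeneModelError(f"{self.id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise GeneModelError(f"{self.id}: exons not in transcription order")
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(f"{self.id}: incomplete CDS bounds")
        if self.is_coding:
            if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
                raise GeneModelError(f"{self.id}: CDS outside transcript span")
            for g in (self.cds_start, self.cds_end - 1):
                if not any(s <= g < e for s, e in self.exons):
                    raise GeneModelError(f"{self.id}: CDS bound falls in an intron")

    # -- basic geometry ----------------------------------------------------

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all exons, 0-based half-open."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _mrna_index(self, g: int) -> int | None:
        """Transcript index (0-based) of genomic base g, or None if intronic."""
        acc = 0
        for s, e in self.exons:
            if s <= g < e:
                return acc + (g - s if self.strand == "+" else e - 1 - g)
            acc += e - s
        return None

    def _genomic_index(self, t: int) -> int:
        """Genomic 0-based position of transcript index t."""
        if not 0 <= t < self.mrna_length:
            raise OutOfRangeError(f"{self.id}: transcript index {t} out of range")
        acc = 0
        for s, e in self.exons:
            if t < acc + (e - s):
                off = t - acc
                return s + off if self.strand == "+" else e - 1 - off
            acc += e - s
        raise AssertionError("unreachable")

    def _cds_mrna_bounds(self) -> tuple[int, int]:
        """Transcript indices of the first and last CDS base (inclusive)."""
        if not self.is_coding:
            raise GeneModelError(f"{self.id}: transcript is non-coding")
        if self.strand == "+":
            first, last = self.cds_start, self.cds_end - 1
        else:
            first, last = self.cds_end - 1, self.cds_start
        t0 = self._mrna_index(first)
        t1 = self._mrna_index(last)
        assert t0 is not None and t1 is not None
        return t0, t1

    # -- validation --------------------------------------------------------

    def validate_cds(self, ref: GenomeReference) -> None:
        """Check ATG..stop structure of the spliced CDS (no internal stops)."""
        cds = self.coding_sequence(ref)
        if len(cds) % 3:
            raise GeneModelError(f"{self.id}: CDS length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            raise GeneModelError(f"{self.id}: CDS does not begin with ATG")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] not in STOP_CODONS:
            raise GeneModelError(f"{self.id}: CDS does not end with a stop codon")
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise GeneModelError(f"{self.id}: internal stop codon at codon {i + 1}")

    # -- sequence extraction ----------------------------------------------

    def spliced_sequence(self, ref: GenomeReference) -> str:
        parts = []
        for s, e in self.exons:
            seq = ref.fetch(self.contig, s, e)
            parts.append(seq if self.strand == "+" else reverse_complement(seq))
        return "".join(parts)

    def coding_sequence(self, ref: GenomeReference) -> str:
        mrna, (t0, t1) = spliced_sequence(self, ref)
        return mrna[t0 : t1 + 1]

    # -- coordinate mapping ------------------------------------------------

    def exon_containing(self, g: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= g < e:
                return i
        return None


def map_genomic_to_cdna(tx: Transcript, gpos: int) -> CdnaCoord:
    """Map a 1-based genomic position to an HGVS-style cDNA coordinate.

    Exonic positions map to c.n / c.-n / c.*n; intronic positions anchor to
    the nearest exon edge (ties prefer the upstream, donor-side edge in
    transcript orientation) with a signed offset.
    """
    g = gpos - 1
    lo, hi = tx.span
    if not lo <= g < hi:
        raise OutOfRangeError(
            f"{tx.id}: genomic position {gpos} outside transcript span "
            f"[{lo + 1}, {hi}]"
        )
    t = tx._mrna_index(g)
    if t is not None:
        return _exonic_coord(tx, t)

    # intronic: flanking exons in transcription order
    for i in range(len(tx.exons) - 1):
        up, down = tx.exons[i], tx.exons[i + 1]
        if tx.strand == "+":
            in_intron = up[1] <= g < down[0]
            d_up = g - (up[1] - 1)
            d_down = down[0] - g
            up_edge, down_edge = up[1] - 1, down[0]
        else:
            in_intron = down[1] <= g < up[0]
            d_up = (up[0]) - g
            d_down = g - (down[1] - 1)
            up_edge, down_edge = up[0], down[1] - 1
        if in_intron:
            if d_up <= d_down:
                anchor = _exonic_coord(tx, tx._mrna_index(up_edge))
                return replace(anchor, offset=d_up)
            anchor = _exonic_coord(tx, tx._mrna_index(down_edge))
            return replace(anchor, offset=-d_down)
    raise AssertionError("position neither exonic nor intronic within span")


def _exonic_coord(tx: Transcript, t: int) -> CdnaCoord:
    if not tx.is_coding:
        # non-coding transcripts get plain transcript positions, rendered as
        # coding-style indices (no UTR concept without a CDS)
        return CdnaCoord("coding", t + 1)
    t0, t1 = tx._cds_mrna_bounds()
    if t < t0:
        return CdnaCoord("utr5", t0 - t)
    if t > t1:
        return CdnaCoord("utr3", t - t1)
    return CdnaCoord("coding", t - t0 + 1)


def map_cdna_to_genomic(tx: Transcript, coord: CdnaCoord) -> int:
    """Inverse of :func:`map_genomic_to_cdna`; returns a 1-based position."""
    if tx.is_coding:
        t0, t1 = tx._cds_mrna_bounds()
        if coord.region == "coding":
            t = t0 + coord.base - 1
        elif coord.region == "utr5":
            t = t0 - coord.base
        else:
            t = t1 + coord.base
    else:
        t = coord.base - 1
    g = tx._genomic_index(t)
    if coord.offset:
        g += coord.offset if tx.strand == "+" else -coord.offset
    return g + 1


def spliced_sequence(tx: Transcript, ref: GenomeReference) -> tuple[str, tuple[int, int]]:
    """Spliced mRNA and the transcript indices of the first/last CDS base.

    For a non-coding transcript the bounds are ``(-1, -1)``.
    """
    mrna = tx.spliced_sequence(ref)
    if not tx.is_coding:
        return mrna, (-1, -1)
    t0, t1 = tx._cds_mrna_bounds()
    return mrna, (t0, t1)


# ---------------------------------------------------------------------------
# GTF I/O


def read_transcripts(path, validate: bool = False, ref: GenomeReference | None = None) -> list[Transcript]:
    """Read exon/CDS features from a GTF into Transcript models.

    1-based inclusive GTF coordinates become 0-based half-open; exon lists
    are transcription-ordered.  Transcripts without CDS lines are flagged
    non-coding.  Features lacking a transcript_id are skipped with a
    warning.  With ``validate=True`` and a reference, each coding
    transcript's CDS is checked for ATG..stop structure.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for ft in db.all_features():
        if ft.featuretype not in ("exon", "CDS"):
            continue
        tids = ft.attributes.get("transcript_id")
        if not tids:
            logger.warning("skipping %s feature without transcript_id at %s:%s",
                           ft.featuretype, ft.seqid, ft.start)
            continue
        tid = tids[0]
        gene = (ft.attributes.get("gene_id") or [tid])[0]
        meta.setdefault(tid, (gene, ft.seqid, ft.strand))
        interval = (ft.start - 1, ft.end)  # to 0-based half-open
        (exons if ft.featuretype == "exon" else cds).setdefault(tid, []).append(interval)

    out = []
    for tid, ex in exons.items():
        gene, contig, strand = meta[tid]
        ex = sorted(ex)
        if strand == "-":
            ex = ex[::-1]
        cs = ce = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
            exon_union = sorted(ex)
            if not any(s <= cs < e for s, e in exon_union) or not any(
                s < ce <= e for s, e in exon_union
            ):
                raise GeneModelError(f"{tid}: CDS bounds outside exons")
        tx = Transcript(id=tid, gene=gene, contig=contig, strand=strand,
                        exons=ex, cds_start=cs, cds_end=ce)
        if validate and ref is not None and tx.is_coding:
            tx.validate_cds(ref)
        out.append(tx)
    return out


def write_transcripts(transcripts: list[Transcript], path, source: str = "ptvburden") -> None:
    """Write exon and CDS features as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene}"; transcript_id "{tx.id}";'
            for s, e in sorted(tx.exons):
                fh.write(
                    f"{tx.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.is_coding:
                for s, e in sorted(tx.exons):
                    cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{tx.contig}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t0\t{attrs}\n"
                        )
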