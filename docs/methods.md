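# Methods

## Scope and model

`ptvburden` implements a comparative rare-variant burden analysis in four
layers: transcript-aware consequence calling, a prioritization funnel,
exact per-variant association, and directional Fisher's-method
aggregation, with a synthetic cohort generator providing all inputs with
known truth.

### Consequence calling

A protein-truncating variant (PTV) is one of: a stop-gain SNV, a
frameshifting indel, or an SNV abrogating an essential splice base. The
classifier works in transcript space: external surfaces (VCF, GTF, HGVS)
are 1-based, all internal arithmetic is 0-based half-open, and exon lists
are kept in transcription order so minus-strand transcripts are handled by
construction rather than by special cases.

Category rules, in order:

1. intronic offset ±1/±2 anchored at a **coding** exon-edge base →
   `splice_donor` (positive offset) / `splice_acceptor` (negative);
2. the same offsets anchored at a **UTR** base → `splice_noncoding_exon`.
   These do not truncate the protein (they disrupt non-coding exons, e.g.
   microRNA-binding 3′UTR sequence) but are counted among PTVs in burden
   tallies, matching how such variants are tallied in the study design
   this package follows;
3. coding SNV whose mutated codon is TAA/TAG/TGA → `stop_gain`;
4. coding indel with length change not divisible by 3 → `frameshift`;
5. everything else → `other`.

Splice reach is exactly ±2 (the essential GT/AG dinucleotides); extended
splice regions are deliberately out of scope. The anchored-base rule in
(1)/(2) resolves the boundary case of a junction whose upstream exon mixes
coding sequence and UTR: `c.*40+2` anchors a UTR base and is therefore a
non-coding-exon splice variant even though the same exon also contains the
end of the CDS.

Indels are 3′-normalized in transcript orientation before naming and
keying (rotation of the inserted/deleted string; leftward on the genome
for minus-strand transcripts), so duplications get their HGVS-canonical
`c.NdupB` names and representation differences cannot break across-sample
intersection.

Frameshift protein effects are recomputed from sequence: the mutated
coding sequence (extended through the 3′UTR, since a shifted frame reads
past the old stop) is translated, the first changed residue found, and the
new-frame stop counted with the changed residue as 1 —
`p.(<Wt><pos><New>fs*<n>)`, `p.(<Wt><pos>*)` if the first changed residue
is itself a stop, `fs*?` if no stop is reached. Three-letter names with
parentheses are the default; a one-letter style (`p.Y65X`) is available
for report parity.

### Prioritization

Three monotone stages over normalized variant keys
(`contig:pos:ref:alt`): presence in ≥ *m* affected cases (strict
intersection when *m* equals the cohort size), ortholog restriction
(genes absent from the map are warned about and treated as unmapped), and
control rarity with a strict `< threshold` comparison at the default 1%.
Variants absent from the control table count as frequency 0 and are kept —
control resources publish observed alleles only, and several of the
study's qualifying variants have control frequency 0.00.

### Association and aggregation

Per-variant tables are case vs control **allele** counts; from genotypes,
alt = 2·hom + het out of 2n. Fisher's exact test follows the R
`fisher.test` two-sided convention (sum of all conditional tables with
point probability ≤ observed), which `scipy.stats.fisher_exact` matches;
an exhaustive binomial-coefficient enumeration oracle in the test suite
verifies every table with margins ≤ 12. Degenerate margins give p = 1
with a warning. The odds ratio is the unconditional sample ratio
(a·d)/(b·c), reported as 0/∞ on zero cells without continuity correction.

Aggregation combines per-variant **one-sided** p-values with Fisher's
method (X = −2Σln pᵢ, upper χ²₂ₖ tail). Because one-sided evidence is
directional, a protective-direction variant contributes the complement
1 − p_less instead of its own small tail; risk-direction variants
contribute p_greater. Both one-sided modes and a two-sided mode are
config-exposed. Genes with no qualifying variants contribute p = 1 and
stay in the family (the family statistic gains 2 df and is thereby
diluted — documented behaviour, controllable via `include_empty_genes`).
Family evidence combines gene-level combined p-values by default;
`variant_level` combines all member-variant p-values directly.

p-values below 2.2 × 10⁻¹⁶ are floored at that value *for reporting only*
(the smallest value R prints by default); aggregation uses unfloored
values unless `floor_for_aggregation` is set. No multiple-testing
correction is applied, matching the analysis this mirrors.

### Local protein alignment

Smith–Waterman with affine gaps (Gotoh), BLOSUM62, gap open 10.0 and
extend 0.5 — EMBOSS `water` defaults, with the opening penalty charged on
the first gap residue (a gap of length L costs 10 + 0.5·(L−1)). Percent
identity and percent similarity (substitution score > 0) use the full
alignment length including gap columns. Traceback ties prefer diagonal,
then gap-in-subject, then gap-in-query, fixed for determinism; when
co-optimal alignments exist the reported one is deterministic but not
necessarily transpose-symmetric (scores always are). Scores are
cross-checked in tests against an exhaustive recursive oracle on tiny
peptides and against Biopython's `PairwiseAligner` under the same gap
model.

## The synthetic generator

Each gene is a four-exon transcript — [5′UTR + CDS₁][CDS₂][CDS₃ + 3′UTR
tail][pure 3′UTR exon] — with canonical GT..AG introns, a valid CDS
(ATG…stop, no internal stops), alternating strands across genes, one gene
per contig. One plantable site per PTV category is designed in: a reserved
TAC codon for the stop gain, a single-base duplication site whose next
base differs (so the planting is already 3′-most), donor/acceptor
essential bases of coding introns, and the donor of the 3′UTR tail
(`c.*40+2T>G`). Truth labels (category, HGVS cDNA name, frequencies) are
constructed from the design layout, not by running the classifier.

Case genotypes at frequency f are Binomial(2, f) per sample — exactly
Hardy–Weinberg — with f_case derived from the control frequency and the
configured allelic odds ratio by the odds transform
(odds_case = OR·f/(1−f)). Control cohorts are published as allele counts,
Binomial(N_alleles, f_control), emulating Exome-Variant-Server-style
tables; default allele numbers are 8,600 (EA) and 4,406 (AA), the
approximate scale of that resource. Canine-style control cohorts are also
emitted as genotype counts. A pedigree mode forces the first `n_shared`
variants to be carried by every case, for intersection-recovery tests.

What the generator does **not** emulate: linkage disequilibrium between
variants (independence is also what the burden method assumes),
sequencing/calling error, relatedness within cohorts, and population
stratification. Passing tests therefore show correctness of the
algorithms and calibration under the model's assumptions — not robustness
to those real-data complications.

## Study sizes and numerical choices

* Default simulated cohort: 12 genes × 5 planted PTVs, 200 cases, planted
  control frequency 0.5% (rare under the 1% filter), odds ratio 5. Sized
  so a full pipeline run takes seconds while leaving every stage
  non-trivial.
* Type-I calibration: 2,000 null cohorts of 3 genes × 2 variants, 500
  cases (1,000 alleles) vs 8,000 control alleles at frequency 0.10. The
  common-allele design is deliberate: one-sided exact tails are nearly
  uniform there, so the nominal 0.05 level is a meaningful target. At
  rare-variant counts the exact test is intrinsically conservative — the
  power study (0.5% variants) shows that regime instead.
* Odds-ratio recovery: 500 cohorts at frequency 0.05; cohorts with a zero
  cell (sample OR undefined) are excluded — at these counts that is
  vanishingly rare.
* Power study: median family combined p at OR ∈ {1, 2, 5, 10} with common
  random numbers across OR values, 200 cases vs 8,000 control alleles at
  0.5%.
* Fisher's-method inputs are validated to (0, 1]; the combined p is kept
  strictly positive (χ² survival probabilities underflow to 0 below
  ~1e-308 and are clamped to the smallest positive float).

## Design decisions where the design was open

* **cDNA coordinate type.** An intronic coordinate stores the region of
  its anchored exonic base (coding/utr5/utr3) plus a signed offset;
  "intronic" is derived (offset ≠ 0). This is what lets `c.*40+2` carry
  both its UTR anchor and its offset, and makes parse/format a bijection.
* **One designated transcript per gene.** Consequences are computed per
  transcript; the pipeline uses the first transcript per gene, mirroring
  one-accession-per-gene analyses.
* **GTF CDS features include the stop codon** (both the writer and the
  simulator follow this; the reader takes CDS bounds as given).
* **Canine-style cohort comparisons report two-sided p**; aggregation
  consumes one-sided directional p-values. Both are exposed via
  `sidedness`.
* **MAF inconsistencies are surfaced, not resolved**: when a genotype
  table carries a published MAF column that disagrees with its own counts
  (the case cohort's 66.7% vs the genotype-derived 58.3%), the pipeline
  computes from counts and emits a QC warning.

## Known limitations

* Consequence calling covers SNVs and simple anchored indels within one
  exon; indels spanning splice junctions classify as `other`.
* No kinship or covariate adjustment: cohorts are treated as unrelated,
  as in the analysis this mirrors (where cases in fact shared a pedigree —
  a caveat there and here).
* Empty genes dilute family-level power (p = 1 at +2 df each); with many
  empty members the family statistic is conservative by construction.
* The sample odds ratio is undefined on zero cells; rare-variant single
  cohorts frequently hit this, which is why recovery studies use common
  alleles and real analyses should read the one-sided p rather than the
  point estimate there.
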