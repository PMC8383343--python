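"""End-to-end orchestration: annotate -> prioritize -> associate -> aggregate.

The pipeline mirrors a two-arm study design: a discovery arm where PTVs
shared by all affected cases are funneled through ortholog and rarity
filters, and a case-control arm where each rare PTV is tested against
control allele counts and aggregated per gene and per gene family with
Fisher's method.

All reports are plain TSV with deterministic formatting: identical config
and seed give byte-identical outputs (the run log carries no timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    AlleleCounts,
    GenotypeCounts,
    aggregate,
    directional_p,
    floor_p,
    variant_association,
)
from .consequence import classify_variant, consequence_table, normalize_3prime, read_vcf
from .gene_models import read_reference, read_transcripts
from .prioritize import (
    ControlFrequencyTable,
    OrthologMap,
    intersect_across_samples,
    ortholog_filter,
    rare_filter,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and the four analysis decisions a run must pin down.

    ``sidedness`` selects the p-value fed to aggregation
    (two_sided / one_sided_greater / complement); ``rare_threshold`` is the
    control-frequency cutoff (strict <); ``aggregation`` combines family
    evidence over gene p-values or directly over variant p-values;
    ``p_floor`` is the reporting floor for vanishing p-values.
    """

    reference: str
    transcripts: str
    vcf: str
    controls: str
    ortholog_map: str | None = None
    out_dir: str = "ptvburden_out"
    population: str = "EA"
    rare_threshold: float = 0.01
    sidedness: str = "complement"
    aggregation: str = "gene_then_family"
    p_floor: float = 2.2e-16
    floor_for_aggregation: bool = False
    min_shared_samples: int | None = None  # None: skip the intersection stage
    family_name: str = "family"
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 < self.rare_threshold <= 1.0:
            raise PipelineError(f"rare_threshold {self.rare_threshold} outside (0, 1]")
        if self.sidedness not in ("two_sided", "one_sided_greater", "complement"):
            raise PipelineError(f"unknown sidedness {self.sidedness!r}")
        if self.aggregation not in ("gene_then_family", "variant_level"):
            raise PipelineError(f"unknown aggregation {self.aggregation!r}")
        for name in ("reference", "transcripts", "vcf", "controls"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{name} file not found: {p}")
        if self.ortholog_map is not None and not Path(self.ortholog_map).exists():
            raise PipelineError(f"ortholog_map file not found: {self.ortholog_map}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Returns a dict with the in-memory results: consequences, funnel counts,
    association table, gene/family aggregation and QC warnings.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc: list[str] = []

    # ---- annotate
    try:
        reference = read_reference(cfg.reference)
        transcripts = read_transcripts(cfg.transcripts)
        variants, samples, genotypes = read_vcf(cfg.vcf)
    except Exception as exc:  # re-raise with the stage name
        raise PipelineError(f"input stage failed: {exc}") from exc

    by_gene = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene, tx)  # one designated transcript per gene
    by_contig = {tx.contig: tx for tx in by_gene.values()}

    records = []  # (variant, consequence, dosages)
    for v, doses in zip(variants, genotypes):
        tx = by_contig.get(v.contig)
        if tx is None:
            qc.append(f"variant {v.key}: no transcript on contig; skipped")
            continue
        try:
            c = classify_variant(v, tx, reference)
        except Exception as exc:
            raise PipelineError(f"annotate stage failed on {v.key}: {exc}") from exc
        records.append((normalize_3prime(v, tx, reference), c, doses))

    cons_df = consequence_table([(v, c) for v, c, _ in records])
    cons_df.to_csv(out / "consequences.tsv", sep="\t", index=False)

    # ---- prioritize
    ptv_records = [(v, c, d) for v, c, d in records if c.is_ptv]
    gene_of = {v.key: c.gene for v, c, _ in ptv_records}
    funnel_counts = {"classified": len(records), "ptv": len(ptv_records)}

    if cfg.min_shared_samples is not None:
        per_sample = [
            {v.key for v, c, d in ptv_records if d[s] > 0}
            for s in range(len(samples))
        ]
        kept = intersect_across_samples(per_sample, cfg.min_shared_samples)
    else:
        kept = {v.key for v, _, _ in ptv_records}
    funnel_counts["shared"] = len(kept)

    if cfg.ortholog_map is not None:
        omap = OrthologMap.from_tsv(cfg.ortholog_map)
        kept = ortholog_filter({k: gene_of[k] for k in kept}, omap)
    funnel_counts["ortholog"] = len(kept)

    controls = ControlFrequencyTable.from_tsv(cfg.controls)
    kept = rare_filter(kept, controls, cfg.population, cfg.rare_threshold)
    funnel_counts["rare"] = len(kept)

    funnel_df = pd.DataFrame(
        [{"stage": k, "variants": n} for k, n in funnel_counts.items()]
    )
    funnel_df.to_csv(out / "funnel.tsv", sep="\t", index=False)

    # ---- associate
    assoc_rows = []
    variant_ps_by_gene: dict[str, list[float]] = {g: [] for g in by_gene}
    for v, c, doses in ptv_records:
        if v.key not in kept:
            continue
        case = GenotypeCounts(
            n_samples=sum(1 for d in doses if d >= 0),
            hom_alt=sum(1 for d in doses if d == 2),
            het=sum(1 for d in doses if d == 1),
        )
        counts = controls.counts(v.key, cfg.population)
        if counts is None:
            qc.append(f"variant {v.key}: absent from controls; tested against 0/"
                      f"{_default_an(controls, cfg.population)}")
            counts = (0, _default_an(controls, cfg.population))
        ctrl = AlleleCounts(*counts)
        r = variant_association(case, ctrl, key=v.key)
        if cfg.sidedness == "two_sided":
            p_dir = r.p_two_sided
        else:
            p_dir = directional_p(r, cfg.sidedness)
        if cfg.floor_for_aggregation:
            p_dir = floor_p(p_dir, cfg.p_floor)
        variant_ps_by_gene.setdefault(c.gene, []).append(p_dir)
        case_ac = AlleleCounts(2 * case.hom_alt + case.het, 2 * case.n_samples)
        assoc_rows.append(
            {
                "gene": c.gene,
                "category": c.category,
                "position": v.pos,
                "hgvs_c": c.hgvs_c,
                "hgvs_p": c.hgvs_p or "-",
                "control_maf_percent": f"{100 * ctrl.maf:.2f}",
                "case_maf_percent": f"{100 * case_ac.maf:.2f}",
                "odds_ratio": _fmt_or(r.odds_ratio),
                "p_two_sided": _fmt_p(floor_p(r.p_two_sided, cfg.p_floor)),
                "p_directional": _fmt_p(floor_p(p_dir, cfg.p_floor)),
                "direction": r.direction,
            }
        )
    assoc_df = pd.DataFrame(assoc_rows)
    assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)

    # ---- aggregate
    families = {cfg.family_name: sorted(by_gene)}
    family_level = "gene" if cfg.aggregation == "gene_then_family" else "variant"
    gene_res, family_res = aggregate(
        variant_ps_by_gene, families, family_level=family_level
    )
    agg_df = write_table_reports(gene_res, family_res, out / "aggregation.tsv")

    # ---- run log
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"ptvburden {__version__}\n")
        for k, v in asdict(cfg).items():
            fh.write(f"config {k} = {v}\n")
        for k, n in funnel_counts.items():
            fh.write(f"funnel {k} = {n}\n")
        fh.write("QC warnings:\n" if qc else "QC warnings: none\n")
        for w in qc:
            fh.write(f"  - {w}\n")

    return {
        "consequences": cons_df,
        "funnel": funnel_df,
        "association": assoc_df,
        "aggregation": agg_df,
        "gene_results": gene_res,
        "family_results": family_res,
        "qc": qc,
    }


def _default_an(controls: ControlFrequencyTable, population: str) -> int:
    sub = controls.df[controls.df["population"] == population]
    return int(sub["allele_number"].max()) if len(sub) else 2


def _fmt_p(p: float) -> str:
    """p-value formatting: plain '1' for exactly 1, 4+ significant digits."""
    if p == 1.0:
        return "1"
    if p >= 1e-3:
        return f"{p:.6g}"
    return f"{p:.4E}"


def _fmt_or(x: float) -> str:
    import math

    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "inf"
    return f"{x:.4g}"


def write_table_reports(gene_res, family_res, path) -> pd.DataFrame:
    """Aggregation TSV: one row per gene, then one row per family."""
    rows = [
        {
            "unit": g,
            "level": "gene",
            "k": r.k,
            "statistic": f"{r.statistic:.6g}",
            "p_combined": _fmt_p(r.p_combined),
        }
        for g, r in sorted(gene_res.items())
    ]
    rows += [
        {
            "unit": f,
            "level": "family",
            "k": r.k,
            "statistic": f"{r.statistic:.6g}",
            "p_combined": _fmt_p(r.p_combined),
        }
        for f, r in sorted(family_res.items())
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
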