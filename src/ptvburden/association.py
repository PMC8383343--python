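"""Allele-count association statistics and Fisher's-method aggregation.

Single variants are tested with Fisher's exact test on a 2x2 allele-count
table (case alt/ref alleles vs control alt/ref alleles).  Gene- and
family-level burden signals are obtained by combining per-variant one-sided
p-values with Fisher's method, X = -2 sum ln p_i ~ chi-square with 2k df.

Because one-sided Fisher p-values carry a direction, a variant whose odds
ratio points the protective way would contribute *small* p to a risk-side
aggregate if its own tail were used.  The complement adjustment therefore
feeds ``1 - p_less`` for protective-direction variants, so opposite-direction
evidence is mapped to the upper end of (0, 1] instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_P_FLOOR = 2.2e-16  # reporting floor, the smallest p R prints by default


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# count containers


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies of a cohort at one biallelic site."""

    n_samples: int
    hom_alt: int
    het: int

    def __post_init__(self) -> None:
        if min(self.n_samples, self.hom_alt, self.het) < 0:
            raise AssociationError("genotype counts must be non-negative")
        if self.hom_alt + self.het > self.n_samples:
            raise AssociationError(
                f"hom_alt + het = {self.hom_alt + self.het} exceeds "
                f"n_samples = {self.n_samples}"
            )

    @property
    def hom_ref(self) -> int:
        return self.n_samples - self.hom_alt - self.het


@dataclass(frozen=True)
class AlleleCounts:
    """Alt-allele count out of a total allele number."""

    alt: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt <= self.total:
            raise AssociationError(f"invalid allele counts {self.alt}/{self.total}")

    @property
    def ref(self) -> int:
        return self.total - self.alt

    @property
    def maf(self) -> float:
        return self.alt / self.total

    @property
    def maf_percent(self) -> str:
        """One-decimal percent, reporting style."""
        return f"{100 * self.maf:.1f}"


def allele_counts(g: GenotypeCounts) -> AlleleCounts:
    """Alt alleles = 2*hom_alt + het out of 2*n_samples."""
    return AlleleCounts(2 * g.hom_alt + g.het, 2 * g.n_samples)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Row 1 = case (alt, ref) alleles; row 2 = control (alt, ref)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AssociationError("table cells must be non-negative")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def degenerate(self) -> bool:
        t = self.as_array
        return (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact(t: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Fisher's exact test p-value on a 2x2 table.

    ``two_sided`` sums all tables with point probability <= the observed
    one (the R ``fisher.test`` convention).  Degenerate margins give p = 1
    with a warning.
    """
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(
        alternative
    )
    if alt is None:
        raise AssociationError(f"unknown alternative {alternative!r}")
    if t.degenerate:
        warnings.warn("degenerate 2x2 margins: p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t.as_array, alternative=alt)[1])


@dataclass(frozen=True)
class AssociationResult:
    """All tails of one case-control allele test, plus the odds ratio."""

    key: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_two_sided: float
    p_greater: float
    p_less: float

    @property
    def direction(self) -> str:
        if math.isnan(self.odds_ratio) or self.odds_ratio == 1.0:
            return "null"
        return "risk" if self.odds_ratio > 1.0 else "protective"


def _odds_ratio(t: ContingencyTable2x2) -> float:
    num, den = t.a * t.d, t.b * t.c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def variant_association(
    case: GenotypeCounts | AlleleCounts,
    control: AlleleCounts,
    key: str = "",
    tails: tuple = ("two_sided", "greater", "less"),
) -> AssociationResult:
    """Fisher exact association of case vs control alt-allele counts.

    ``tails`` restricts which p-values are computed (the others are NaN);
    the two-sided tail costs an order of magnitude more than the one-sided
    tails on large tables, and aggregation only consumes the one-sided ones.
    """
    if isinstance(case, GenotypeCounts):
        case = allele_counts(case)
    if case.total == 0 or control.total == 0:
        raise AssociationError("both cohorts need a positive allele number")
    t = ContingencyTable2x2(case.alt, case.ref, control.alt, control.ref)

    def tail(name: str) -> float:
        return fisher_exact(t, name) if name in tails else math.nan

    return AssociationResult(
        key=key,
        table=t,
        odds_ratio=_odds_ratio(t),
        p_two_sided=tail("two_sided"),
        p_greater=tail("greater"),
        p_less=tail("less"),
    )


def directional_p(r: AssociationResult, mode: str = "complement") -> float:
    """One-sided p oriented toward case enrichment.

    ``one_sided_greater``: the case-enrichment tail itself.  ``complement``:
    the same tail for risk-direction variants, but ``1 - p_less`` for
    protective ones, so opposite-direction evidence lands near 1 rather
    than contributing spuriously small values to an aggregate.
    """
    if mode == "one_sided_greater":
        return r.p_greater
    if mode == "complement":
        if r.direction == "protective":
            return 1.0 - r.p_less
        return r.p_greater
    raise AssociationError(f"unknown directional mode {mode!r}")


# ---------------------------------------------------------------------------
# Fisher's method


@dataclass(frozen=True)
class AggregationResult:
    """Fisher's-method combination of k member p-values."""

    unit: str
    p_values: tuple[float, ...]
    statistic: float
    df: int
    p_combined: float

    @property
    def k(self) -> int:
        return len(self.p_values)


def fisher_method(ps, unit: str = "") -> AggregationResult:
    """Combine p-values: X = -2 sum ln p_i, upper chi-square tail at 2k df."""
    ps = tuple(float(p) for p in ps)
    if not ps:
        raise AssociationError("cannot combine an empty p-value list")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise AssociationError(
                f"p-values must lie in (0, 1]; got {p} (floor tiny values first)"
            )
    x = -2.0 * sum(math.log(p) for p in ps) + 0.0  # avoid -0.0
    p_comb = float(stats.chi2.sf(x, 2 * len(ps)))
    # chi2.sf returns exactly 0 below ~1e-308; keep p in (0, 1]
    p_comb = max(p_comb, 5e-324)
    return AggregationResult(unit, ps, x, 2 * len(ps), p_comb)


def aggregate(
    variant_ps_by_gene: dict[str, list[float]],
    families: dict[str, list[str]] | None = None,
    include_empty_genes: bool = True,
    family_level: str = "gene",
) -> tuple[dict[str, AggregationResult], dict[str, AggregationResult]]:
    """Gene- then family-level Fisher's-method aggregation.

    ``variant_ps_by_gene`` maps gene -> directional per-variant p-values
    (possibly empty).  Genes without qualifying variants contribute p = 1
    when ``include_empty_genes`` (a documented dilution of the family
    signal).  ``family_level`` chooses whether the family statistic combines
    the member gene p-values (``"gene"``, default) or all member variant
    p-values directly (``"variant"``).
    """
    gene_results: dict[str, AggregationResult] = {}
    for gene, ps in variant_ps_by_gene.items():
        if ps:
            gene_results[gene] = fisher_method(ps, unit=gene)
        elif include_empty_genes:
            gene_results[gene] = fisher_method([1.0], unit=gene)

    family_results: dict[str, AggregationResult] = {}
    if families:
        for fam, genes in families.items():
            members = [g for g in genes if g in gene_results]
            if not members:
                raise AssociationError(f"family {fam!r} has no member genes")
            if family_level == "gene":
                ps = [gene_results[g].p_combined for g in members]
            elif family_level == "variant":
                ps = [p for g in members for p in (variant_ps_by_gene.get(g) or [1.0])]
            else:
                raise AssociationError(f"unknown family_level {family_level!r}")
            family_results[fam] = fisher_method(ps, unit=fam)
    return gene_results, family_results


def floor_p(p: float, floor: float = DEFAULT_P_FLOOR) -> float:
    """Reporting floor for vanishing p-values (printed as the floor)."""
    return max(p, floor)


# ---------------------------------------------------------------------------
# genotype-count table reports (canine-style cohort comparison)


def read_genotype_table(path) -> pd.DataFrame:
    """Read a genotype-count TSV with columns cohort, label, n, hom_alt, het."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"cohort", "label", "n", "hom_alt", "het"}
    missing = required - set(df.columns)
    if missing:
        raise AssociationError(f"genotype table missing columns: {sorted(missing)}")
    return df


def genotype_table_report(
    df: pd.DataFrame, case_cohort: str
) -> tuple[pd.DataFrame, list[str]]:
    """Cohort MAFs and Fisher exact p-values against a designated case row.

    Each non-case cohort (rows pooled over labels) is compared to the case
    cohort on the genotype-derived allele counts.  Returns the report table
    and a list of QC warnings (e.g. a printed MAF that disagrees with its
    genotype counts, when the table carries a ``reported_maf`` column).
    """
    qc: list[str] = []

    def cohort_counts(sub: pd.DataFrame) -> GenotypeCounts:
        return GenotypeCounts(
            int(sub["n"].sum()), int(sub["hom_alt"].sum()), int(sub["het"].sum())
        )

    case = cohort_counts(df[df["cohort"] == case_cohort])
    if case.n_samples == 0:
        raise AssociationError(f"case cohort {case_cohort!r} not found")
    case_alleles = allele_counts(case)

    rows = []
    for cohort, sub in df.groupby("cohort", sort=False):
        g = cohort_counts(sub)
        ac = allele_counts(g)
        if cohort == case_cohort:
            p = math.nan
        else:
            p = variant_association(case_alleles, ac).p_two_sided
        rows.append(
            {
                "cohort": cohort,
                "n": g.n_samples,
                "hom_alt": g.hom_alt,
                "het": g.het,
                "alt_alleles": ac.alt,
                "total_alleles": ac.total,
                "maf_percent": ac.maf_percent,
                "p_two_sided": p,
            }
        )
        if "reported_maf" in sub.columns and len(sub) == 1:
            reported = sub["reported_maf"].iloc[0]
            if pd.notna(reported) and f"{float(reported):.1f}" != ac.maf_percent:
                qc.append(
                    f"cohort {cohort!r}: reported MAF {reported} disagrees with "
                    f"genotype-derived {ac.maf_percent} "
                    f"({ac.alt}/{ac.total} alleles)"
                )
    # per-label MAFs for multi-breed cohorts
    label_rows = []
    for (cohort, label), sub in df.groupby(["cohort", "label"], sort=False):
        g = cohort_counts(sub)
        label_rows.append(
            {"cohort": cohort, "label": label, "maf_percent": allele_counts(g).maf_percent}
        )
    report = pd.DataFrame(rows)
    report.attrs["label_mafs"] = pd.DataFrame(label_rows)
    return report, qc
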