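"""The variant-prioritization funnel.

Candidate PTVs are narrowed in three stages: (1) keep variants shared by at
least ``min_samples`` affected cases; (2) keep variants in genes with a
known ortholog in the target species; (3) keep variants rare (< 1% by
default) in an ethnic-matched control allele-frequency table.  Each stage
returns a subset of its input, so the funnel is monotone and the stages
commute.

Variants are keyed by ``contig:pos:ref:alt`` of their 3'-normalized
representation, so representation differences between callers cannot break
the across-sample intersection.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


class PrioritizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ortholog map


class OrthologMap:
    """source gene -> target-species gene, or None for no ortholog."""

    def __init__(self, mapping: dict[str, str | None]):
        self.mapping = dict(mapping)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["source", "target"], dtype=str)
        if df["source"].duplicated().any():
            dupes = df.loc[df["source"].duplicated(), "source"].tolist()
            raise PrioritizeError(f"duplicate source genes in ortholog map: {dupes}")
        mapping = {
            row.source: (None if pd.isna(row.target) or row.target.upper() == "NONE"
                         else row.target)
            for row in df.itertuples()
        }
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for src, tgt in self.mapping.items():
                fh.write(f"{src}\t{tgt if tgt else 'NONE'}\n")

    def target(self, gene: str) -> str | None:
        if gene not in self.mapping:
            logger.warning("gene %r absent from ortholog map; treated as NONE", gene)
            return None
        return self.mapping[gene]


# ---------------------------------------------------------------------------
# control frequency table


class ControlFrequencyTable:
    """Per-variant, per-population control allele counts (EVS-style)."""

    COLUMNS = ["variant", "population", "alt_count", "allele_number"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise PrioritizeError(f"control table missing columns: {sorted(missing)}")
        bad = df[(df["alt_count"] < 0) | (df["alt_count"] > df["allele_number"])
                 | (df["allele_number"] <= 0)]
        if len(bad):
            raise PrioritizeError(f"invalid control counts:\n{bad}")
        self.df = df.set_index(["variant", "population"], drop=False)

    @classmethod
    def from_tsv(cls, path) -> "ControlFrequencyTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.df.reset_index(drop=True)[self.COLUMNS].to_csv(path, sep="\t", index=False)

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    def frequency(self, variant_key: str, population: str) -> float:
        """Control alt-allele frequency; absent variants count as 0."""
        try:
            row = self.df.loc[(variant_key, population)]
        except KeyError:
            return 0.0
        return float(row["alt_count"]) / float(row["allele_number"])

    def counts(self, variant_key: str, population: str) -> tuple[int, int] | None:
        try:
            row = self.df.loc[(variant_key, population)]
        except KeyError:
            return None
        return int(row["alt_count"]), int(row["allele_number"])


# ---------------------------------------------------------------------------
# funnel stages


def intersect_across_samples(per_sample_ptvs: list[set[str]], min_samples: int | None = None) -> set[str]:
    """Variant keys present in at least ``min_samples`` of the per-sample
    sets (default: all of them — strict intersection)."""
    if not per_sample_ptvs:
        raise PrioritizeError("no sample variant sets provided")
    if min_samples is None:
        min_samples = len(per_sample_ptvs)
    if not 1 <= min_samples <= len(per_sample_ptvs):
        raise PrioritizeError(
            f"min_samples = {min_samples} outside [1, {len(per_sample_ptvs)}]"
        )
    counts: dict[str, int] = {}
    for s in per_sample_ptvs:
        for key in s:
            counts[key] = counts.get(key, 0) + 1
    return {k for k, n in counts.items() if n >= min_samples}


def ortholog_filter(variant_genes: dict[str, str], omap: OrthologMap) -> set[str]:
    """Keep variants whose gene has a (non-None) ortholog target."""
    return {key for key, gene in variant_genes.items() if omap.target(gene) is not None}


def rare_filter(
    variants: set[str],
    controls: ControlFrequencyTable,
    population: str,
    threshold: float = 0.01,
) -> set[str]:
    """Keep variants with control frequency strictly below ``threshold``.

    Variants absent from the control table are kept (frequency 0).
    """
    if not 0.0 < threshold <= 1.0:
        raise PrioritizeError(f"threshold {threshold} outside (0, 1]")
    return {v for v in variants if controls.frequency(v, population) < threshold}
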