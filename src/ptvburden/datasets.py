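"""Packaged summary-statistic tables.

Two small published tables ship with the package: genotype counts of the
canine CEACAM24 c.247dupG frameshift allele across case and control
cohorts, and pairwise EMBOSS-water percent identity/similarity of dog and
human CEACAM proteins against dog CEACAM24.  They are the inputs for the
cohort-comparison and homology-summary analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("ptvburden.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def canine_ceacam24_genotypes() -> pd.DataFrame:
    """Genotype counts (cohort, label, n, hom_alt, het, reported_maf)."""
    return _load("canine_ceacam24_genotypes.tsv")


def ceacam24_homology() -> pd.DataFrame:
    """Pairwise identity/similarity vs dog CEACAM24 (species, gene, ...)."""
    return _load("ceacam24_homology.tsv")
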