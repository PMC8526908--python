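"""Packaged reference tables from the published mouse podocyte study.

Two small tables ship with the package:

* the 32 predicted miR-145-5p targets among the podocyte essential genes,
  with each gene's mean single-podocyte expression (RPKM) and its
  cumulative weighted context++ score; and
* the ten most abundant endogenous podocyte miRNA families with their
  abundances (RPKM) and their essential-gene target lists.

They serve as worked-example inputs and as ground truth for regression
tests; re-deriving them from a live TargetScan snapshot would shift with
database releases and is deliberately not attempted.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression import EssentialGeneSet
from .families import Family, FamilyProfile, top_k_families

__all__ = [
    "load_mir145_hits",
    "load_family_baseline",
    "baseline_family_profile",
    "PROFILE_GRAND_TOTAL_RPKM",
    "GTPASE_REGULATOR_SYMBOLS",
    "MIR145_5P",
]

MIR145_5P = "miR-145-5p"

#: total miRNA abundance of the full podocyte small-RNA profile (RPKM);
#: family shares are percentages of this, not of the top-10 subtotal
PROFILE_GRAND_TOTAL_RPKM = 189784.0

#: GTPase-activating proteins among the miR-145-5p essential-gene targets
GTPASE_REGULATOR_SYMBOLS = frozenset({"ARHGAP24", "ARHGAP28", "SRGAP1"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("mirtox.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_mir145_hits() -> pd.DataFrame:
    """The 32 miR-145-5p targets among podocyte essential genes.

    Columns: symbol, description, mean_rpkm, context_score; rows ordered by
    descending mean expression.
    """
    return _read("podocyte_mir145_essential_targets.tsv")


def load_family_baseline() -> pd.DataFrame:
    """Top-10 endogenous podocyte miRNA families.

    Columns: family, rpkm, essential_target_genes (semicolon-joined).
    """
    return _read("podocyte_family_baseline.tsv")


def baseline_family_profile(grand_total: float = PROFILE_GRAND_TOTAL_RPKM) -> FamilyProfile:
    """The endogenous baseline as a ready-made :class:`FamilyProfile`."""
    df = load_family_baseline()
    partition = {
        r.family: Family(
            label=r.family,
            seed=None,
            members=[r.family],
            abundance=float(r.rpkm),
            essential_targets=str(r.essential_target_genes).split(";"),
        )
        for r in df.itertuples()
    }
    return top_k_families(partition, k=len(partition), grand_total=grand_total)


def mir145_essential_set() -> EssentialGeneSet:
    """The 32 reference hits packaged as an essential-gene set.

    Useful for exercising intersection and enrichment code against the
    published numbers without the original single-cell matrix (which is not
    redistributable at full scale).
    """
    df = load_mir145_hits()
    return EssentialGeneSet(
        genes=df["symbol"].tolist(),
        cutoff=0.1,
        min_fraction=1.0,
        per_gene_mean=dict(zip(df["symbol"], df["mean_rpkm"].astype(float))),
    )
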