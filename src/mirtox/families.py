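"""Seed-family collapsing of miRNA abundance profiles and the endogenous
baseline.

Mature miRNAs sharing the seed (nucleotides 2-8 of the mature sequence)
share a target repertoire and are collapsed into one family.  The top-K
most abundant families of a cell type define the *endogenous baseline*: the
typical number of that cell type's essential genes targeted by miRNAs the
cell tolerates.  A candidate miRNA whose essential-gene target burden far
exceeds this baseline is suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import EssentialGeneSet
from .targets import TargetTable, intersect_essential, top_n_targets

__all__ = [
    "MiRNAEntry",
    "MiRNAProfile",
    "Family",
    "FamilyProfile",
    "BaselineSummary",
    "assign_families",
    "top_k_families",
    "per_family_essential_targets",
    "baseline_summary",
    "is_expressed",
    "read_profile",
    "read_family_map",
]

_RNA = set("ACGU")


def round1(x: float) -> float:
    """Round half-up to one decimal (matches printed-table precision)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def seed_of(sequence: str) -> str:
    """7-mer seed: nucleotides 2-8 of the mature sequence (1-based)."""
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {sequence!r}")
    bad = set(seq) - _RNA
    if bad:
        raise ValueError(f"invalid RNA alphabet character(s) {sorted(bad)} in {sequence!r}")
    return seq[1:8]


@dataclass
class MiRNAEntry:
    name: str
    sequence: str | None
    abundance: float  # RPKM


@dataclass
class MiRNAProfile:
    """Small-RNA abundance profile of one cell type."""

    entries: list[MiRNAEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate miRNA names in profile")
        if any(e.abundance < 0 for e in self.entries):
            raise ValueError("abundances must be >= 0")
        if self.entries and sum(e.abundance for e in self.entries) <= 0:
            raise ValueError("total abundance must be > 0")

    @property
    def total_abundance(self) -> float:
        return sum(e.abundance for e in self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


@dataclass
class Family:
    label: str
    seed: str | None
    members: list[str]
    abundance: float
    share_pct: float | None = None
    essential_targets: list[str] = field(default_factory=list)

    @property
    def n_essential_targets(self) -> int:
        return len(self.essential_targets)


@dataclass
class FamilyProfile:
    families: list[Family]
    total_abundance: float
    grand_total_reference: float | None = None

    @property
    def cumulative_share_pct(self) -> float:
        denom = self.grand_total_reference or self.total_abundance
        return round1(100.0 * sum(f.abundance for f in self.families) / denom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [f.label for f in self.families],
                "seed": [f.seed or "" for f in self.families],
                "rpkm": [f.abundance for f in self.families],
                "pct_total": [f.share_pct for f in self.families],
                "n_essential_targets": [f.n_essential_targets for f in self.families],
                "target_genes": [";".join(f.essential_targets) for f in self.families],
            }
        )


@dataclass
class BaselineSummary:
    """Endogenous-baseline statistics over the selected families."""

    mean_count: float  # mean essential-target count per family, one decimal
    union_count: int  # distinct essential genes targeted by any family
    top_share_pct: float  # cumulative abundance share of the families

    def to_dict(self) -> dict:
        return {
            "mean_count": self.mean_count,
            "union_count": self.union_count,
            "top_share_pct": self.top_share_pct,
        }


def assign_families(
    profile: MiRNAProfile,
    family_map: Mapping[str, str] | None = None,
) -> dict[str, Family]:
    """Partition a profile into seed families.

    Entries sharing nucleotides 2-8 share a family.  An explicit
    name -> family-label map overrides sequence grouping (and is the only
    route for entries without a sequence).  The family label defaults to the
    lexicographically first member name.
    """
    family_map = {k: v for k, v in (family_map or {}).items()}
    groups: dict[str, list[MiRNAEntry]] = {}
    seeds: dict[str, str | None] = {}
    for e in profile.entries:
        if e.name in family_map:
            key = f"label:{family_map[e.name]}"
            seeds.setdefault(key, seed_of(e.sequence) if e.sequence else None)
        elif e.sequence:
            s = seed_of(e.sequence)
            key = f"seed:{s}"
            seeds[key] = s
        else:
            raise ValueError(f"entry {e.name!r} has no sequence and no family-map label")
        groups.setdefault(key, []).append(e)

    out: dict[str, Family] = {}
    for key, members in groups.items():
        if key.startswith("label:"):
            label = key[len("label:"):]
        else:
            label = min(m.name for m in members)
        out[label] = Family(
            label=label,
            seed=seeds.get(key),
            members=sorted(m.name for m in members),
            abundance=sum(m.abundance for m in members),
        )
    return out


def top_k_families(
    partition: Mapping[str, Family],
    k: int = 10,
    grand_total: float | None = None,
) -> FamilyProfile:
    """Keep the ``k`` most abundant families and compute abundance shares.

    Shares are percentages of ``grand_total`` when given (the full profile's
    total, allowing the kept families to sum below 100%), else of the
    partition total; reported half-up to one decimal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fams = sorted(partition.values(), key=lambda f: (-f.abundance, f.label))
    total = sum(f.abundance for f in fams)
    kept = fams[:k]
    if grand_total is not None and grand_total < sum(f.abundance for f in kept) - 1e-9:
        raise ValueError("grand_total is smaller than the selected families' total")
    denom = grand_total if grand_total is not None else total
    for f in kept:
        f.share_pct = round1(100.0 * f.abundance / denom)
    return FamilyProfile(
        families=kept,
        total_abundance=total,
        grand_total_reference=grand_total,
    )


def baseline_summary(family_profile: FamilyProfile) -> BaselineSummary:
    """Summarize the endogenous baseline from per-family essential targets."""
    fams = family_profile.families
    counts = [f.n_essential_targets for f in fams]
    union: set[str] = set()
    for f in fams:
        union |= {g.upper() for g in f.essential_targets}
    mean = round1(sum(counts) / len(counts)) if counts else 0.0
    return BaselineSummary(
        mean_count=mean,
        union_count=len(union),
        top_share_pct=family_profile.cumulative_share_pct,
    )


def per_family_essential_targets(
    family_profile: FamilyProfile,
    target_table: TargetTable,
    essential: EssentialGeneSet,
    top_n: int = 500,
) -> tuple[FamilyProfile, BaselineSummary]:
    """Count essential-gene targets per family.

    The target table may be keyed by the family label or by member miRNA
    names; member target lists are unioned per family before intersecting
    with the essential set.  Families with no target records get a count of
    zero (a parsing mismatch, flagged by a warning).
    """
    import warnings

    known = set(target_table.records["mirna"])
    for fam in family_profile.families:
        keys = [k for k in [fam.label, *fam.members] if k in known]
        if not keys:
            warnings.warn(f"family {fam.label!r} has no target records", stacklevel=2)
            fam.essential_targets = []
            continue
        genes: list[str] = []
        seen: set[str] = set()
        for key in keys:
            for g in top_n_targets(target_table, key, n=top_n):
                if g.upper() not in seen:
                    seen.add(g.upper())
                    genes.append(g)
        hits = intersect_essential(genes, essential) if genes else []
        fam.essential_targets = [h.gene for h in hits]
    return family_profile, baseline_summary(family_profile)


def is_expressed(
    query: str,
    profile: MiRNAProfile,
    min_abundance: float = 0.0,
    partition: Mapping[str, Family] | None = None,
) -> bool:
    """Is a miRNA (or family) endogenously expressed above ``min_abundance``?

    True when any profile entry with a matching name — or any member of the
    matching family in ``partition`` — has abundance strictly above the
    threshold.  Matching is case-insensitive.
    """
    q = query.upper()
    abund = {e.name.upper(): e.abundance for e in profile.entries}
    if q in abund and abund[q] > min_abundance:
        return True
    if partition:
        for fam in partition.values():
            if fam.label.upper() == q:
                return any(abund.get(m.upper(), 0.0) > min_abundance for m in fam.members)
    return False


# ---------------------------------------------------------------------------
# IO

def read_profile(path: str | Path) -> MiRNAProfile:
    """Profile TSV with columns name, sequence (optional), rpkm."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "name" not in cols or "rpkm" not in cols:
        raise ValueError("profile TSV needs columns: name, [sequence,] rpkm")
    seq_col = cols.get("sequence")
    entries = [
        MiRNAEntry(
            name=str(r[cols["name"]]),
            sequence=(None if seq_col is None or pd.isna(r[seq_col]) else str(r[seq_col])),
            abundance=float(r[cols["rpkm"]]),
        )
        for _, r in df.iterrows()
    ]
    return MiRNAProfile(entries=entries)


def read_family_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: miRNA name, family label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("family map needs two columns: name, family_label")
    first = str(df.iloc[0, 0]).lower()
    if first in ("name", "mirna"):
        df = df.iloc[1:]
    return {str(a): str(b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
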