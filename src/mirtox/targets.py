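"""Ranked miRNA target predictions and intersection with essential genes.

Predictions are consumed from TargetScan-style "context scores" tables whose
cumulative weighted context++ score is negative, with more negative values
meaning stronger predicted repression.  Ranking therefore sorts ascending by
score.  Symbol matching against essential-gene sets is case-insensitive
(prediction tables and single-cell annotations frequently mix human- and
mouse-style casing); no ortholog mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .expression import EssentialGeneSet

__all__ = [
    "TargetTable",
    "EssentialTargetHit",
    "load_target_table",
    "top_n_targets",
    "target_scores",
    "intersect_essential",
]

# header fragments identifying the TargetScan context-scores dialect
_TS_COLUMNS = {
    "gene": "gene symbol",
    "mirna": "mirna",
    "score": "cumulative weighted context++ score",
}


@dataclass
class TargetTable:
    """De-duplicated (miRNA, gene, score) records.

    ``n_skipped`` counts malformed lines dropped during parsing.
    """

    records: pd.DataFrame  # columns: mirna, gene, score
    source_dialect: str = "simple_tsv"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        req = {"mirna", "gene", "score"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        if self.records.duplicated(["mirna", "gene"]).any():
            raise ValueError("duplicate (mirna, gene) pairs after de-duplication")

    def __len__(self) -> int:
        return len(self.records)

    def mirnas(self) -> list[str]:
        return sorted(self.records["mirna"].unique())

    def __contains__(self, mirna: str) -> bool:
        return mirna in set(self.records["mirna"])

    @classmethod
    def from_records(
        cls, rows: Sequence[tuple[str, str, float]], dialect: str = "simple_tsv"
    ) -> "TargetTable":
        df = pd.DataFrame(rows, columns=["mirna", "gene", "score"])
        df = _dedup(df)
        return cls(records=df, source_dialect=dialect)


@dataclass
class EssentialTargetHit:
    """One essential gene among a miRNA's selected targets."""

    gene: str
    mean_expression: float
    score: float


def _dedup(df: pd.DataFrame) -> pd.DataFrame:
    # keep the most negative (strongest) score per (mirna, gene)
    df = df.sort_values(["mirna", "gene", "score"], kind="mergesort")
    return df.drop_duplicates(["mirna", "gene"], keep="first").reset_index(drop=True)


def load_target_table(path: str | Path, dialect: str = "targetscan_context") -> TargetTable:
    """Parse a target-prediction table.

    ``targetscan_context``: tab-separated with a header containing at least
    "Gene Symbol", "miRNA" and "cumulative weighted context++ score"
    (matched case-insensitively).  ``simple_tsv``: three columns
    mirna, gene, score.  Duplicate (miRNA, gene) pairs collapse to the most
    negative score; lines with unparseable scores are skipped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "targetscan_context":
        colmap: dict[str, str] = {}
        for key, frag in _TS_COLUMNS.items():
            matches = [c for c in raw.columns if frag in c.lower()]
            if not matches:
                raise ValueError(f"missing required column matching {frag!r}")
            colmap[key] = matches[0]
        df = raw[[colmap["mirna"], colmap["gene"], colmap["score"]]].copy()
        df.columns = ["mirna", "gene", "score"]
    elif dialect == "simple_tsv":
        lower = [c.lower() for c in raw.columns]
        if {"mirna", "gene", "score"}.issubset(lower):
            df = raw.rename(columns=dict(zip(raw.columns, lower)))[["mirna", "gene", "score"]]
        elif raw.shape[1] >= 3:
            # headerless file: the sniffed header row is data
            raw = pd.read_csv(path, sep="\t", dtype=str, header=None)
            df = raw.iloc[:, :3].copy()
            df.columns = ["mirna", "gene", "score"]
        else:
            raise ValueError("simple_tsv requires columns mirna, gene, score")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    ok = df["score"].notna() & df["mirna"].astype(bool) & df["gene"].astype(bool)
    n_skipped = int((~ok).sum())
    df = _dedup(df[ok])
    return TargetTable(records=df, source_dialect=dialect, n_skipped=n_skipped)


def top_n_targets(table: TargetTable, mirna: str, n: int = 500) -> list[str]:
    """Top-``n`` predicted targets of ``mirna``, strongest first.

    Ranking is ascending by context++ score (most negative first); ties are
    broken by gene symbol so the selection is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sub = table.records[table.records["mirna"] == mirna]
    if sub.empty:
        raise KeyError(f"miRNA {mirna!r} not present in target table")
    sub = sub.sort_values(["score", "gene"], kind="mergesort")
    return sub["gene"].head(n).tolist()


def target_scores(table: TargetTable, mirna: str) -> dict[str, float]:
    """Map gene (uppercased) -> context++ score for one miRNA."""
    sub = table.records[table.records["mirna"] == mirna]
    return {g.upper(): float(s) for g, s in zip(sub["gene"], sub["score"])}


def intersect_essential(
    targets: Sequence[str],
    essential: EssentialGeneSet,
    scores: Mapping[str, float] | None = None,
) -> list[EssentialTargetHit]:
    """Essential genes among the selected targets, by descending expression.

    Matching is case-insensitive.  ``scores`` optionally supplies the
    context++ score per gene (keys uppercased); absent scores are NaN.
    Hits are sorted by mean expression descending, ties by symbol.
    """
    if len(targets) == 0 or len(essential) == 0:
        raise ValueError("targets and essential set must be non-empty")
    ess_by_upper = {g.upper(): g for g in essential.genes}
    scores = {k.upper(): v for k, v in (scores or {}).items()}
    hits = []
    seen: set[str] = set()
    for t in targets:
        u = t.upper()
        if u in ess_by_upper and u not in seen:
            seen.add(u)
            g = ess_by_upper[u]
            hits.append(
                EssentialTargetHit(
                    gene=g,
                    mean_expression=essential.per_gene_mean[g],
                    score=scores.get(u, float("nan")),
                )
            )
    hits.sort(key=lambda h: (-h.mean_expression, h.gene))
    return hits
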