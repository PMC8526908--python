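"""Cell-type toxicity verdict for a candidate miRNA.

The pipeline: call essential genes from the cell type's single-cell
expression, select the candidate miRNA's top-N predicted targets, intersect
with the essential set, test the hits for functional enrichment, and
contrast the hit count against the endogenous baseline (the mean
essential-target count of the cell type's own most abundant miRNA
families).  A candidate is flagged *predicted_toxic* when all three hold:

* its essential-gene target burden is at least ``fold_threshold`` times the
  endogenous baseline mean,
* the hits are functionally enriched (any term with q < alpha), and
* the miRNA is not itself endogenously expressed in the cell type
  (an expressed miRNA is evidently tolerated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from .enrichment import AnnotationSet, EnrichmentResult, Ontology, enrich, no_enrichment_check
from .expression import ExpressionMatrix, call_essential_genes
from .families import (
    BaselineSummary,
    MiRNAProfile,
    assign_families,
    is_expressed,
    per_family_essential_targets,
    top_k_families,
)
from .targets import EssentialTargetHit, TargetTable, intersect_essential, target_scores, top_n_targets

__all__ = ["ToxicityConfig", "ToxicityReport", "predict_toxicity", "derive_verdict"]

VERDICTS = ("predicted_toxic", "not_predicted_toxic", "indeterminate")


@dataclass
class ToxicityConfig:
    """Tunable pipeline parameters.

    ``fold_threshold`` and ``alpha`` are decision plumbing with sensible
    defaults, not biological constants; vary them in sensitivity analyses.
    """

    cutoff: float = 0.1  # RPKM threshold for essential-gene calling
    min_fraction: float = 1.0  # fraction of cells required above cutoff
    top_n: int = 500  # targets kept per miRNA
    k_families: int = 10  # endogenous families in the baseline
    alpha: float = 0.05  # FDR threshold for "enriched"
    fold_threshold: float = 2.0  # burden multiple of baseline mean
    min_term_size: int = 2
    grand_total: float | None = None  # external total for family shares
    require_not_expressed: bool = True
    background: list[str] | None = None  # None = genes detected in the matrix

    @classmethod
    def from_file(cls, path: str | Path) -> "ToxicityConfig":
        """Plain key=value file; unknown keys rejected."""
        kwargs: dict = {}
        numeric = {
            "cutoff": float, "min_fraction": float, "top_n": int, "k_families": int,
            "alpha": float, "fold_threshold": float, "min_term_size": int,
            "grand_total": float,
        }
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in numeric:
                kwargs[key] = numeric[key](val)
            elif key == "require_not_expressed":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key == "background":
                kwargs[key] = [g for g in val.split(",") if g]
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class ToxicityReport:
    mirna: str
    n_essential_targets: int
    hits: list[EssentialTargetHit]
    baseline: BaselineSummary | None
    fold_vs_baseline: float
    endogenously_expressed: bool
    top_terms: list[EnrichmentResult]
    enriched: bool
    verdict: str
    n_essential_genes: int = 0
    stage_failure: str | None = None

    def to_dict(self) -> dict:
        return {
            "mirna": self.mirna,
            "n_essential_targets": self.n_essential_targets,
            "hits": [asdict(h) for h in self.hits],
            "baseline": self.baseline.to_dict() if self.baseline else None,
            "fold_vs_baseline": self.fold_vs_baseline,
            "endogenously_expressed": self.endogenously_expressed,
            "top_terms": [t.to_dict() for t in self.top_terms],
            "enriched": self.enriched,
            "verdict": self.verdict,
            "n_essential_genes": self.n_essential_genes,
            "stage_failure": self.stage_failure,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ToxicityReport":
        return cls(
            mirna=d["mirna"],
            n_essential_targets=d["n_essential_targets"],
            hits=[EssentialTargetHit(**h) for h in d["hits"]],
            baseline=BaselineSummary(**d["baseline"]) if d.get("baseline") else None,
            fold_vs_baseline=d["fold_vs_baseline"],
            endogenously_expressed=d["endogenously_expressed"],
            top_terms=[EnrichmentResult(**t) for t in d["top_terms"]],
            enriched=d["enriched"],
            verdict=d["verdict"],
            n_essential_genes=d.get("n_essential_genes", 0),
            stage_failure=d.get("stage_failure"),
        )

    @classmethod
    def from_json(cls, s: str) -> "ToxicityReport":
        return cls.from_dict(json.loads(s))


def _fold(n_hits: int, baseline_mean: float) -> float:
    if n_hits == 0:
        return 0.0
    if baseline_mean <= 0:
        return math.inf
    return n_hits / baseline_mean


def derive_verdict(
    n_essential_targets: int,
    fold_vs_baseline: float,
    enriched: bool,
    endogenously_expressed: bool,
    config: ToxicityConfig,
    stage_failure: str | None = None,
) -> str:
    """Pure decision rule; re-derivable from a serialized report."""
    if stage_failure is not None:
        return "indeterminate"
    toxic = fold_vs_baseline >= config.fold_threshold and enriched
    if config.require_not_expressed and endogenously_expressed:
        toxic = False
    return "predicted_toxic" if toxic else "not_predicted_toxic"


def predict_toxicity(
    mirna: str,
    expression_matrix: ExpressionMatrix,
    target_table: TargetTable,
    profile: MiRNAProfile | None,
    ontology: Ontology,
    annotations: AnnotationSet | Mapping[str, set[str]],
    config: ToxicityConfig | None = None,
    family_map: Mapping[str, str] | None = None,
) -> ToxicityReport:
    """Run the full prediction pipeline for one candidate miRNA.

    Returns an *indeterminate* report (with an explicit ``stage_failure``
    marker) when the target table lacks the candidate or no abundance
    profile is available for the baseline / expression check.
    """
    config = config or ToxicityConfig()
    if not isinstance(annotations, AnnotationSet):
        from .enrichment import propagate

        annotations = propagate(annotations, ontology)

    essential = call_essential_genes(
        expression_matrix, cutoff=config.cutoff, min_fraction=config.min_fraction
    )

    def _indeterminate(reason: str) -> ToxicityReport:
        return ToxicityReport(
            mirna=mirna,
            n_essential_targets=0,
            hits=[],
            baseline=None,
            fold_vs_baseline=0.0,
            endogenously_expressed=False,
            top_terms=[],
            enriched=False,
            verdict="indeterminate",
            n_essential_genes=len(essential),
            stage_failure=reason,
        )

    if mirna not in target_table:
        return _indeterminate(f"miRNA {mirna!r} absent from target table")
    if profile is None or not profile.entries:
        return _indeterminate("no miRNA abundance profile for the cell type")

    targets = top_n_targets(target_table, mirna, n=config.top_n)
    hits = (
        intersect_essential(targets, essential, scores=target_scores(target_table, mirna))
        if len(essential)
        else []
    )

    background = config.background or expression_matrix.genes
    enriched = False
    top_terms: list[EnrichmentResult] = []
    if hits:
        results = enrich(
            [h.gene for h in hits],
            background,
            annotations,
            ontology,
            min_term_size=config.min_term_size,
        )
        top_terms = results[:20]
        enriched = not no_enrichment_check(results, alpha=config.alpha)

    partition = assign_families(profile, family_map=family_map)
    fam_profile = top_k_families(partition, k=config.k_families, grand_total=config.grand_total)
    fam_profile, baseline = per_family_essential_targets(
        fam_profile, target_table, essential, top_n=config.top_n
    )

    expressed = is_expressed(mirna, profile, partition=partition)
    fold = _fold(len(hits), baseline.mean_count)
    verdict = derive_verdict(len(hits), fold, enriched, expressed, config)
    return ToxicityReport(
        mirna=mirna,
        n_essential_targets=len(hits),
        hits=hits,
        baseline=baseline,
        fold_vs_baseline=fold,
        endogenously_expressed=expressed,
        top_terms=top_terms,
        enriched=enriched,
        verdict=verdict,
        n_essential_genes=len(essential),
    )
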