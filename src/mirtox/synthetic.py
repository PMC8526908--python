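"""Seeded generators for every input the toxicity pipeline consumes.

The generators emulate the statistical structure the method assumes rather
than the read-level physics of sequencing:

* an RPKM matrix from a homogeneous cell population — a planted set of
  ubiquitously expressed essential genes (per-cell expression floored
  strictly above the calling cutoff) against dispensable genes silenced in
  individual cells by Bernoulli dropout, with lognormal gene-level means so
  pairwise cell correlations land in the 0.1-0.5 band typical of
  single-cell data;
* a target table with one planted "toxic" miRNA whose top-N predictions
  overlap the essential set by a controlled fraction, benign miRNAs whose
  targets are drawn only from dispensable genes, and target records for
  each endogenous family;
* a mature-miRNA abundance profile concentrated in a few seed families
  (shares default to the published podocyte family distribution, where the
  ten most abundant families carry ~90% of miRNA content);
* a small ontology DAG with one planted term covering a chosen fraction of
  the toxic miRNA's essential hits.

All randomness flows from ``SimConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .enrichment import Ontology
from .expression import ExpressionMatrix
from .families import MiRNAEntry, MiRNAProfile
from .targets import TargetTable

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_expression",
    "simulate_targets",
    "simulate_profile",
    "simulate_ontology",
    "simulate_bundle",
]

# abundance shares of the ten dominant podocyte miRNA families (published
# small-RNA profile); the ~10% remainder is spread over minor families
_PODOCYTE_FAMILY_SHARES = (
    0.441, 0.198, 0.052, 0.047, 0.043, 0.031, 0.028, 0.030, 0.020, 0.010,
)

_RNA = "ACGU"
TOXIC_NAME = "syn-miR-toxic"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults are sized for fast tests; :meth:`podocyte_scale` mirrors the
    published podocyte setting (611 essential genes among ~12,000 detected,
    top-500 targets per miRNA).
    """

    n_cells: int = 20
    n_genes: int = 400
    n_essential: int = 40
    essential_floor: float = 0.2  # min per-cell RPKM of essential genes (> cutoff 0.1)
    dropout_rate: float = 0.5  # per-cell silencing probability of dispensable genes
    lognorm_mean: float = 1.0  # gene-level log-mean of RPKM
    lognorm_sigma: float = 1.5  # gene-level log-sd (heavy tail drives correlation)
    noise_sigma: float = 0.8  # cell-level multiplicative lognormal noise
    n_mirnas: int = 6  # 1 planted toxic + benign
    n_targets_per_mirna: int = 100
    toxic_target_overlap: float = 0.064  # fraction of toxic top-N inside the essential set
    family_shares: tuple[float, ...] = _PODOCYTE_FAMILY_SHARES
    profile_total: float = 189784.0  # total profile abundance (RPKM)
    n_minor_families: int = 10  # singletons carrying the share remainder
    planted_term_coverage: float = 0.8  # fraction of toxic hits under the planted term
    background_term_rate: float = 0.05  # per-term annotation probability elsewhere
    n_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_essential > self.n_genes:
            raise ValueError("n_essential cannot exceed n_genes")
        for name in ("dropout_rate", "toxic_target_overlap", "planted_term_coverage",
                     "background_term_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.family_shares)) > 1 + 1e-9:
            raise ValueError("family_shares must sum to <= 1")

    @classmethod
    def podocyte_scale(cls, seed: int = 0) -> "SimConfig":
        return cls(
            n_cells=24,
            n_genes=12000,
            n_essential=611,
            n_targets_per_mirna=500,
            seed=seed,
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, list[str]]:
    """RPKM matrix plus the planted essential-gene truth list.

    Essential genes: per-cell value = ``essential_floor`` + gene-mean x
    lognormal noise, hence strictly above any cutoff below the floor in
    every cell.  Dispensable genes: expressed with probability
    ``1 - dropout_rate`` per cell, else exactly 0.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    ess_idx = rng.choice(config.n_genes, size=config.n_essential, replace=False)
    is_ess = np.zeros(config.n_genes, dtype=bool)
    is_ess[ess_idx] = True

    mu = rng.lognormal(config.lognorm_mean, config.lognorm_sigma, size=config.n_genes)
    noise = rng.lognormal(0.0, config.noise_sigma, size=(config.n_genes, config.n_cells))
    values = mu[:, None] * noise
    keep = rng.random((config.n_genes, config.n_cells)) >= config.dropout_rate
    values = np.where(is_ess[:, None], values + config.essential_floor, values * keep)

    matrix = ExpressionMatrix(
        genes=genes,
        cells=[f"cell{i:03d}" for i in range(1, config.n_cells + 1)],
        values=values,
        unit="rpkm",
    )
    truth = [genes[i] for i in sorted(ess_idx)]
    return matrix, truth


def _family_labels(config: SimConfig) -> list[str]:
    return [f"sfam-{i:02d}" for i in range(1, len(config.family_shares) + 1)]


def simulate_targets(
    config: SimConfig,
    genes: Sequence[str],
    truth: Sequence[str],
) -> TargetTable:
    """Target table with a planted toxic miRNA, benign miRNAs and one record
    set per endogenous family label.

    The toxic miRNA's ``n_targets_per_mirna`` predictions contain
    ``round(toxic_target_overlap * N)`` planted essential genes; benign
    miRNAs and endogenous families draw targets uniformly from dispensable
    genes only.  Scores are negative, drawn so planted essential targets
    rank at least as strongly as the rest.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth_set = set(truth)
    dispensable = [g for g in genes if g not in truth_set]
    n = config.n_targets_per_mirna
    rows: list[tuple[str, str, float]] = []

    n_ess = round(config.toxic_target_overlap * n)
    if n_ess > len(truth):
        raise ValueError("toxic_target_overlap demands more essential genes than planted")
    ess_targets = list(rng.choice(sorted(truth_set), size=n_ess, replace=False))
    other = list(rng.choice(dispensable, size=min(n - n_ess, len(dispensable)), replace=False))
    strong = -np.sort(rng.uniform(0.2, 1.0, size=len(ess_targets)))[::-1]
    weak = -np.sort(rng.uniform(0.01, 0.5, size=len(other)))[::-1]
    rows += [(TOXIC_NAME, g, float(s)) for g, s in zip(ess_targets, strong)]
    rows += [(TOXIC_NAME, g, float(s)) for g, s in zip(other, weak)]

    benign_keys = [f"syn-miR-b{i}" for i in range(1, config.n_mirnas)]
    for key in benign_keys + _family_labels(config):
        picks = rng.choice(dispensable, size=min(n, len(dispensable)), replace=False)
        scores = -rng.uniform(0.01, 1.0, size=len(picks))
        rows += [(key, g, float(s)) for g, s in zip(picks, scores)]

    return TargetTable.from_records(rows, dialect="simple_tsv")


def _random_seed_7mers(rng: np.random.Generator, n: int) -> list[str]:
    seeds: set[str] = set()
    while len(seeds) < n:
        seeds.add("".join(rng.choice(list(_RNA), size=7)))
    return sorted(seeds)


def simulate_profile(config: SimConfig) -> tuple[MiRNAProfile, dict[str, str]]:
    """Abundance profile concentrated in ``family_shares`` seed families.

    Returns the profile and a name -> family-label map.  Each major family
    has 1-3 members sharing a seed; the share remainder is spread over
    minor singleton families.  The planted toxic candidate is, by
    construction, absent from the profile.
    """
    rng = np.random.default_rng(config.seed + 2)
    labels = _family_labels(config)
    n_fams = len(labels) + config.n_minor_families
    seeds = _random_seed_7mers(rng, n_fams)
    remainder = max(0.0, 1.0 - sum(config.family_shares))
    minor_share = remainder / max(config.n_minor_families, 1)
    shares = list(config.family_shares) + [minor_share] * config.n_minor_families
    all_labels = labels + [f"sfam-minor-{i:02d}" for i in range(1, config.n_minor_families + 1)]

    entries: list[MiRNAEntry] = []
    family_map: dict[str, str] = {}
    for i, (label, share) in enumerate(zip(all_labels, shares)):
        total = share * config.profile_total
        n_members = int(rng.integers(1, 4)) if label in labels else 1
        weights = rng.dirichlet(np.ones(n_members) * 2.0)
        for j in range(n_members):
            name = f"{label}-m{j + 1}"
            flank5 = "".join(rng.choice(list(_RNA), size=1))
            flank3 = "".join(rng.choice(list(_RNA), size=14))
            entries.append(
                MiRNAEntry(
                    name=name,
                    sequence=flank5 + seeds[i] + flank3,
                    abundance=float(total * weights[j]),
                )
            )
            family_map[name] = label
    return MiRNAProfile(entries=entries), family_map


def simulate_ontology(
    config: SimConfig,
    hit_genes: Sequence[str],
    background_genes: Sequence[str],
) -> tuple[Ontology, dict[str, set[str]], str]:
    """Small DAG with one planted over-represented term.

    The planted term annotates ``round(planted_term_coverage * n_hits)`` of
    the toxic miRNA's essential hits plus background-rate noise; every
    other term annotates background genes at ``background_term_rate``.
    Returns (ontology, direct annotations, planted term id).
    """
    rng = np.random.default_rng(config.seed + 3)
    n_terms = max(config.n_terms, 3)
    terms = [f"SYN:{i:07d}" for i in range(n_terms)]
    root = terms[0]
    edges = []
    for i, t in enumerate(terms[1:], start=1):
        n_parents = 1 if i < 3 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        edges += [(t, terms[p]) for p in parents]
    names = {t: f"synthetic process {i}" for i, t in enumerate(terms)}
    names[root] = "synthetic biological process root"
    onto = Ontology.from_edges(terms, edges, names=names,
                               namespaces={t: "biological_process" for t in terms})

    planted = terms[-1]
    annotations: dict[str, set[str]] = {}
    for t in terms[1:]:
        if t == planted:
            continue
        mask = rng.random(len(background_genes)) < config.background_term_rate
        for g, m in zip(background_genes, mask):
            if m:
                annotations.setdefault(g.upper(), set()).add(t)
    n_cov = round(config.planted_term_coverage * len(hit_genes))
    covered = list(rng.choice(sorted(hit_genes), size=n_cov, replace=False)) if n_cov else []
    noise_mask = rng.random(len(background_genes)) < config.background_term_rate
    for g in covered:
        annotations.setdefault(g.upper(), set()).add(planted)
    for g, m in zip(background_genes, noise_mask):
        if m:
            annotations.setdefault(g.upper(), set()).add(planted)
    # every background gene gets at least the root so the universe is annotated
    for g in background_genes:
        annotations.setdefault(g.upper(), set()).add(root)
    return onto, annotations, planted


@dataclass
class SimBundle:
    """One complete synthetic study."""

    config: SimConfig
    matrix: ExpressionMatrix
    truth: list[str]
    target_table: TargetTable
    profile: MiRNAProfile
    family_map: dict[str, str]
    ontology: Ontology
    annotations: dict[str, set[str]]
    planted_term: str
    toxic_mirna: str = TOXIC_NAME
    benign_mirnas: list[str] = field(default_factory=list)


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Generate a coherent set of inputs for an end-to-end run."""
    matrix, truth = simulate_expression(config)
    table = simulate_targets(config, matrix.genes, truth)
    profile, family_map = simulate_profile(config)
    hits = sorted(
        table.records[
            (table.records["mirna"] == TOXIC_NAME)
            & (table.records["gene"].isin(truth))
        ]["gene"]
    )
    onto, annotations, planted = simulate_ontology(config, hits, matrix.genes)
    return SimBundle(
        config=config,
        matrix=matrix,
        truth=truth,
        target_table=table,
        profile=profile,
        family_map=family_map,
        ontology=onto,
        annotations=annotations,
        planted_term=planted,
        benign_mirnas=[f"syn-miR-b{i}" for i in range(1, config.n_mirnas)],
    )
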