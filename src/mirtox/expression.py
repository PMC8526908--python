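"""Single-cell expression handling and essential-gene calling.

The central idea: in a homogeneous, pre-sorted cell population, a gene that
is expressed above a detection cutoff in *every* individual cell is a
candidate essential gene for that cell type.  This module holds the
expression container, RPKM normalization, the commonality criterion, and a
pairwise cell-correlation summary used to sanity-check the heterogeneity of
the input population (single-cell data of a homogeneous type typically shows
pairwise Pearson r in the 0.1-0.5 band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "EssentialGeneSet",
    "CorrelationSummary",
    "compute_rpkm",
    "call_essential_genes",
    "cutoff_sensitivity",
    "pairwise_cell_correlation",
    "read_expression_tsv",
    "read_expression_mtx",
    "read_gene_lengths",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells abundance grid with an explicit unit tag.

    Parameters
    ----------
    genes : ordered gene symbols (unique after uppercasing)
    cells : ordered cell identifiers
    values : 2-D non-negative array, shape ``(len(genes), len(cells))``
    unit : ``"counts"`` or ``"rpkm"``
    gene_lengths : optional map symbol -> transcript length in bp, required
        for RPKM normalization of a counts matrix
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    unit: str = "rpkm"
    gene_lengths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("counts", "rpkm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.ndim != 2 or self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        upper = [g.upper() for g in self.genes]
        if len(set(upper)) != len(upper):
            seen: set[str] = set()
            dup = next(g for g in upper if (g in seen) or seen.add(g))
            raise ValueError(f"duplicate gene symbol after case-normalization: {dup}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = {k.upper(): float(v) for k, v in self.gene_lengths.items()}
            bad = [g for g, v in self.gene_lengths.items() if not v > 0]
            if bad:
                raise ValueError(f"non-positive gene length for {bad[0]}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


@dataclass
class EssentialGeneSet:
    """Result of the commonality criterion.

    ``genes`` preserves the input matrix casing; membership checks are
    case-insensitive via :meth:`__contains__`.
    """

    genes: list[str]
    cutoff: float
    min_fraction: float
    per_gene_mean: dict[str, float]
    n_cells: int = 0
    n_cells_above_cutoff: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.per_gene_mean) != set(self.genes):
            raise ValueError("per_gene_mean keys must equal the gene set")
        self._upper = {g.upper() for g in self.genes}

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._upper

    def __len__(self) -> int:
        return len(self.genes)

    def mean_expression(self, gene: str) -> float:
        for g, v in self.per_gene_mean.items():
            if g.upper() == gene.upper():
                return v
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "mean_rpkm": [self.per_gene_mean[g] for g in self.genes],
                "n_cells_above_cutoff": [
                    self.n_cells_above_cutoff.get(g, self.n_cells) for g in self.genes
                ],
            }
        )


@dataclass
class CorrelationSummary:
    min: float
    median: float
    max: float
    n_pairs: int
    n_skipped: int


def compute_rpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize raw counts to reads per kilobase per million mapped reads.

    ``rpkm[g, c] = counts[g, c] * 1e9 / (total_counts[c] * length[g])``

    Zeros are preserved exactly and each cell's column is invariant to a
    uniform rescaling of that cell's counts.
    """
    if matrix.unit != "counts":
        raise ValueError("compute_rpkm expects a counts matrix")
    if matrix.gene_lengths is None:
        raise ValueError("gene_lengths are required for RPKM normalization")
    lengths = np.empty(matrix.n_genes)
    for i, g in enumerate(matrix.genes):
        try:
            lengths[i] = matrix.gene_lengths[g.upper()]
        except KeyError:
            raise ValueError(f"missing gene length for {g}") from None
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"cell {matrix.cells[zero[0]]} has zero total counts")
    rpkm = matrix.values * 1e9 / (totals[np.newaxis, :] * lengths[:, np.newaxis])
    return ExpressionMatrix(
        genes=list(matrix.genes),
        cells=list(matrix.cells),
        values=rpkm,
        unit="rpkm",
        gene_lengths=dict(matrix.gene_lengths),
    )


def _min_cells(min_fraction: float, n_cells: int) -> int:
    # guard against float artifacts such as 0.9 * 20 = 18.000000000000004
    return math.ceil(min_fraction * n_cells - 1e-9)


def call_essential_genes(
    matrix: ExpressionMatrix,
    cutoff: float = 0.1,
    min_fraction: float = 1.0,
) -> EssentialGeneSet:
    """Call essential genes by the all-cells commonality criterion.

    A gene is called essential when its expression is strictly greater than
    ``cutoff`` RPKM in at least ``ceil(min_fraction * n_cells)`` cells
    (default: every cell).  The comparison is strict, so values exactly at
    the cutoff do not count as expressed.
    """
    if matrix.unit != "rpkm":
        raise ValueError("essential-gene calling expects an RPKM matrix")
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("empty expression matrix")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    need = _min_cells(min_fraction, matrix.n_cells)
    above = (matrix.values > cutoff).sum(axis=1)
    keep = above >= need
    genes = [g for g, k in zip(matrix.genes, keep) if k]
    means = matrix.values.mean(axis=1)
    return EssentialGeneSet(
        genes=genes,
        cutoff=cutoff,
        min_fraction=min_fraction,
        per_gene_mean={g: float(means[i]) for i, g in enumerate(matrix.genes) if keep[i]},
        n_cells=matrix.n_cells,
        n_cells_above_cutoff={g: int(above[i]) for i, g in enumerate(matrix.genes) if keep[i]},
    )


def cutoff_sensitivity(
    matrix: ExpressionMatrix,
    cutoffs: Sequence[float],
    min_fraction: float = 1.0,
) -> dict[float, int]:
    """Essential-set size at each cutoff; sizes are non-increasing in cutoff."""
    if len(cutoffs) == 0:
        raise ValueError("cutoffs must be non-empty")
    return {
        float(c): len(call_essential_genes(matrix, cutoff=c, min_fraction=min_fraction))
        for c in cutoffs
    }


def pairwise_cell_correlation(matrix: ExpressionMatrix) -> CorrelationSummary:
    """Summary (min, median, max) of Pearson r over all cell pairs.

    Pairs involving a constant cell vector are undefined and skipped; the
    number of skipped pairs is reported in the summary.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    v = matrix.values
    sd = v.std(axis=0)
    ok = sd > 0
    rs: list[float] = []
    skipped = 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(v, rowvar=False)
    for i in range(matrix.n_cells):
        for j in range(i + 1, matrix.n_cells):
            if ok[i] and ok[j]:
                rs.append(float(corr[i, j]))
            else:
                skipped += 1
    if not rs:
        raise ValueError("no cell pair with nonzero variance")
    arr = np.array(rs)
    return CorrelationSummary(
        min=float(arr.min()),
        median=float(np.median(arr)),
        max=float(arr.max()),
        n_pairs=len(rs),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# IO

def read_gene_lengths(path: str | Path) -> dict[str, float]:
    """Two-column TSV: gene symbol, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("gene length file must have two columns: gene, length")
    # tolerate a header row
    if not str(df.iloc[0, 1]).replace(".", "", 1).isdigit():
        df = df.iloc[1:]
    return {str(g).upper(): float(v) for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_expression_tsv(
    path: str | Path,
    unit: str = "rpkm",
    gene_lengths: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Dense TSV: first column gene symbols, header row of cell IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        unit=unit,
        gene_lengths=dict(gene_lengths) if gene_lengths is not None else None,
    )


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    unit: str = "rpkm",
    gene_lengths: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """MatrixMarket matrix (genes x cells) with sidecar label files."""
    from scipy.io import mmread

    m = mmread(str(mtx_path))
    values = m.toarray() if hasattr(m, "toarray") else np.asarray(m)
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    cells = [line.strip() for line in Path(cells_path).read_text().splitlines() if line.strip()]
    return ExpressionMatrix(
        genes=genes,
        cells=cells,
        values=values,
        unit=unit,
        gene_lengths=dict(gene_lengths) if gene_lengths is not None else None,
    )
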