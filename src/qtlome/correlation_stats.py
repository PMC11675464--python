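"""Pearson correlations with permutation p-values, at two scales.

Genome level: per-chromosome QTL counts against gene counts and chromosome
lengths.  Chromosome level: per-window QTL density against gene (or SNP)
density within each chromosome, at every window scale, summarized by the
mean of per-chromosome correlations (r-bar).  Chromosomes with fewer than
``min_windows`` windows (default 10) at a scale are excluded, as are
constant count vectors (their correlation is undefined; excluding them
keeps r-bar unbiased rather than forcing r = 0).

p-values come from a seeded permutation test (default n = 1000): one
vector is shuffled, the two-sided p is
``(1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``, so p is never zero and is
bounded below by ``1/(n_perm+1)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly
from .windowing import WindowGrid


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (constant vector or too few points)."""


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    r: float
    n_points: int
    p_value: float
    n_permutations: int
    seed: int


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-test seed below 2^31, derived from one global seed."""
    return (int(global_seed) ^ zlib.crc32(label.encode())) & 0x7FFFFFFF


def _validate(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on constant input."""
    x, y = _validate(np.asarray(x), np.asarray(y))
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the Pearson correlation of x, y."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, y = _validate(np.asarray(x), np.asarray(y))
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r_obs = float(xc @ yc / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r_perm = perms @ xc / denom
    n_extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs)))
    return (1 + n_extreme) / (n_perm + 1)


def correlate(
    label: str,
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson r plus permutation p, with a label-derived seed substream."""
    test_seed = derive_seed(seed, label)
    r = pearson_r(x, y)
    p = permutation_pvalue(x, y, n_perm=n_perm, seed=test_seed)
    return CorrelationResult(label, r, len(np.asarray(x)), p, n_perm, test_seed)


# ---------------------------------------------------------------------------
# Genome-level correlations (one point per chromosome)
# ---------------------------------------------------------------------------


def genome_level_correlations(
    assembly: GenomeAssembly,
    qtl_counts: Mapping[str, int],
    gene_counts: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    leave_out: Sequence[str] = (),
) -> list[CorrelationResult]:
    """QTL count vs gene count and vs chromosome length, across chromosomes.

    ``leave_out`` drops chromosomes before correlating (e.g. to measure the
    influence of outlier chromosomes on the genome-level correlation).
    """
    names = [c for c in assembly.names if c not in set(leave_out)]
    if len(names) < 3:
        raise UndefinedCorrelationError("need at least 3 chromosomes")
    lengths = assembly.lengths
    q = [float(qtl_counts.get(c, 0)) for c in names]
    g = [float(gene_counts.get(c, 0)) for c in names]
    size = [float(lengths[c]) for c in names]
    return [
        correlate("r_qtl_genes", g, q, n_perm, seed),
        correlate("r_qtl_chr_size", size, q, n_perm, seed),
        correlate("r_genes_chr_size", size, g, n_perm, seed),
    ]


# ---------------------------------------------------------------------------
# Window-level correlation matrix (chromosome x scale)
# ---------------------------------------------------------------------------

PAIRS = {
    "qtl_gene": ("qtl_count", "gene_count"),
    "qtl_snp": ("qtl_count", "snp_count"),
    "gene_snp": ("gene_count", "snp_count"),
}


@dataclass
class ChromosomeCorrelationMatrix:
    """Per-chromosome, per-scale window-density correlations.

    Cells are NaN where a chromosome is excluded at a scale (fewer than
    ``min_windows`` windows, or a constant count vector).  ``column_means``
    averages only the included cells (r-bar per scale).
    """

    pair: str
    r: pd.DataFrame  # rows: chromosomes, cols: scales
    p: pd.DataFrame
    min_windows: int

    @property
    def column_means(self) -> pd.Series:
        return self.r.mean(axis=0, skipna=True)

    def to_tsv(self, path) -> None:
        out = self.r.copy()
        stars = self.p.map(
            lambda v: "**" if v <= 0.01 else ("*" if v <= 0.05 else "")
        )
        annotated = out.round(4).astype(object)
        for col in out.columns:
            annotated[col] = [
                "excluded" if pd.isna(rv) else f"{rv:.4f}{s}"
                for rv, s in zip(out[col], stars[col])
            ]
        annotated.loc["r_bar"] = [f"{v:.4f}" for v in self.column_means]
        annotated.to_csv(path, sep="\t", index_label="chrom")


def window_level_matrix(
    grids: Mapping[int, WindowGrid],
    min_windows: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    pair: str = "qtl_gene",
) -> ChromosomeCorrelationMatrix:
    """Correlate two per-window counters within each chromosome and scale."""
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {sorted(PAIRS)}")
    xf, yf = PAIRS[pair]
    scales = sorted(grids)
    assembly = grids[scales[0]].assembly
    r_mat = pd.DataFrame(index=list(assembly.names), columns=scales, dtype=float)
    p_mat = pd.DataFrame(index=list(assembly.names), columns=scales, dtype=float)
    for scale in scales:
        grid = grids[scale]
        for chrom in assembly.names:
            sl = grid.chrom_slice(chrom)
            x = getattr(grid, xf)[sl]
            y = getattr(grid, yf)[sl]
            if x.size < min_windows:
                continue
            try:
                res = correlate(f"{pair}@{chrom}@{scale}", x, y, n_perm, seed)
            except UndefinedCorrelationError:
                continue
            r_mat.loc[chrom, scale] = res.r
            p_mat.loc[chrom, scale] = res.p_value
    return ChromosomeCorrelationMatrix(pair, r_mat, p_mat, min_windows)


def qtl_vs_study_trait_correlation(
    grid: WindowGrid, n_perm: int = 1000, seed: int = 0
) -> tuple[CorrelationResult, CorrelationResult]:
    """Correlate per-window QTL counts with distinct-study and distinct-trait
    counts — high values indicate that dense windows are also pleiotropic."""
    return (
        correlate("r_qtl_studies", grid.qtl_count, grid.study_count, n_perm, seed),
        correlate("r_qtl_traits", grid.qtl_count, grid.trait_count, n_perm, seed),
    )


def write_correlations_tsv(results: Sequence[CorrelationResult], path) -> None:
    from pathlib import Path

    lines = ["label\tr\tn_points\tp_value\tn_permutations\tseed"]
    for res in results:
        lines.append(
            f"{res.label}\t{res.r:.6f}\t{res.n_points}\t{res.p_value:.6g}"
            f"\t{res.n_permutations}\t{res.seed}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
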