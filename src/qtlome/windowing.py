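"""Fixed-width genome windows, per-window feature counts, and coverage.

Each chromosome is tiled gap-free into windows of a fixed width (the
analysis scales default to 0.25, 1, 2.5 and 5 Mbp); the final window of a
chromosome may be shorter and is flagged as partial.  Every feature — QTL,
gene, or SNP position — is assigned to exactly ONE window, the one holding
its midpoint, so per-window counts always sum to the input totals (a
property the downstream hypergeometric test relies on: its counts are draws
from one finite population).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, GeneRecord, QTLRecord

DEFAULT_SCALES = (250_000, 1_000_000, 2_500_000, 5_000_000)


@dataclass
class WindowGrid:
    """A gap-free tiling of an assembly at one window size, with counters."""

    assembly: GenomeAssembly
    window_size: int
    chroms: np.ndarray  # per-window chromosome name
    starts: np.ndarray
    ends: np.ndarray
    qtl_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    gene_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    snp_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    study_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    trait_count: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.starts)
        for name in ("qtl_count", "gene_count", "snp_count", "study_count", "trait_count"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=np.int64))
        # offset of each chromosome's first window, for vectorized lookup
        self._offsets: dict[str, tuple[int, int]] = {}
        lo = 0
        for name, length in self.assembly.chromosomes:
            n_win = max(1, -(-length // self.window_size))
            self._offsets[name] = (lo, n_win)
            lo += n_win

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def is_partial(self) -> np.ndarray:
        return self.lengths != self.window_size

    def chrom_slice(self, chrom: str) -> slice:
        lo, n_win = self._offsets[chrom]
        return slice(lo, lo + n_win)

    def locate(self, chrom: str, position: int) -> int:
        """Global index of the window containing a position."""
        lo, n_win = self._offsets[chrom]
        return lo + min(position // self.window_size, n_win - 1)

    def locate_many(self, chroms: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        return np.array(
            [self.locate(c, p) for c, p in zip(chroms, positions)], dtype=np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "qtl_count": self.qtl_count,
                "gene_count": self.gene_count,
                "snp_count": self.snp_count,
                "study_count": self.study_count,
                "trait_count": self.trait_count,
                "partial": self.is_partial,
            }
        )


def make_grid(assembly: GenomeAssembly, window_size: int) -> WindowGrid:
    """Tile every chromosome into [0,w), [w,2w), ... plus a final partial."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in assembly.chromosomes:
        edges = list(range(0, length, window_size)) + [length]
        for a, b in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(a)
            ends.append(b)
    return WindowGrid(
        assembly=assembly,
        window_size=window_size,
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
    )


def count_features(
    grid: WindowGrid,
    qtl: Sequence[QTLRecord] = (),
    genes: Sequence[GeneRecord] = (),
    snps: Sequence[tuple[str, int]] = (),
) -> WindowGrid:
    """Fill the grid's counters by midpoint assignment (in place).

    ``study_count`` and ``trait_count`` are the numbers of distinct study
    identifiers and trait names among the QTL assigned to each window.
    """
    n = grid.n_windows
    for r in qtl:
        if r.chrom not in grid.assembly:
            raise ValueError(f"QTL {r.qtl_id!r} on unknown chromosome {r.chrom!r}")
    for g in genes:
        if g.chrom not in grid.assembly:
            raise ValueError(f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}")
    for c, p in snps:
        if c not in grid.assembly:
            raise ValueError(f"SNP on unknown chromosome {c!r}")

    if qtl:
        idx = grid.locate_many([r.chrom for r in qtl], [r.midpoint for r in qtl])
        grid.qtl_count = np.bincount(idx, minlength=n).astype(np.int64)
        assigned = pd.DataFrame(
            {
                "window": idx,
                "study": [r.study_id for r in qtl],
                "trait": [r.trait_name for r in qtl],
            }
        )
        per_window = assigned.groupby("window").agg(
            studies=("study", "nunique"), traits=("trait", "nunique")
        )
        grid.study_count = np.zeros(n, dtype=np.int64)
        grid.trait_count = np.zeros(n, dtype=np.int64)
        grid.study_count[per_window.index.to_numpy()] = per_window["studies"].to_numpy()
        grid.trait_count[per_window.index.to_numpy()] = per_window["traits"].to_numpy()
    if genes:
        idx = grid.locate_many([g.chrom for g in genes], [g.midpoint for g in genes])
        grid.gene_count = np.bincount(idx, minlength=n).astype(np.int64)
    if snps:
        idx = grid.locate_many([c for c, _ in snps], [p for _, p in snps])
        grid.snp_count = np.bincount(idx, minlength=n).astype(np.int64)
    return grid


def assign_windows(grid: WindowGrid, qtl: Sequence[QTLRecord]) -> np.ndarray:
    """Window index of each QTL's midpoint (same rule as count_features)."""
    return grid.locate_many([r.chrom for r in qtl], [r.midpoint for r in qtl])


def chromosome_density_summary(grid: WindowGrid) -> pd.DataFrame:
    """Per-chromosome median and quartiles of the window QTL counts.

    The median uses the conventional mean-of-central-pair rule for an even
    number of windows.
    """
    rows = []
    for name, _ in grid.assembly.chromosomes:
        counts = grid.qtl_count[grid.chrom_slice(name)]
        if counts.size == 0:
            continue
        rows.append(
            {
                "chrom": name,
                "n_windows": counts.size,
                "q1": float(np.percentile(counts, 25)),
                "median": float(np.median(counts)),
                "q3": float(np.percentile(counts, 75)),
                "total_qtl": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CoverageSummary:
    """Fraction of the assembly lying under the union of QTL intervals."""

    species_label: str
    covered_bp: int
    total_bp: int

    @property
    def fraction(self) -> float:
        return self.covered_bp / self.total_bp if self.total_bp else 0.0


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals on one sequence."""
    total = 0
    current_start: Optional[int] = None
    current_end = 0
    for start, end in sorted(intervals):
        if current_start is None or start > current_end:
            if current_start is not None:
                total += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_start is not None:
        total += current_end - current_start
    return total


def genome_coverage(
    qtl: Sequence[QTLRecord], assembly: GenomeAssembly
) -> CoverageSummary:
    """Base pairs covered by at least one QTL, as a fraction of the genome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in qtl:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))  # type: ignore[arg-type]
    covered = sum(union_length(ivs) for ivs in by_chrom.values())
    return CoverageSummary(assembly.species_label, covered, assembly.total_length)


def write_grid_tsv(grid: WindowGrid, path) -> None:
    """BED-compatible window count table (chrom, start, end, counts...)."""
    grid.to_frame().to_csv(path, sep="\t", index=False)
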