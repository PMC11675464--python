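"""Resampling overlap test between QTL intervals and genes of interest.

The question: do more unique QTL fall on a given gene set (major genes,
top candidate genes) than on comparable random pulls from the genome?
Unique QTL are reduced to 250 kbp intervals centered on their midpoints;
the observed statistic is the number of QTL intervals touching (>= 1 bp)
at least one gene of the set.  The null redraws the gene set: either a
random same-size subset of the gene universe, or random length-matched
genomic segments.  With 1000 permutations the one-tailed enrichment p-value
is ``(1 + #{null >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import GenomeAssembly, GeneRecord, GeneSet, QTLRecord
from .qc_merge import deduplicate

NULL_MODES = ("random_genes", "random_segments")
Interval = tuple[str, int, int]


@dataclass
class PermTestResult:
    gene_set_label: str
    observed_overlaps: int
    null_overlaps: np.ndarray
    n_perm: int
    p_value: float
    z_score: Optional[float]
    null_mode: str
    seed: int
    alternative: str = "greater"

    def null_to_tsv(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(
            "overlaps\n" + "\n".join(str(int(v)) for v in self.null_overlaps) + "\n"
        )


# ---------------------------------------------------------------------------
# Query preparation
# ---------------------------------------------------------------------------


def prepare_unique_qtl(
    records: Sequence[QTLRecord],
    assembly: GenomeAssembly,
    width: int = 250_000,
    dedup_key: str = "position_trait",
) -> list[Interval]:
    """Deduplicate records and replace each with a fixed-width interval
    centered on its midpoint, shifted inward at chromosome ends."""
    unique, _ = deduplicate(records, dedup_key)
    lengths = assembly.lengths
    out: list[Interval] = []
    for r in unique:
        chrom_len = lengths[r.chrom]
        if chrom_len <= width:
            out.append((r.chrom, 0, chrom_len))
            continue
        start = r.midpoint - width // 2
        end = start + width
        if start < 0:
            start, end = 0, width
        elif end > chrom_len:
            start, end = chrom_len - width, chrom_len
        out.append((r.chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# Overlap counting
# ---------------------------------------------------------------------------


def _merged_by_chrom(intervals: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union-merge intervals per chromosome into sorted start/end arrays."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        grouped.setdefault(chrom, []).append((start, end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in grouped.items():
        ivs.sort()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def count_overlaps(query: Sequence[Interval], targets: Sequence[Interval]) -> int:
    """Number of query intervals touching >= 1 bp of any target interval.

    Each query interval counts at most once, regardless of how many targets
    it touches.
    """
    merged = _merged_by_chrom(targets)
    count = 0
    for chrom, start, end in query:
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        if i < len(starts) and starts[i] < end:
            count += 1
    return count


def _hit_lists(
    query: Sequence[Interval], universe: Sequence[GeneRecord]
) -> list[np.ndarray]:
    """For each universe gene, the indices of query intervals it touches."""
    trees: dict[str, IntervalTree] = {}
    for i, (chrom, start, end) in enumerate(query):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, i)
    hits: list[np.ndarray] = []
    for g in universe:
        tree = trees.get(g.chrom)
        if tree is None:
            hits.append(np.empty(0, dtype=np.int64))
        else:
            hits.append(
                np.array(sorted(iv.data for iv in tree.overlap(g.start, g.end)),
                         dtype=np.int64)
            )
    return hits


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def permutation_overlap_test(
    qtl_intervals: Sequence[Interval],
    gene_set: GeneSet,
    universe: Sequence[GeneRecord] | GenomeAssembly,
    n_perm: int = 1000,
    null_mode: str = "random_genes",
    seed: int = 0,
    alternative: str = "greater",
) -> PermTestResult:
    """Overlap count of QTL with a gene set against a resampled null.

    ``random_genes`` draws same-cardinality gene subsets from ``universe``
    (a gene annotation) without replacement; ``random_segments`` places
    length-matched segments uniformly on the assembly, redrawing placements
    that would extend past a chromosome end so segment lengths stay exact.
    """
    if null_mode not in NULL_MODES:
        raise ValueError(f"null_mode must be one of {NULL_MODES}")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if not gene_set.members:
        raise ValueError("gene set is empty")
    n_q = len(qtl_intervals)
    rng = np.random.default_rng(seed)
    observed = count_overlaps(qtl_intervals, gene_set.intervals())

    null = np.zeros(n_perm, dtype=np.int64)
    if null_mode == "random_genes":
        if isinstance(universe, GenomeAssembly):
            raise ValueError("random_genes needs a gene annotation as universe")
        genes = list(universe)
        k = len(gene_set.members)
        if k > len(genes):
            raise ValueError("gene set larger than the gene universe")
        hits = _hit_lists(qtl_intervals, genes)
        flags = np.zeros(n_q, dtype=bool)
        for b in range(n_perm):
            flags[:] = False
            for j in rng.choice(len(genes), size=k, replace=False):
                flags[hits[j]] = True
            null[b] = int(flags.sum())
    else:
        assembly = (
            universe
            if isinstance(universe, GenomeAssembly)
            else GenomeAssembly(
                "universe",
                tuple(
                    (c, max(e for g2 in universe if g2.chrom == c for e in (g2.end,)))
                    for c in {g.chrom for g in universe}
                ),
            )
        )
        chrom_names = list(assembly.names)
        chrom_lens = np.array([assembly.length_of(c) for c in chrom_names], dtype=np.int64)
        weights = chrom_lens / chrom_lens.sum()
        seg_lengths = [g.length for g in gene_set.members]
        for b in range(n_perm):
            segments: list[Interval] = []
            for length in seg_lengths:
                while True:  # redraw placements running past the chromosome end
                    ci = int(rng.choice(len(chrom_names), p=weights))
                    pos = int(rng.integers(0, chrom_lens[ci]))
                    if pos + length <= chrom_lens[ci]:
                        segments.append((chrom_names[ci], pos, pos + length))
                        break
            null[b] = count_overlaps(qtl_intervals, segments)

    if alternative == "greater":
        n_extreme = int(np.sum(null >= observed))
    else:
        n_extreme = int(np.sum(null <= observed))
    p = (1 + n_extreme) / (n_perm + 1)
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - float(null.mean())) / sd if sd > 0 else None
    return PermTestResult(
        gene_set.label, observed, null, n_perm, p, z, null_mode, seed, alternative
    )


# ---------------------------------------------------------------------------
# Candidate-gene ranking
# ---------------------------------------------------------------------------


def rank_candidate_genes(
    records: Sequence[QTLRecord], top_n: int = 30
) -> list[tuple[str, int]]:
    """Most frequently reported associated genes, ties broken alphabetically."""
    counts = Counter(r.gene_symbol for r in records if r.gene_symbol)
    if not counts:
        import logging

        logging.getLogger("qtlome").warning("no gene symbols present in records")
        return []
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]
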