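"""Enrichment tests for QTL counts in chromosomes and genome windows.

Three nulls:

* chromosome level — the number of QTL on a chromosome is Binomial(n, p)
  with n the genome-wide QTL count and p the chromosome's share of the
  genome length; the expectation is n x p and the exact binomial test is
  two-tailed, so both enrichment and depletion are detected;
* window level — same binomial machinery, but p is the window's share of
  genes (genes in window / total genes), so a window is judged against the
  local gene content rather than raw length; windows without genes have an
  undefined null and are skipped (and reported), not floored;
* trait level — for one phenotypic label (class, type, or trait), the count
  of labelled QTL in a window follows a hypergeometric law: drawing the
  label's k database QTL from a population split into the window's m QTL
  and the remaining n; the upper tail P(X >= q) tests over-representation.

All families are Benjamini-Hochberg adjusted; for the trait tests the
default family is per label across windows (one Manhattan panel per label),
with global pooling available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GenomeAssembly, QTLRecord
from .windowing import WindowGrid, assign_windows

TRAIT_LEVELS = {
    "class": "trait_class",
    "type": "trait_type",
    "trait": "trait_name",
}

BH_FAMILIES = ("per_label", "global")


@dataclass
class BinomialTest:
    """One binomially tested unit (a chromosome or a window)."""

    unit: str
    n_total: int
    p_null: float
    observed: int
    p_raw: float
    p_adj: Optional[float] = None

    @property
    def expected(self) -> float:
        return self.n_total * self.p_null

    @property
    def direction(self) -> str:
        if self.observed > self.expected:
            return "enriched"
        if self.observed < self.expected:
            return "depleted"
        return "neutral"


@dataclass
class HypergeomTest:
    """One (window, phenotype label) over-representation test."""

    window: str
    trait_level: str
    trait_label: str
    q_obs: int
    m: int
    n_rest: int
    k: int
    p_raw: float
    p_adj: Optional[float] = None

    @property
    def expected(self) -> float:
        return self.k * self.m / (self.m + self.n_rest)


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


def binomial_two_sided(observed: int, n_total: int, p_null: float) -> float:
    """Exact two-sided binomial p-value.

    All outcomes whose pmf does not exceed pmf(observed) (within the
    standard 1e-7 relative tolerance) contribute, so the p-value is 1 when
    the observation sits at the mode.
    """
    if not 0 <= observed <= n_total:
        raise ValueError("observed must lie in [0, n_total]")
    if not 0 < p_null < 1:
        raise ValueError("p_null must be strictly inside (0, 1)")
    return float(stats.binomtest(observed, n_total, p_null).pvalue)


def hypergeom_upper(q_obs: int, m: int, n_rest: int, k: int) -> float:
    """P(X >= q_obs) for X ~ Hypergeometric(population m+n_rest, m, k)."""
    if min(q_obs, m, n_rest, k) < 0:
        raise ValueError("all counts must be non-negative")
    if q_obs > min(m, k):
        raise ValueError("q_obs cannot exceed min(m, k)")
    if k > m + n_rest:
        raise ValueError("cannot draw more than the population")
    return float(stats.hypergeom.sf(q_obs - 1, m + n_rest, m, k))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; preserves input order, never decreases p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Chromosome-level enrichment
# ---------------------------------------------------------------------------


def chromosome_enrichment(
    assembly: GenomeAssembly,
    observed: Mapping[str, int],
    adjust: bool = True,
) -> list[BinomialTest]:
    """Binomial test per chromosome with p = chromosome size / genome size."""
    total_qtl = sum(observed.get(c, 0) for c in assembly.names)
    total_len = assembly.total_length
    tests = []
    for name, length in assembly.chromosomes:
        p_null = length / total_len
        if not 0 < p_null < 1:  # single-chromosome assembly
            continue
        obs = int(observed.get(name, 0))
        tests.append(
            BinomialTest(name, total_qtl, p_null, obs, binomial_two_sided(obs, total_qtl, p_null))
        )
    if adjust and tests:
        for t, adj in zip(tests, benjamini_hochberg([t.p_raw for t in tests])):
            t.p_adj = float(adj)
    return tests


# ---------------------------------------------------------------------------
# Window-level enrichment (gene-proportion null)
# ---------------------------------------------------------------------------


@dataclass
class SkippedWindow:
    unit: str
    reason: str


def window_enrichment(
    grid: WindowGrid,
    min_window_fraction: float = 0.0,
    adjust: bool = True,
) -> tuple[list[BinomialTest], list[SkippedWindow]]:
    """Binomial test per window with p = window gene share.

    Windows with zero genes (undefined null) are skipped and reported, as
    are partial windows shorter than ``min_window_fraction`` of the window
    size when that threshold is set above zero.
    """
    total_genes = int(grid.gene_count.sum())
    if total_genes == 0:
        raise ValueError("gene counts are empty; count genes on the grid first")
    n_total = int(grid.qtl_count.sum())
    tests: list[BinomialTest] = []
    skipped: list[SkippedWindow] = []
    min_len = min_window_fraction * grid.window_size
    for i in range(grid.n_windows):
        unit = f"{grid.chroms[i]}:{grid.starts[i]}-{grid.ends[i]}"
        if grid.ends[i] - grid.starts[i] < min_len:
            skipped.append(SkippedWindow(unit, "partial_window"))
            continue
        g = int(grid.gene_count[i])
        if g == 0:
            skipped.append(SkippedWindow(unit, "zero_genes"))
            continue
        p_null = g / total_genes
        if p_null >= 1:
            skipped.append(SkippedWindow(unit, "degenerate_null"))
            continue
        obs = int(grid.qtl_count[i])
        tests.append(
            BinomialTest(unit, n_total, p_null, obs, binomial_two_sided(obs, n_total, p_null))
        )
    if adjust and tests:
        for t, adj in zip(tests, benjamini_hochberg([t.p_raw for t in tests])):
            t.p_adj = float(adj)
    return tests, skipped


# ---------------------------------------------------------------------------
# Trait-level enrichment (hypergeometric)
# ---------------------------------------------------------------------------


def trait_window_enrichment(
    grid: WindowGrid,
    qtl: Sequence[QTLRecord],
    level: str = "trait",
    bh_family: str = "per_label",
) -> list[HypergeomTest]:
    """Hypergeometric over-representation of each phenotype label per window.

    Tests every (window, label) pair with at least one labelled QTL in the
    window; QTL with an empty label at the requested level are outside every
    label family but still count toward window totals.
    """
    if level not in TRAIT_LEVELS:
        raise ValueError(f"level must be one of {sorted(TRAIT_LEVELS)}")
    if bh_family not in BH_FAMILIES:
        raise ValueError(f"bh_family must be one of {BH_FAMILIES}")
    field = TRAIT_LEVELS[level]
    idx = assign_windows(grid, qtl)
    labels = [getattr(r, field) for r in qtl]
    df = pd.DataFrame({"window": idx, "label": labels})
    total = len(qtl)
    m_per_window = df.groupby("window").size()
    k_per_label = df[df["label"] != ""].groupby("label").size()
    pair_counts = (
        df[df["label"] != ""].groupby(["window", "label"]).size().reset_index(name="q")
    )
    tests: list[HypergeomTest] = []
    for row in pair_counts.itertuples(index=False):
        w, label, q = int(row.window), row.label, int(row.q)
        m = int(m_per_window.loc[w])
        k = int(k_per_label.loc[label])
        unit = f"{grid.chroms[w]}:{grid.starts[w]}-{grid.ends[w]}"
        tests.append(
            HypergeomTest(unit, level, label, q, m, total - m, k,
                          hypergeom_upper(q, m, total - m, k))
        )
    if not tests:
        return tests
    if bh_family == "global":
        for t, adj in zip(tests, benjamini_hochberg([t.p_raw for t in tests])):
            t.p_adj = float(adj)
    else:
        by_label: dict[str, list[HypergeomTest]] = {}
        for t in tests:
            by_label.setdefault(t.trait_label, []).append(t)
        for family in by_label.values():
            for t, adj in zip(family, benjamini_hochberg([t.p_raw for t in family])):
                t.p_adj = float(adj)
    return tests


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def binomial_tests_frame(tests: Sequence[BinomialTest]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit": [t.unit for t in tests],
            "observed": [t.observed for t in tests],
            "expected": [t.expected for t in tests],
            "p_null": [t.p_null for t in tests],
            "p_raw": [t.p_raw for t in tests],
            "p_adj": [t.p_adj for t in tests],
            "direction": [t.direction for t in tests],
        }
    )


def hypergeom_tests_frame(tests: Sequence[HypergeomTest]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": [t.window for t in tests],
            "level": [t.trait_level for t in tests],
            "label": [t.trait_label for t in tests],
            "q_obs": [t.q_obs for t in tests],
            "m": [t.m for t in tests],
            "n_rest": [t.n_rest for t in tests],
            "k": [t.k for t in tests],
            "expected": [t.expected for t in tests],
            "p_raw": [t.p_raw for t in tests],
            "p_adj": [t.p_adj for t in tests],
        }
    )
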