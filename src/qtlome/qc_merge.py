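"""Quality control and merging of QTL annotations.

The cascade applied to a raw QTL catalog, in order:

1. anomaly filters — records lacking coordinates, with inverted or negative
   coordinates, lying off the assembly or past a chromosome end, or longer
   than ``max_qtl_length`` (default 10 Mbp) are removed, each counted under
   exactly one ledger reason (first matching rule wins);
2. duplicate removal — records sharing position, trait and study collapse
   to the first occurrence;
3. same-study/same-trait merging — single-linkage chaining of records that
   overlap by at least 1 bp or are separated by less than ``merge_gap``
   (default 500 kbp); a chained cluster becomes one record when its span is
   at most ``merge_span_cap`` (default 1 Mbp), otherwise the densest
   1 Mbp windows covering at least ``min_span_coverage`` (default 30%) of
   the span replace it;
4. size standardization — every record is brought into the
   [``min_std_length``, ``max_std_length``] band (default 250 kbp – 1 Mbp)
   by expanding or trimming around its midpoint, shifting inward at
   chromosome ends.

Steps 3–4 are iterated to a fixed point so that re-running the whole
cascade on its own output is the identity (expansion to 250 kbp can close
a gap below the merge threshold; iterating resolves this deterministically —
the record count is non-increasing, so the loop terminates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .genome_io import GenomeAssembly, QTLRecord

DEDUP_KEYS = ("position_trait", "position")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the quality-control cascade (all lengths in bp)."""

    max_qtl_length: int = 10_000_000
    merge_gap: int = 500_000
    merge_span_cap: int = 1_000_000
    min_std_length: int = 250_000
    max_std_length: int = 1_000_000
    min_span_coverage: float = 0.30
    dedup_key: str = "position_trait"

    def __post_init__(self) -> None:
        if not (0 < self.min_std_length <= self.max_std_length <= self.max_qtl_length):
            raise ValueError("require 0 < min_std_length <= max_std_length <= max_qtl_length")
        if not (0 < self.min_span_coverage <= 1):
            raise ValueError("min_span_coverage must be in (0, 1]")
        if self.merge_gap <= 0 or self.merge_span_cap <= 0:
            raise ValueError("merge_gap and merge_span_cap must be positive")
        if self.dedup_key not in DEDUP_KEYS:
            raise ValueError(f"dedup_key must be one of {DEDUP_KEYS}")


@dataclass
class QCLedger:
    """Accounting of every record entering and leaving the cascade."""

    input_total: int = 0
    output_total: int = 0
    missing_coordinates: int = 0
    anomalous_position: int = 0
    out_of_bounds: int = 0
    over_length: int = 0
    duplicate: int = 0
    merged_away: int = 0

    REASONS = (
        "missing_coordinates",
        "anomalous_position",
        "out_of_bounds",
        "over_length",
        "duplicate",
        "merged_away",
    )

    @property
    def removed_total(self) -> int:
        return sum(getattr(self, reason) for reason in self.REASONS)

    def conserves(self) -> bool:
        return self.input_total == self.output_total + self.removed_total

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("input_total", self.input_total)]
        rows += [(reason, getattr(self, reason)) for reason in self.REASONS]
        rows.append(("output_total", self.output_total))
        return rows


@dataclass
class MergeCluster:
    """A chained group of same-chromosome, same-study, same-trait records."""

    key: tuple[str, str, str]
    members: list[QTLRecord]

    @property
    def span_start(self) -> int:
        return min(r.start for r in self.members)  # type: ignore[type-var]

    @property
    def span_end(self) -> int:
        return max(r.end for r in self.members)  # type: ignore[type-var]

    @property
    def span(self) -> int:
        return self.span_end - self.span_start


@dataclass
class RemovedRecord:
    record: QTLRecord
    reason: str


# ---------------------------------------------------------------------------
# Stage 1: anomaly + over-length filters
# ---------------------------------------------------------------------------


def filter_anomalies(
    records: Sequence[QTLRecord],
    assembly: GenomeAssembly,
    cfg: QCConfig = QCConfig(),
) -> tuple[list[QTLRecord], QCLedger, list[RemovedRecord]]:
    """Remove unusable records; each removal increments exactly one reason.

    Rule order (first match wins): missing coordinates; anomalous position
    (start >= end or start < 0); unknown chromosome or end past the
    chromosome length; length above ``max_qtl_length``.
    """
    ledger = QCLedger(input_total=len(records))
    kept: list[QTLRecord] = []
    removed: list[RemovedRecord] = []
    lengths = assembly.lengths
    for r in records:
        if not r.has_coordinates:
            reason = "missing_coordinates"
        elif r.start >= r.end or r.start < 0:  # type: ignore[operator]
            reason = "anomalous_position"
        elif r.chrom not in lengths or r.end > lengths[r.chrom]:  # type: ignore[operator]
            reason = "out_of_bounds"
        elif r.length > cfg.max_qtl_length:
            reason = "over_length"
        else:
            kept.append(r)
            continue
        setattr(ledger, reason, getattr(ledger, reason) + 1)
        removed.append(RemovedRecord(r, reason))
    ledger.output_total = len(kept)
    return kept, ledger, removed


# ---------------------------------------------------------------------------
# Stage 2: duplicate removal
# ---------------------------------------------------------------------------


def _dedup_key(record: QTLRecord, mode: str) -> tuple:
    if mode == "position":
        return (record.chrom, record.start, record.end)
    return (record.chrom, record.start, record.end, record.trait_name, record.study_id)


def deduplicate(
    records: Sequence[QTLRecord], key: str = "position_trait"
) -> tuple[list[QTLRecord], int]:
    """Collapse records sharing (chrom, start, end, trait, study) — or
    position only, with ``key='position'`` — to the first occurrence."""
    if key not in DEDUP_KEYS:
        raise ValueError(f"key must be one of {DEDUP_KEYS}")
    seen: set[tuple] = set()
    kept: list[QTLRecord] = []
    for r in records:
        k = _dedup_key(r, key)
        if k in seen:
            continue
        seen.add(k)
        kept.append(r)
    return kept, len(records) - len(kept)


def count_unique(records: Sequence[QTLRecord], key: str = "position_trait") -> int:
    """Number of unique annotations under the configured key."""
    return len({_dedup_key(r, key) for r in records})


# ---------------------------------------------------------------------------
# Stage 3: same-study / same-trait clustering and merging
# ---------------------------------------------------------------------------


def _record_sort_key(r: QTLRecord) -> tuple:
    return (r.chrom, r.start, r.end, r.trait_name, r.study_id, r.qtl_id)


def build_clusters(records: Sequence[QTLRecord], cfg: QCConfig) -> list[MergeCluster]:
    """Chain same-key records that overlap >= 1 bp or sit < merge_gap apart."""
    groups: dict[tuple[str, str, str], list[QTLRecord]] = {}
    for r in records:
        groups.setdefault((r.chrom, r.study_id, r.trait_name), []).append(r)
    clusters: list[MergeCluster] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=_record_sort_key)
        current = [members[0]]
        reach = members[0].end
        for r in members[1:]:
            # gap < merge_gap subsumes overlap (negative gap); strict '<'
            if r.start - reach < cfg.merge_gap:  # type: ignore[operator]
                current.append(r)
                reach = max(reach, r.end)  # type: ignore[arg-type]
            else:
                clusters.append(MergeCluster(key, current))
                current, reach = [r], r.end
        clusters.append(MergeCluster(key, current))
    return clusters


def densest_windows(cluster: MergeCluster, cfg: QCConfig) -> list[tuple[int, int]]:
    """Pick the 1 Mbp tiles of a long cluster holding the most members.

    Candidate tiles of width ``merge_span_cap`` are anchored at the span
    start with a ``merge_gap`` step; each is scored by member midpoints;
    tiles are chosen greedily by descending score (ties: leftmost),
    skipping overlaps, until the selected length reaches
    ``min_span_coverage`` of the span.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    if cluster.span <= cfg.merge_span_cap:
        raise ValueError("densest_windows requires span > merge_span_cap")
    width, step = cfg.merge_span_cap, cfg.merge_gap
    s0, s1 = cluster.span_start, cluster.span_end
    starts = list(range(s0, s1 - width + 1, step))
    if not starts:
        starts = [s0]
    midpoints = sorted(r.midpoint for r in cluster.members)
    import bisect

    def score(a: int) -> int:
        return bisect.bisect_left(midpoints, a + width) - bisect.bisect_left(midpoints, a)

    ranked = sorted(starts, key=lambda a: (-score(a), a))
    target = cfg.min_span_coverage * cluster.span
    selected: list[tuple[int, int]] = []
    covered = 0
    for a in ranked:
        if covered >= target:
            break
        if any(a < e and a + width > s for s, e in selected):
            continue
        selected.append((a, a + width))
        covered += width
    return sorted(selected)


def _merge_cluster(cluster: MergeCluster, cfg: QCConfig) -> list[QTLRecord]:
    if len(cluster.members) == 1:
        return [cluster.members[0]]
    first = cluster.members[0]  # members are coordinate-sorted
    merged_ids = ",".join(r.qtl_id for r in cluster.members)
    extra = tuple(
        [(k, v) for k, v in first.extra if k != "merged_ids"] + [("merged_ids", merged_ids)]
    )
    if cluster.span <= cfg.merge_span_cap:
        return [
            replace(first, start=cluster.span_start, end=cluster.span_end, extra=extra)
        ]
    out = []
    for i, (s, e) in enumerate(densest_windows(cluster, cfg)):
        out.append(replace(first, start=s, end=e, qtl_id=f"{first.qtl_id}_w{i}", extra=extra))
    return out


def cluster_and_merge(
    records: Sequence[QTLRecord], cfg: QCConfig = QCConfig()
) -> tuple[list[QTLRecord], int]:
    """Merge same-study/same-trait chained records; returns (merged, removed).

    Clusters whose span fits ``merge_span_cap`` collapse to one covering
    record; longer clusters are replaced by their densest 1 Mbp windows.
    Output is coordinate-sorted; the ledger delta is the net record
    reduction.
    """
    merged: list[QTLRecord] = []
    for cluster in build_clusters(records, cfg):
        merged.extend(_merge_cluster(cluster, cfg))
    merged.sort(key=_record_sort_key)
    return merged, len(records) - len(merged)


# ---------------------------------------------------------------------------
# Stage 4: size standardization
# ---------------------------------------------------------------------------


def _standardize_one(r: QTLRecord, chrom_len: int, cfg: QCConfig) -> QTLRecord:
    length = r.length
    if cfg.min_std_length <= length <= cfg.max_std_length:
        return r
    target = cfg.min_std_length if length < cfg.min_std_length else cfg.max_std_length
    if chrom_len < target:  # chromosome shorter than the standard length
        return r.with_interval(0, chrom_len)
    mid = r.midpoint
    start = mid - target // 2
    end = start + target
    if start < 0:
        start, end = 0, target
    elif end > chrom_len:
        start, end = chrom_len - target, chrom_len
    return r.with_interval(start, end)


def standardize_sizes(
    records: Sequence[QTLRecord],
    assembly: GenomeAssembly,
    cfg: QCConfig = QCConfig(),
) -> list[QTLRecord]:
    """Bring every record into the standard length band around its midpoint."""
    lengths = assembly.lengths
    return [_standardize_one(r, lengths[r.chrom], cfg) for r in records]


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


def run_qc(
    records: Sequence[QTLRecord],
    assembly: GenomeAssembly,
    cfg: QCConfig = QCConfig(),
) -> tuple[list[QTLRecord], QCLedger, list[RemovedRecord]]:
    """Run the full cascade; the ledger accounts for every input record.

    Merging and standardization are iterated to a fixed point, which makes
    the cascade idempotent (see module docstring).
    """
    kept, ledger, removed = filter_anomalies(records, assembly, cfg)
    kept, n_dup = deduplicate(kept, cfg.dedup_key)
    ledger.duplicate = n_dup

    current = sorted(kept, key=_record_sort_key)
    while True:
        merged, n_merged = cluster_and_merge(current, cfg)
        ledger.merged_away += n_merged
        std = standardize_sizes(merged, assembly, cfg)
        std.sort(key=_record_sort_key)
        if std == current:
            break
        current = std
    ledger.output_total = len(current)
    assert ledger.conserves(), "QC ledger failed conservation"
    return current, ledger, removed


def write_ledger_tsv(ledger: QCLedger, path) -> None:
    from pathlib import Path

    lines = ["category\tcount"] + [f"{k}\t{v}" for k, v in ledger.as_rows()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_removed_tsv(removed: Iterable[RemovedRecord], path) -> None:
    from pathlib import Path

    lines = ["chrom\tstart\tend\tqtl_id\ttrait_name\tstudy_id\treason"]
    for item in removed:
        r = item.record
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    "." if r.start is None else str(r.start),
                    "." if r.end is None else str(r.end),
                    r.qtl_id,
                    r.trait_name,
                    r.study_id,
                    item.reason,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
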