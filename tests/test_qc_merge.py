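"""The quality-control cascade: filters, dedup, merging, standardization."""

import random

import pytest
from hypothesis import given, strategies as st

from qtlome import (
    GenomeAssembly,
    QCConfig,
    cluster_and_merge,
    deduplicate,
    densest_windows,
    filter_anomalies,
    run_qc,
    standardize_sizes,
)
from qtlome.qc_merge import MergeCluster, build_clusters

CFG = QCConfig()
ASM = GenomeAssembly(
    "toy", (("chr1", 10_000_000), ("chr2", 6_000_000), ("chr3", 3_000_000))
)


class TestFilterAnomalies:
    def test_zero_length_interval_is_anomalous(self, assembly, Q):
        kept, ledger, removed = filter_anomalies([Q(start=0, end=0)], assembly)
        assert kept == []
        assert ledger.anomalous_position == 1
        assert removed[0].reason == "anomalous_position"

    def test_over_length_removed(self, assembly, Q):
        kept, ledger, _ = filter_anomalies([Q(start=0, end=12_000_000, chrom="chr1")],
                                           assembly)
        # chr1 is 10 Mbp, so the boundary rule fires before the length rule
        assert ledger.out_of_bounds == 1
        kept, ledger, _ = filter_anomalies(
            [Q(start=0, end=12_000_000, chrom="chr1")],
            GenomeAssembly("big", (("chr1", 50_000_000),)),
        )
        assert ledger.over_length == 1

    def test_past_chromosome_end_is_out_of_bounds(self, assembly, Q):
        record = Q(chrom="chr3", start=2_995_000, end=3_005_000)
        kept, ledger, _ = filter_anomalies([record], assembly)
        assert ledger.out_of_bounds == 1

    def test_each_removal_has_exactly_one_reason(self, assembly, Q):
        # missing coordinates wins over everything else
        record = Q(chrom="chr99", start=None, end=None)
        _, ledger, _ = filter_anomalies([record], assembly)
        assert ledger.missing_coordinates == 1
        assert ledger.removed_total == 1


class TestDeduplicate:
    def test_identical_records_collapse(self, Q):
        a, b = Q(qtl_id="a"), Q(qtl_id="b")
        kept, delta = deduplicate([a, b])
        assert kept == [a] and delta == 1

    def test_same_interval_different_trait_both_kept(self, Q):
        a = Q(trait="growth")
        b = Q(trait="milk")
        kept, delta = deduplicate([a, b])
        assert len(kept) == 2 and delta == 0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_n_copies_leave_one(self, Q, n):
        records = [Q(qtl_id=f"c{i}") for i in range(n)]
        kept, delta = deduplicate(records)
        assert len(kept) == 1 and delta == n - 1

    def test_position_only_key_ignores_trait(self, Q):
        kept, delta = deduplicate([Q(trait="growth"), Q(trait="milk")], key="position")
        assert len(kept) == 1 and delta == 1


class TestClusterAndMerge:
    def test_sub_threshold_gap_merges(self, Q):
        a = Q(start=100_000, end=200_000)
        b = Q(start=650_000, end=700_000)  # gap 450 kbp < 500 kbp
        merged, delta = cluster_and_merge([a, b])
        assert delta == 1
        assert (merged[0].start, merged[0].end) == (100_000, 700_000)
        assert dict(merged[0].extra)["merged_ids"] == f"{a.qtl_id},{b.qtl_id}"

    def test_exact_threshold_gap_does_not_merge(self, Q):
        a = Q(start=100_000, end=200_000)
        b = Q(start=700_000, end=750_000)  # gap exactly 500 kbp
        merged, delta = cluster_and_merge([a, b])
        assert delta == 0 and len(merged) == 2

    def test_different_study_never_merges(self, Q):
        a = Q(start=0, end=100_000, study="S1")
        b = Q(start=50_000, end=150_000, study="S2")
        merged, delta = cluster_and_merge([a, b])
        assert delta == 0 and len(merged) == 2

    def test_merge_matches_pairwise_connected_components(self, Q):
        """Single-linkage chaining equals the O(n^2) components oracle."""
        rng = random.Random(7)
        for _ in range(200):
            n = rng.randint(1, 12)
            records = []
            for i in range(n):
                # multiples of 250 kbp exercise gap-exactly-500-kbp ties
                start = rng.randrange(0, 40) * 250_000
                length = rng.choice([1, 50_000, 250_000, 750_000])
                records.append(Q(start=start, end=start + length, qtl_id=f"r{i}"))
            clusters = build_clusters(records, CFG)
            got = {frozenset(m.qtl_id for m in c.members) for c in clusters}
            assert got == set(_component_oracle(records, CFG.merge_gap))


def _component_oracle(records, gap):
    """Brute-force union-find over the pairwise overlap-or-near relation."""
    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(records):
        for j, b in enumerate(records):
            if i < j and a.start < b.end + gap and b.start < a.end + gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, r in enumerate(records):
        groups.setdefault(find(i), set()).add(r.qtl_id)
    return [frozenset(g) for g in groups.values()]


class TestDensestWindows:
    def test_concentrated_members_need_one_window(self, Q):
        members = [Q(start=i * 100_000, end=i * 100_000 + 1_000, qtl_id=f"m{i}")
                   for i in range(8)]
        members.append(Q(start=2_800_000, end=3_000_000, qtl_id="tail"))
        cluster = MergeCluster(("chr1", "S1", "growth"), sorted(members, key=lambda r: r.start))
        assert cluster.span == 3_000_000
        # 0.9 Mbp of coverage is required; the first tile holds 8 of 9 midpoints
        assert densest_windows(cluster, CFG) == [(0, 1_000_000)]

    def test_uniform_members_over_10mbp_select_three_windows(self, Q):
        members = [Q(start=i * 250_000, end=i * 250_000 + 1_000, qtl_id=f"m{i}")
                   for i in range(40)]
        members.append(Q(start=9_999_000, end=10_000_000, qtl_id="tail"))
        cluster = MergeCluster(("chr1", "S1", "growth"), sorted(members, key=lambda r: r.start))
        selected = densest_windows(cluster, CFG)
        assert len(selected) == 3
        assert sum(e - s for s, e in selected) >= 0.30 * cluster.span
        # non-overlapping and sorted
        assert all(a[1] <= b[0] for a, b in zip(selected, selected[1:]))

    def test_short_span_is_a_contract_violation(self, Q):
        cluster = MergeCluster(("chr1", "S1", "growth"), [Q(start=0, end=500_000)])
        with pytest.raises(ValueError):
            densest_windows(cluster, CFG)

    def test_empty_cluster_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            densest_windows(MergeCluster(("chr1", "S1", "g"), []), CFG)


class TestStandardizeSizes:
    def test_point_record_expands_to_250kbp_around_midpoint(self, assembly, Q):
        (out,) = standardize_sizes([Q(start=1_234_567, end=1_234_568)], assembly)
        assert (out.start, out.end) == (1_109_567, 1_359_567)

    def test_long_record_trims_to_central_1mbp(self, assembly, Q):
        (out,) = standardize_sizes([Q(start=2_000_000, end=7_000_000)], assembly)
        assert (out.start, out.end) == (4_000_000, 5_000_000)

    def test_in_band_record_unchanged(self, assembly, Q):
        record = Q(start=1_000_000, end=1_300_000)
        assert standardize_sizes([record], assembly) == [record]

    def test_boundary_shifts_inward_preserving_length(self, assembly, Q):
        (out,) = standardize_sizes([Q(start=10_000, end=10_001)], assembly)
        assert (out.start, out.end) == (0, 250_000)
        (out,) = standardize_sizes([Q(chrom="chr3", start=2_999_000, end=2_999_001)],
                                   assembly)
        assert (out.start, out.end) == (2_750_000, 3_000_000)

    def test_chromosome_shorter_than_standard_clamps(self, Q):
        tiny = GenomeAssembly("tiny", (("chr1", 100_000),))
        (out,) = standardize_sizes([Q(start=10, end=11)], tiny)
        assert (out.start, out.end) == (0, 100_000)


interval_st = st.tuples(
    st.integers(0, 36).map(lambda k: k * 250_000),
    st.sampled_from([1, 100_000, 400_000, 2_000_000]),
)


@st.composite
def record_batch(draw, Q_factory=None):
    ivs = draw(st.lists(interval_st, min_size=0, max_size=25))
    studies = draw(st.lists(st.sampled_from(["S1", "S2"]), min_size=len(ivs),
                            max_size=len(ivs)))
    return list(zip(ivs, studies))


class TestCascadeProperties:
    @given(record_batch())
    def test_ledger_conservation_and_idempotence(self, batch):
        from qtlome import QTLRecord

        records = [
            QTLRecord("chr1", s, min(s + ln, 10_000_000), f"q{i}", "growth",
                      study_id=study)
            for i, ((s, ln), study) in enumerate(batch)
        ]
        out, ledger, _ = run_qc(records, ASM)
        assert ledger.conserves()
        again, ledger2, _ = run_qc(out, ASM)
        assert again == out
        assert ledger2.removed_total == 0

    @given(record_batch(), st.randoms(use_true_random=False))
    def test_shuffling_input_does_not_change_output(self, batch, rnd):
        from qtlome import QTLRecord

        records = [
            QTLRecord("chr1", s, min(s + ln, 10_000_000), f"q{i}", "growth",
                      study_id=study)
            for i, ((s, ln), study) in enumerate(batch)
        ]
        out1, _, _ = run_qc(records, ASM)
        shuffled = records[:]
        rnd.shuffle(shuffled)
        out2, _, _ = run_qc(shuffled, ASM)
        assert [(r.chrom, r.start, r.end) for r in out1] == [
            (r.chrom, r.start, r.end) for r in out2
        ]

    @given(record_batch())
    def test_output_lengths_inside_standard_band(self, batch):
        from qtlome import QTLRecord

        records = [
            QTLRecord("chr1", s, min(s + ln, 10_000_000), f"q{i}", "growth",
                      study_id=study)
            for i, ((s, ln), study) in enumerate(batch)
        ]
        out, _, _ = run_qc(records, ASM)
        for r in out:
            assert CFG.min_std_length <= r.length <= CFG.max_std_length
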