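import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uromark.discovery import (
    ConfigurationError,
    WindowConfig,
    annotate_tss,
    filter_windows,
    merge_candidates,
    sample_qc_summary,
    scan_windows,
)
from uromark.simulate import PlantedDmr, RrbsSimConfig, simulate_rrbs
from uromark.types import MethylationCalls, TssAnnotation, WindowStat


def make_window(chrom, start, end, sample_betas=None):
    sample_betas = sample_betas or {"t1": 0.8, "o1": 0.02}
    t = [b for s, b in sample_betas.items() if s.startswith("t")]
    o = [b for s, b in sample_betas.items() if s.startswith("o")]
    return WindowStat(
        chrom=chrom,
        start=start,
        end=end,
        n_cpgs=4,
        sample_betas=sample_betas,
        target_group_mean=float(np.mean(t)),
        offtarget_group_mean=float(np.mean(o)),
    )


def groups_for(samples):
    return {s.sample_id: s.sample_id.rsplit("_", 1)[0] for s in samples}


class TestScanWindows:
    def test_window_beta_is_unweighted_cpg_mean(self):
        # betas 0.0 and 1.0 with very different coverage -> mean 0.5
        t = MethylationCalls.from_records(
            "target_1", [("chr1", 10, 0, 100), ("chr1", 20, 10, 0)]
        )
        o = MethylationCalls.from_records(
            "offtarget_1", [("chr1", 10, 0, 50), ("chr1", 20, 0, 10)]
        )
        cfg = WindowConfig(window_sizes=(200,), min_cpgs_per_window=2, min_coverage_per_cpg=1)
        wins = scan_windows([t, o], groups_for([t, o]), cfg)
        assert len(wins) == 1
        assert wins[0].sample_betas["target_1"] == pytest.approx(0.5)
        assert wins[0].sample_betas["offtarget_1"] == pytest.approx(0.0)

    def test_low_coverage_cpg_excluded_from_count(self):
        recs = [("chr1", 10 + 5 * i, 5, 5) for i in range(4)]
        t = MethylationCalls.from_records("target_1", recs[:3] + [("chr1", 40, 5, 4)])
        o = MethylationCalls.from_records("offtarget_1", recs)
        cfg = WindowConfig(window_sizes=(200,), min_cpgs_per_window=4, min_coverage_per_cpg=10)
        # target sample has only 3 CpGs at coverage >= 10 -> no window emitted
        assert scan_windows([t, o], groups_for([t, o]), cfg) == []

    def test_planted_dmr_windows_match_brute_force(self):
        cfg = RrbsSimConfig(
            n_target_lines=4,
            n_offtarget_lines=4,
            n_cpgs=1500,
            planted_dmrs=[PlantedDmr("chr1", 100_000, 800, 20, 0.9, 0.05)],
            seed=42,
        )
        samples, truth = simulate_rrbs(cfg)
        groups = groups_for(samples)
        wcfg = WindowConfig()
        wins = scan_windows(samples, groups, wcfg)

        # oracle: recompute every emitted window per sample from raw records
        for w in wins:
            for s in samples:
                df = s.records
                sel = (
                    (df["chrom"] == w.chrom)
                    & (df["pos"] >= w.start)
                    & (df["pos"] < w.end)
                    & (df["n_meth"] + df["n_unmeth"] >= wcfg.min_coverage_per_cpg)
                )
                betas = df.loc[sel, "n_meth"] / (
                    df.loc[sel, "n_meth"] + df.loc[sel, "n_unmeth"]
                )
                assert sel.sum() >= wcfg.min_cpgs_per_window
                assert w.sample_betas[s.sample_id] == pytest.approx(betas.mean())

        region = truth[0]
        big = [w for w in wins if w.delta > 0.7]
        assert big, "no windows recovered the planted region"
        for w in big:
            assert w.start < region.end and region.start < w.end

    def test_empty_group_rejected(self, small_sample):
        with pytest.raises(ConfigurationError):
            scan_windows([small_sample], {"s1": "target"}, WindowConfig())

    def test_unknown_group_label_rejected(self, small_sample):
        with pytest.raises(ConfigurationError):
            scan_windows([small_sample], {"s1": "cases"}, WindowConfig())


class TestFilterWindows:
    def test_clean_separation_retained(self):
        betas = {f"t{i}": 0.8 for i in range(8)} | {f"o{i}": 0.02 for i in range(8)}
        w = make_window("chr1", 0, 200, betas)
        groups = {s: "target" if s.startswith("t") else "offtarget" for s in betas}
        assert filter_windows([w], groups) == [w]

    def test_single_hot_offtarget_sample_rejects(self):
        betas = {f"t{i}": 0.8 for i in range(8)} | {f"o{i}": 0.02 for i in range(8)}
        betas["o3"] = 0.5
        w = make_window("chr1", 0, 200, betas)
        groups = {s: "target" if s.startswith("t") else "offtarget" for s in betas}
        assert filter_windows([w], groups) == []

    def test_matches_row_by_row_predicate(self, rng):
        groups = {f"t{i}": "target" for i in range(8)}
        groups |= {f"o{i}": "offtarget" for i in range(8)}
        cfg = WindowConfig()
        windows = []
        for j in range(100):
            betas = {s: float(rng.random()) * (0.6 if g == "offtarget" else 1.0)
                     for s, g in groups.items()}
            windows.append(make_window("chr1", 200 * j, 200 * j + 200, betas))
        kept = filter_windows(windows, groups, cfg)
        expected = []
        for w in windows:
            t = [w.sample_betas[s] for s in groups if groups[s] == "target"]
            o = [w.sample_betas[s] for s in groups if groups[s] == "offtarget"]
            ok_t = sum(b >= cfg.min_target_beta for b in t) / len(t) >= cfg.min_target_fraction
            ok_o = sum(b > cfg.max_offtarget_beta for b in o) / len(o) <= cfg.max_offtarget_fraction
            if ok_t and ok_o:
                expected.append(w)
        assert kept == expected


def merge_oracle(intervals):
    """O(n^2) transitive-closure merge by union-find."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    merged = {}
    for i in range(n):
        r = find(i)
        c, s, e = intervals[i]
        if r in merged:
            _, ms, me = merged[r]
            merged[r] = (c, min(ms, s), max(me, e))
        else:
            merged[r] = (c, s, e)
    return sorted(merged.values())


class TestMergeCandidates:
    def test_overlap_union(self):
        wins = [make_window("chr1", 100, 300), make_window("chr1", 200, 1200)]
        cands = merge_candidates(wins)
        assert [(c.chrom, c.start, c.end) for c in cands] == [("chr1", 100, 1200)]
        assert len(cands[0].source_windows) == 2

    def test_abutting_half_open_does_not_merge(self):
        wins = [make_window("chr1", 100, 300), make_window("chr1", 300, 500)]
        assert len(merge_candidates(wins)) == 2

    def test_matches_union_find_oracle(self, rng):
        for _ in range(50):
            intervals = []
            for _ in range(rng.integers(1, 50)):
                chrom = f"chr{rng.integers(1, 3)}"
                start = int(rng.integers(0, 5000))
                intervals.append((chrom, start, start + int(rng.integers(100, 1200))))
            wins = [make_window(c, s, e) for c, s, e in intervals]
            got = [(c.chrom, c.start, c.end) for c in merge_candidates(wins)]
            assert got == merge_oracle(intervals)

    @settings(deadline=None, max_examples=80)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 3000),
                st.integers(1, 800),
            ),
            max_size=25,
        ),
        st.randoms(use_true_random=False),
    )
    def test_idempotent_and_order_invariant(self, raw, shuffler):
        wins = [make_window(c, s, s + span) for c, s, span in raw]
        base = [(c.chrom, c.start, c.end) for c in merge_candidates(wins)]
        shuffled = list(wins)
        shuffler.shuffle(shuffled)
        assert [(c.chrom, c.start, c.end) for c in merge_candidates(shuffled)] == base
        # idempotence: re-merging the merged candidates changes nothing
        remerged = merge_candidates(
            [make_window(c, s, e) for c, s, e in base]
        )
        assert [(c.chrom, c.start, c.end) for c in remerged] == base


class TestAnnotateTss:
    @pytest.fixture
    def tss(self):
        return TssAnnotation(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1", "chr1"],
                    "tss_pos": [3000, 5100, 6700],
                    "strand": ["+", "-", "+"],
                    "gene_id": ["a", "b", "c"],
                }
            )
        )

    def make_candidate(self, start, end):
        return merge_candidates([make_window("chr1", start, end)])

    def test_distance_to_upstream_tss(self, tss):
        only = TssAnnotation(tss.entries.iloc[[0]])
        (c,) = annotate_tss(self.make_candidate(5000, 5200), only)
        assert c.tss_distance == 2000 and c.distal is True

    def test_tss_inside_gives_zero(self, tss):
        (c,) = annotate_tss(self.make_candidate(5000, 5200), tss)
        assert c.tss_distance == 0 and c.distal is False

    def test_distal_boundary_is_strict(self, tss):
        only = TssAnnotation(tss.entries.iloc[[2]])
        (c,) = annotate_tss(self.make_candidate(5000, 5200), only)
        assert c.tss_distance == 1500 and c.distal is False

    def test_missing_chromosome_flagged(self, tss):
        cand = merge_candidates([make_window("chrZ", 0, 200)])
        (c,) = annotate_tss(cand, tss)
        assert c.tss_distance is None and c.distal is None


class TestQcSummary:
    def test_two_cpg_example(self):
        s = MethylationCalls.from_records(
            "x", [("chr1", 1, 5, 5), ("chr1", 2, 10, 0)]
        )
        qc = sample_qc_summary(s)
        assert qc.mean_coverage == pytest.approx(10.0)
        assert qc.mean_beta == pytest.approx(0.75)

    def test_fully_unmethylated(self):
        s = MethylationCalls.from_records(
            "x", [("chr1", 1, 0, 5), ("chr1", 2, 0, 9)]
        )
        assert sample_qc_summary(s).mean_beta == 0.0

    def test_matches_independent_recomputation(self, rng):
        n = 1000
        pos = np.sort(rng.choice(10_000_000, n, replace=False))
        m = rng.integers(0, 40, n)
        u = rng.integers(1, 40, n)
        s = MethylationCalls.from_records(
            "x", list(zip(["chr1"] * n, pos.tolist(), m.tolist(), u.tolist()))
        )
        qc = sample_qc_summary(s)
        assert qc.mean_coverage == pytest.approx(np.mean(m + u))
        assert qc.mean_beta == pytest.approx(np.mean(m / (m + u)))
        assert qc.n_cpgs == n
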