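"""Exome segment calling, sliding-window profiles and the per-cell CNV test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellverdict import cnv, io
from conftest import make_matrix


def brute_force_runs(ratios, starts, ends, delta, min_span):
    """Independent run-scan oracle: enumerate every maximal run directly."""
    state = [1 if r > 1 + delta else (-1 if r < 1 - delta else 0) for r in ratios]
    out = []
    n = len(state)
    for i in range(n):
        for j in range(i, n):
            seg = state[i : j + 1]
            if 0 in seg or len(set(seg)) != 1:
                continue
            # maximality
            if i > 0 and state[i - 1] == state[i]:
                continue
            if j < n - 1 and state[j + 1] == state[j]:
                continue
            if ends[j] - starts[i] >= min_span:
                out.append((starts[i], ends[j], "gain" if state[i] == 1 else "loss"))
    return out


class TestExomeSegments:
    def test_flat_ratios_give_no_segments(self):
        bins = pd.DataFrame(
            {"chrom": "chr1", "start": range(0, 50, 10), "end": range(10, 60, 10),
             "depth_ratio": 1.0}
        )
        assert cnv.call_exome_segments(bins, min_span=1) == []

    def test_chr7_gain_and_chr10_loss_pattern(self):
        rows = []
        for chrom, ratio in [("chr7", 1.5), ("chr10", 0.5)]:
            for start in range(0, 40_000_000, 2_000_000):
                rows.append((chrom, start, start + 2_000_000, ratio))
        segs = cnv.call_exome_segments(pd.DataFrame(rows, columns=["chrom", "start", "end", "depth_ratio"]), delta=0.2)
        by_chrom = {s.chrom: s for s in segs}
        assert by_chrom["chr7"].direction == "gain" and by_chrom["chr7"].whole_chromosome
        assert by_chrom["chr10"].direction == "loss" and by_chrom["chr10"].whole_chromosome

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_bins_match_run_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        starts = np.arange(n) * 1_000_000
        ends = starts + 1_000_000
        ratios = rng.choice([0.4, 0.9, 1.0, 1.1, 1.6], size=n)
        bins = pd.DataFrame(
            {"chrom": "chr3", "start": starts, "end": ends, "depth_ratio": ratios}
        )
        got = [
            (s.start, s.end, s.direction)
            for s in cnv.call_exome_segments(bins, delta=0.2, min_span=2_000_000)
        ]
        assert got == brute_force_runs(ratios, starts, ends, 0.2, 2_000_000)

    def test_empty_bins_warn_and_return_nothing(self, caplog):
        bins = pd.DataFrame(columns=["chrom", "start", "end", "depth_ratio"])
        with caplog.at_level("WARNING"):
            assert cnv.call_exome_segments(bins) == []
        assert "empty" in caplog.text


def _cpm(values, genes, cells):
    return io.to_cpm(make_matrix(values, genes, cells))


class TestWindowProfile:
    def test_single_window_hand_computation(self):
        # one window, tumor window mean 4, control mean 2, pseudocount 0 -> log2fc 1
        genes = ["a", "b"]
        order = {"chr1": genes}
        tumor = make_matrix([[4.0], [4.0]], genes, ["t1"], unit=io.CPM)
        control = make_matrix([[2.0], [2.0]], genes, ["n1"], unit=io.CPM)
        prof = cnv.window_log2fc(tumor, control, order, w=2, pseudocount=0.0)
        assert prof.data["log2fc"].tolist() == pytest.approx([1.0])

    def test_window_count_is_n_minus_w_plus_one(self, bundle, biopsy_cpm, control_cpm):
        order = io.order_genes(bundle.annotation, biopsy_cpm.gene_ids)
        prof = cnv.window_log2fc(biopsy_cpm, control_cpm, order, w=100)
        for chrom, genes in order.items():
            n_win = prof.data[prof.data["chrom"] == chrom]["window_index"].nunique()
            assert n_win == len(genes) - 100 + 1

    def test_short_chromosome_yields_zero_windows(self):
        genes = ["a", "b", "c"]
        order = {"chr1": ["a", "b"], "chr2": ["c"]}
        tumor = make_matrix([[1.0]] * 3, genes, ["t1"], unit=io.CPM)
        control = make_matrix([[1.0]] * 3, genes, ["n1"], unit=io.CPM)
        prof = cnv.window_log2fc(tumor, control, order, w=2)
        assert set(prof.data["chrom"]) == {"chr1"}
        assert prof.skipped_chroms == ("chr2",)

    def test_matches_brute_force_loop_oracle(self):
        rng = np.random.default_rng(11)
        n_genes, n_cells, n_ctrl, w = 180, 20, 15, 7
        genes = [f"g{i:03d}" for i in range(n_genes)]
        order = {"chr1": genes[:100], "chr2": genes[100:]}
        tumor = make_matrix(rng.gamma(2, 50, (n_genes, n_cells)), genes,
                            [f"t{i}" for i in range(n_cells)], unit=io.CPM)
        control = make_matrix(rng.gamma(2, 50, (n_genes, n_ctrl)), genes,
                              [f"n{i}" for i in range(n_ctrl)], unit=io.CPM)
        pc = 1.0
        prof = cnv.window_log2fc(tumor, control, order, w=w, pseudocount=pc)
        # brute force: explicit loops, control as mean over cells of window means
        for chrom, chrom_genes in order.items():
            mat = prof.matrix(chrom)
            for i in range(len(chrom_genes) - w + 1):
                win = chrom_genes[i : i + w]
                c_means = [control.values.loc[win, c].mean() for c in control.cell_ids]
                c_stat = float(np.mean(c_means))
                for cell in tumor.cell_ids:
                    t_stat = float(tumor.values.loc[win, cell].mean())
                    expected = np.log2((t_stat + pc) / (c_stat + pc))
                    assert mat.loc[cell, i] == pytest.approx(expected, abs=1e-12)

    def test_control_self_normalization_is_centered(self, bundle, control_cpm):
        # control cells fed in as the "tumor" input: cell-averaged window
        # values should sit near zero
        order = io.order_genes(bundle.annotation, control_cpm.gene_ids)
        half = control_cpm.subset_cells(list(control_cpm.cell_ids[:50]))
        prof = cnv.window_log2fc(half, control_cpm, order, w=100)
        window_means = prof.data.groupby(["chrom", "window_index"])["log2fc"].mean()
        assert window_means.abs().mean() < 0.05

    def test_requires_cpm(self):
        m = make_matrix([[1.0], [1.0]], ["a", "b"], ["c1"])
        with pytest.raises(ValueError, match="CPM"):
            cnv.window_log2fc(m, m, {"chr1": ["a", "b"]})


class TestPresenceTest:
    def test_control_median_is_absent_at_quantile_half(self):
        controls = np.arange(1, 202, dtype=float)  # median 101
        call, q, warn = cnv.test_cnv_presence(101.0, controls, "gain")
        assert (call, q, warn) == ("absent", 0.5, None)

    def test_extreme_low_value_is_present_loss(self):
        rng = np.random.default_rng(3)
        controls = rng.normal(1000, 50, 200)
        value = controls.min() - 100
        call, q, _ = cnv.test_cnv_presence(value, controls, "loss")
        assert call == "present" and q < 0.005
        # exhaustive rank oracle
        assert q == (np.sum(controls < value) + 0.5 * np.sum(controls == value)) / 200

    def test_degenerate_controls_yield_absent_with_warning(self):
        call, _, warn = cnv.test_cnv_presence(5.0, np.full(30, 1.0), "gain")
        assert call == "absent" and warn == "degenerate_control"

    def test_control_floor_enforced(self):
        with pytest.raises(ValueError, match="control"):
            cnv.test_cnv_presence(1.0, np.arange(10.0), "gain")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.floats(0, 1e5, allow_nan=False), min_size=25, max_size=60),
        st.floats(0, 1e5, allow_nan=False),
        st.floats(1.0, 3.0),
    )
    def test_uniform_scaling_up_never_lowers_gain_quantile(self, controls, value, factor):
        controls = np.asarray(controls)
        q1 = cnv.empirical_quantile(value, controls)
        q2 = cnv.empirical_quantile(value * factor, controls)
        assert q2 >= q1 - 1e-12


class TestSegmentStatistic:
    def test_sum_total_cpm_over_segment_genes(self):
        m = _cpm([[1, 2], [3, 4], [6, 4]], ["a", "b", "c"], ["c1", "c2"])
        stat = cnv.segment_statistic(m, ["a", "c"])
        assert stat["c1"] == pytest.approx((1 + 6) / 10 * 1e6)
        assert stat["c2"] == pytest.approx((2 + 4) / 10 * 1e6)

    def test_whole_chromosome_segment_uses_all_annotated_genes(self, bundle):
        seg = cnv.CnvSegment("chr10", 0, 1, "loss", 0.55, whole_chromosome=True)
        genes = cnv.segment_genes(seg, bundle.annotation)
        ann10 = bundle.annotation[bundle.annotation["chrom"] == "chr10"]
        assert genes == ann10.sort_values(["start", "gene_id"])["gene_id"].tolist()
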