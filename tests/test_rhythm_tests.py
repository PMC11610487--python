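import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waspclock._exact import sf_from_pmf, umbrella_null_pmf
from waspclock.core_io import ExpressionMatrix, PipelineConfig, ValidationError
from waspclock.rhythm_tests import (bh_adjust, detect_rhythmic, tau_batch,
                                    tau_test, umbrella_batch, umbrella_test)

N_SHAPES = 30  # k * (k - 1) umbrella orderings for the 6-group default design


class TestBHAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.4] * 5), [0.4] * 5)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_order_preserving_and_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestUmbrellaTest:
    def test_perfectly_ordered_series_attains_extreme_p(self, dd_design):
        """A series strictly concordant with one shape reaches S_max and
        p = n_shapes * P(S = S_max), checked against the exact null."""
        # rising CT13->CT1 over groups 3,4,5,0; falling 0,1,2,3 (peak group 0)
        group_rank = {3: 0, 4: 1, 5: 2, 0: 3, 1: 2.5, 2: 1.2}
        y = np.empty(12)
        for s in range(12):
            g = s % 6
            y[s] = group_rank[g] * 10 + (1 if s >= 6 else 0)  # no ties
        p, phase, shape = umbrella_test(y, dd_design)
        assert shape == (0, 3)
        assert phase == 1.0
        pmf = umbrella_null_pmf(6, 2, 3)
        assert p == pytest.approx(N_SHAPES * pmf[-1], rel=1e-12)

    def test_rank_invariance_under_monotone_transform(self, dd_design):
        rng = np.random.default_rng(2)
        y = rng.uniform(1, 50, 12)
        p0, ph0, s0 = umbrella_test(y, dd_design)
        p1, ph1, s1 = umbrella_test(np.exp(y / 10.0), dd_design)
        assert (p0, ph0, s0) == (p1, ph1, s1)

    def test_constant_series_p_is_one(self, dd_design):
        p, phase, _ = umbrella_test(np.full(12, 3.3), dd_design)
        assert p == 1.0

    def test_batch_matches_single(self, dd_design):
        rng = np.random.default_rng(3)
        Y = rng.uniform(1, 10, (5, 12))
        p, phase, _ = umbrella_batch(Y, dd_design)
        for i in range(5):
            pi, phi, _ = umbrella_test(Y[i], dd_design)
            assert pi == pytest.approx(p[i]) and phi == phase[i]

    def test_null_is_conservative(self, dd_design):
        rng = np.random.default_rng(4)
        p, _, _ = umbrella_batch(rng.normal(size=(2000, 12)), dd_design)
        grid = np.linspace(0.005, 1, 100)
        ecdf = (p[:, None] <= grid[None, :]).mean(axis=0)
        assert (ecdf - grid).max() <= 1.63 / np.sqrt(2000)  # one-sided KS 99%


class TestTauTest:
    def test_noiseless_cosine_recovers_phase_at_minimal_p(self, dd_design, times):
        y = np.cos(2 * np.pi * (times - 4.0) / 24.0) + np.linspace(0, 1e-6, 12)
        p, phase = tau_test(y, dd_design)
        assert phase == pytest.approx(5.0)  # nearest grid acrophase to CT4
        # minimal attainable: perfect concordance with the (2,4,4,2) tie-block
        # reference, times Bonferroni over the 6 phases
        from waspclock._exact import jt_null_pmf
        pmf = jt_null_pmf((2, 4, 4, 2))
        assert p == pytest.approx(6 * pmf[-1], rel=1e-9)

    def test_time_reversal_mirrors_phase(self, dd_design, times):
        rng = np.random.default_rng(5)
        y = np.cos(2 * np.pi * (times - 9.0) / 24.0) + rng.normal(0, 0.05, 12)
        p0, ph0 = tau_test(y, dd_design)
        p1, ph1 = tau_test(y[::-1], dd_design)
        assert p0 == pytest.approx(p1, rel=1e-9)
        # reversing time about the sampling window maps peak t* -> t0+t45-t*
        expected = (1.0 + 45.0 - ph0) % 24.0
        assert ph1 % 24.0 == pytest.approx(expected % 24.0)

    def test_cyclic_shift_shifts_phase_by_interval(self, dd_design, times):
        rng = np.random.default_rng(6)
        y = np.cos(2 * np.pi * (times - 13.0) / 24.0) + rng.normal(0, 0.05, 12)
        p0, ph0 = tau_test(y, dd_design)
        # shifting the series one sampling step later in time
        y_shift = np.roll(y, 1)
        p1, ph1 = tau_test(y_shift, dd_design)
        assert p1 == pytest.approx(p0, rel=1e-9)
        assert ph1 == pytest.approx((ph0 + 4.0) % 24.0)

    def test_constant_series_p_is_one(self, dd_design):
        p, _ = tau_test(np.zeros(12), dd_design)
        assert p == 1.0


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 10_000))
def test_umbrella_p_in_unit_interval_and_phase_on_grid(seed):
    from waspclock.core_io import TimeDesign
    design = TimeDesign("DD")
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 100, 12)
    p, phase, _ = umbrella_test(y, design)
    assert 0 < p <= 1
    assert phase in {1.0, 5.0, 9.0, 13.0, 17.0, 21.0}


class TestDetectRhythmic:
    def test_global_null_yields_no_discoveries(self, dd_design):
        rng = np.random.default_rng(7)
        mat = ExpressionMatrix(
            transcript_ids=np.array([f"T{i}" for i in range(1500)], dtype=object),
            values=np.exp(rng.normal(2, 0.3, (1500, 12))), design=dd_design)
        table, summary = detect_rhythmic(mat)
        assert summary["n_rhythmic_strict"] <= 5
        assert (table["q_umbrella"] >= table["p_umbrella"] - 1e-12).all()

    def test_strong_rhythms_are_detected_with_correct_phase(self, dd_design, times):
        """High-amplitude cosines against a flat background: detection at
        q < 0.1 recovers them with phases within one sampling interval."""
        rng = np.random.default_rng(8)
        n_sig, n_null = 60, 900
        phases = rng.choice([1.0, 9.0, 17.0], n_sig)
        sig = 3.0 ** (np.cos(2 * np.pi * (times[None, :] - phases[:, None]) / 24.0) / 2)
        base = np.ones((n_null, 12))
        Y = np.vstack([sig, base]) * np.exp(rng.normal(0, 0.1, (n_sig + n_null, 12)))
        mat = ExpressionMatrix(
            transcript_ids=np.array([f"T{i}" for i in range(len(Y))], dtype=object),
            values=Y * 20, design=dd_design)
        table, summary = detect_rhythmic(mat)
        hit = table["q_umbrella"] < 0.1
        truth = np.arange(len(Y)) < n_sig
        sens = hit[truth].mean()
        assert sens >= 0.9
        fdr = (~truth[hit]).mean() if hit.any() else 0.0
        assert fdr <= 0.1
        tp = hit.to_numpy() & truth
        d = np.abs((table["phase_umbrella"].to_numpy()[tp] - phases[tp[:n_sig]] + 12) % 24 - 12)
        assert (d <= 4.0).mean() >= 0.95
        assert 0 <= summary["tau_agreement"] <= 1

    def test_gene_level_mode_only_changes_multi_transcript_genes(self, dd_design):
        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 30, (6, 12))
        genes = np.array(["g1", "g1", "g2", "g3", "g4", "g5"], dtype=object)
        mat = ExpressionMatrix(
            transcript_ids=np.array([f"t{i}" for i in range(6)], dtype=object),
            values=vals, design=dd_design, gene_ids=genes)
        t_tab, _ = detect_rhythmic(mat)
        g_tab, _ = detect_rhythmic(mat, gene_level=True)
        g_tab = g_tab.set_index("transcript_id")
        t_tab = t_tab.set_index("transcript_id")
        # single-transcript genes keep their transcript-level p
        for t, g in (("t2", "g2"), ("t3", "g3"), ("t4", "g4"), ("t5", "g5")):
            assert g_tab.loc[g, "p_umbrella"] == t_tab.loc[t, "p_umbrella"]
        assert len(g_tab) == 5
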