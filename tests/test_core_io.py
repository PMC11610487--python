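import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waspclock.core_io import (ExpressionMatrix, FormatError, PipelineConfig,
                               TimeDesign, ValidationError, normalize,
                               read_expression, reliable_mask, size_factors,
                               write_expression)


class TestTimeDesign:
    def test_default_design_is_twelve_points_every_4h(self, dd_design):
        assert len(dd_design.times) == 12
        assert dd_design.interval == 4.0
        assert dd_design.span == 48.0
        assert dd_design.times[0] == 1.0 and dd_design.times[-1] == 45.0

    def test_phase_groups_fold_two_cycles(self, dd_design):
        assert dd_design.n_phase_groups(24.0) == 6
        grp = dd_design.phase_groups(24.0)
        assert list(grp) == [0, 1, 2, 3, 4, 5] * 2
        assert list(dd_design.group_centers()) == [1.0, 5.0, 9.0, 13.0, 17.0, 21.0]

    @pytest.mark.parametrize("times", [(1.0,), (1, 5, 8), (5, 1, 9)])
    def test_irregular_times_rejected(self, times):
        with pytest.raises(ValidationError):
            TimeDesign("DD", tuple(float(t) for t in times))

    def test_interval_must_divide_period(self):
        d = TimeDesign("DD", tuple(1.0 + 5.0 * i for i in range(10)))
        with pytest.raises(ValidationError):
            d.n_phase_groups(24.0)


class TestReadWrite:
    def test_round_trip_preserves_values(self, tmp_path, dd_design):
        rng = np.random.default_rng(0)
        mat = ExpressionMatrix(
            transcript_ids=np.array([f"T{i}" for i in range(3)], dtype=object),
            values=rng.uniform(1, 100, (3, 12)),
            design=dd_design,
            gene_ids=np.array(["G0", "G0", "G1"], dtype=object),
        )
        path = tmp_path / "m.tsv"
        write_expression(mat, path)
        back = read_expression(path, dd_design)
        assert back.n_transcripts == 3
        np.testing.assert_allclose(back.values, mat.values)
        assert list(back.gene_ids) == list(mat.gene_ids)

    def test_missing_value_drops_transcript(self, tmp_path, dd_design):
        df = pd.DataFrame(np.ones((3, 12), dtype=object),
                          columns=dd_design.sample_names())
        df.insert(0, "transcript_id", ["a", "b", "c"])
        df.iloc[1, 3] = "NA"
        path = tmp_path / "na.tsv"
        df.to_csv(path, sep="\t", index=False)
        mat = read_expression(path, dd_design)
        assert list(mat.transcript_ids) == ["a", "c"]

    def test_column_count_mismatch_is_format_error(self, tmp_path, dd_design):
        df = pd.DataFrame(np.ones((2, 11)))
        df.insert(0, "transcript_id", ["a", "b"])
        path = tmp_path / "short.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError):
            read_expression(path, dd_design)

    def test_negative_values_rejected(self, tmp_path, dd_design):
        df = pd.DataFrame(np.ones((1, 12)), columns=dd_design.sample_names())
        df.iloc[0, 5] = -1.0
        df.insert(0, "transcript_id", ["a"])
        path = tmp_path / "neg.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError):
            read_expression(path, dd_design)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        v = np.tile(np.array([[3.0], [7.0], [1.0]]), (1, 4))
        np.testing.assert_allclose(size_factors(v), np.ones(4))

    def test_doubled_sample_gets_double_factor(self):
        v = np.array([[2.0, 1.0]])
        f = size_factors(v)
        assert f[0] / f[1] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.5, 50, (20, 4))
        # independent oracle: literal median-of-ratios with per-row geometric means
        ref = []
        gm = [np.prod(row) ** (1 / 4) for row in v]
        for j in range(4):
            ref.append(np.median([v[i, j] / gm[i] for i in range(20)]))
        np.testing.assert_allclose(size_factors(v), ref, rtol=1e-12)

    def test_zero_rows_excluded_from_geometric_mean(self):
        v = np.array([[0.0, 5.0], [4.0, 1.0]])
        f = size_factors(v)  # only the all-positive row informs the factors
        np.testing.assert_allclose(f, [2.0, 0.5])

    def test_no_positive_transcript_is_an_error(self):
        with pytest.raises(ValidationError):
            size_factors(np.array([[0.0, 1.0], [2.0, 0.0]]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 3), st.floats(0.1, 10.0))
    def test_scale_equivariance_up_to_common_rescaling(self, col, c):
        """Scaling one column by c scales its factor by c relative to the
        others (factors are defined up to a common multiplicative constant)."""
        rng = np.random.default_rng(7)
        v = rng.uniform(0.5, 20, (15, 4))
        f0 = size_factors(v)
        v2 = v.copy()
        v2[:, col] *= c
        f1 = size_factors(v2)
        other = (col + 1) % 4
        assert f1[col] / f1[other] == pytest.approx(c * f0[col] / f0[other], rel=1e-9)

    def test_normalize_divides_by_factors(self, dd_design):
        rng = np.random.default_rng(3)
        mat = ExpressionMatrix(
            transcript_ids=np.array([f"T{i}" for i in range(5)], dtype=object),
            values=rng.uniform(1, 10, (5, 12)), design=dd_design)
        out = normalize(mat)
        np.testing.assert_allclose(out.values * size_factors(mat.values), mat.values)


class TestReliableMask:
    def test_floor_is_inclusive(self, dd_design):
        vals = np.vstack([np.full(12, 5.0), np.full(12, 5.0), np.zeros(12)])
        vals[1, 4] = 4.9
        mat = ExpressionMatrix(
            transcript_ids=np.array(["hi", "dip", "zero"], dtype=object),
            values=vals, design=dd_design)
        assert list(reliable_mask(mat, 5.0)) == [True, False, False]

    def test_monotone_in_floor(self, dd_design, small_sim):
        _, dd, _, _ = small_sim
        m1 = reliable_mask(dd, 2.0)
        m2 = reliable_mask(dd, 5.0)
        assert not (m2 & ~m1).any()


class TestPipelineConfig:
    def test_defaults_are_study_constants(self):
        c = PipelineConfig()
        assert (c.rain_q_strict, c.rain_q_broad, c.jtk_q) == (0.1, 0.2, 0.6)
        assert c.reliable_fpkm_min == 5.0 and c.fc_cutoff == 1.5
        assert c.n_clusters == 30 and c.fuzzifier_m == 1.25

    def test_grid_spans_20_to_28_in_fifth_hours(self):
        g = PipelineConfig().grid()
        assert g[0] == 20.0 and g[-1] == 28.0 and len(g) == 41
        assert np.allclose(np.diff(g), 0.2)

    @pytest.mark.parametrize("kw", [{"rain_q_strict": 0.0}, {"jtk_q": 1.5},
                                    {"fc_cutoff": 1.0},
                                    {"period_grid": (28.0, 20.0, 0.2)}])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            PipelineConfig(**kw)
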