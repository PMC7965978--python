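import numpy as np
import pandas as pd
import pytest

from crossclass.generate import (
    _level2_feeder_aggregate,
    build_feeder_structure,
    draw_group_sizes,
    generate_dataset,
    generate_level2_effects,
    read_dataset_csv,
    write_dataset_csv,
)
from helpers import make_dataset


class TestFeederStructure:
    def test_each_column_has_f_distinct_feeders(self, rng):
        st = build_feeder_structure(30, 30, 2, rng)
        assert st.n_feeders == 2
        for rows in st.feeders_of.values():
            assert len(set(rows)) == 2
            assert all(0 <= k < 30 for k in rows)

    def test_f_equal_to_rows_forces_full_set(self, rng):
        st = build_feeder_structure(30, 30, 30, rng)
        for rows in st.feeders_of.values():
            assert sorted(rows) == list(range(30))

    def test_same_seed_gives_identical_structure(self):
        a = build_feeder_structure(30, 30, 4, np.random.default_rng(5))
        b = build_feeder_structure(30, 30, 4, np.random.default_rng(5))
        assert a.feeders_of == b.feeders_of

    def test_too_many_feeders_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feeder_structure(30, 30, 31, rng)

    def test_matched_link_includes_home_row(self, rng):
        st = build_feeder_structure(20, 20, 3, rng, link_matched=True)
        for j, rows in st.feeders_of.items():
            assert j in rows


class TestGroupSizes:
    def test_zero_sd_is_degenerate(self, rng):
        assert (draw_group_sizes(30, 40, 0.0, rng) == 40).all()

    def test_sample_mean_matches_normal(self):
        sizes = draw_group_sizes(10000, 20, 2.0, np.random.default_rng(42))
        assert abs(sizes.mean() - 20) < 0.1

    def test_sizes_cluster_around_mean_and_floor_at_one(self, rng):
        sizes = draw_group_sizes(30, 40, 2.0, rng)
        assert ((sizes > 30) & (sizes < 50)).all()
        tiny = draw_group_sizes(200, 1.5, 3.0, rng)
        assert (tiny >= 1).all()


class TestLevel2Effects:
    def test_zero_variance_gives_zero_vectors(self, rng):
        b, c = generate_level2_effects(10, 10, 0.0, 0.4, rng)
        assert not b.any() and not c.any()

    def test_matched_pairs_have_requested_correlation(self):
        rng = np.random.default_rng(3)
        b, c = generate_level2_effects(5000, 5000, 0.2143, 0.4, rng)
        assert abs(np.corrcoef(b, c)[0, 1] - 0.4) < 0.03
        assert abs(b.var() / 0.2143 - 1) < 0.05
        assert abs(c.var() / 0.2143 - 1) < 0.05

    def test_independent_when_rho_zero(self):
        rng = np.random.default_rng(3)
        b, c = generate_level2_effects(5000, 5000, 1.0, 0.0, rng)
        assert abs(np.corrcoef(b, c)[0, 1]) < 0.05

    def test_correlation_requires_equal_counts(self, rng):
        with pytest.raises(ValueError):
            generate_level2_effects(10, 12, 1.0, 0.4, rng)

    def test_feeder_aggregate_preserves_marginals_and_links(self):
        rng = np.random.default_rng(9)
        st = build_feeder_structure(4000, 4000, 2, rng)
        b, c = _level2_feeder_aggregate(st, 0.2143, 0.2143, 0.4, rng)
        assert abs(b.var() / 0.2143 - 1) < 0.05
        assert abs(c.var() / 0.2143 - 1) < 0.05
        ftab = np.array([st.feeders_of[j] for j in range(4000)])
        agg = c[ftab].sum(axis=1) / np.sqrt(2 * 0.2143)
        assert abs(np.corrcoef(b, agg)[0, 1] - 0.4) < 0.03


class TestGenerateDataset:
    def test_membership_and_group_constant_invariants(self):
        ds, cond, _ = make_dataset(groups=30, size=20.0, f=2, seed=11)
        rec = ds.records
        for j, sub in rec.groupby("j"):
            assert set(sub["k"]).issubset(set(ds.structure.feeders_of[j]))
            assert sub["w"].nunique() == 1
        for _, sub in rec.groupby("k"):
            assert sub["z"].nunique() == 1
        assert rec.groupby("j").size().min() >= 1

    def test_pure_function_of_seed(self):
        a, *_ = make_dataset(groups=10, seed=3)
        b, *_ = make_dataset(groups=10, seed=3)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_outcome_mean_matches_expectation(self):
        # E[Y] = 100 + mc * 3 * 50 = 130 at mc = 0.2
        ds, *_ = make_dataset(mc=0.2, f=4, groups=200, size=40.0, iucc=0.05, seed=2)
        assert ds.n > 7000
        assert abs(ds.records["y"].mean() - 130.0) < 1.0

    def test_noise_free_limit_reproduces_linear_predictor(self):
        ds, cond, params = make_dataset(
            mc=0.5, groups=10, iucc=0.0, seed=4, sigma2_override=1e-12
        )
        rec = ds.records
        lin = 100 + 0.5 * (rec["x"] + rec["w"] + rec["z"])
        assert np.abs(rec["y"] - lin).max() < 1e-4

    def test_ols_recovers_slopes_on_large_sample(self):
        ds, *_ = make_dataset(mc=0.5, f=4, groups=500, size=100.0, iucc=0.05, seed=6)
        rec = ds.records
        X = np.column_stack(
            [np.ones(ds.n), rec["x"], rec["w"], rec["z"]]
        )
        beta, *_ = np.linalg.lstsq(X, rec["y"].to_numpy(), rcond=None)
        assert np.allclose(beta[1:], 0.5, atol=0.02)

    def test_residual_variance_decomposition(self):
        # conditional on groups the residual SD is sigma = 1; marginally the
        # level-2 effects add 2 * tau
        tau = 0.2143
        resid_all = []
        for rep in range(40):
            ds, cond, params = make_dataset(
                mc=0.5, f=2, groups=30, size=20.0, iucc=0.15, seed=13, rep=rep
            )
            rec = ds.records
            lin = 100 + 0.5 * (rec["x"] + rec["w"] + rec["z"])
            resid_all.append(rec["y"] - lin)
        marginal = np.concatenate(resid_all).var()
        assert abs(marginal - (2 * tau + 1.0)) < 0.05

    def test_csv_round_trip(self, tmp_path):
        ds, *_ = make_dataset(groups=6, seed=8)
        path = tmp_path / "data.csv"
        write_dataset_csv(ds, path)
        back = read_dataset_csv(path)
        pd.testing.assert_frame_equal(ds.records, back.records)
        assert back.structure.feeders_of == ds.structure.feeders_of
        assert back.truth == ds.truth
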