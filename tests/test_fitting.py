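"""Model-matrix fitting and model comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eventrsa import (
    build_model_matrix,
    compare_model_fits,
    encoding_similarity_matrix,
    group_fit,
    point_biserial_fit,
    rm_anova_fits,
    subject_fit_table,
    tukey_hsd,
)
from eventrsa.design import ModelMatrix


def _brute_pearson(x, y):
    """Independent covariance-based Pearson oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).sum()
    return cov / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())


def _sim_from_lower_half_colmajor(lower, n):
    """Fill a symmetric matrix from a column-major lower-half listing
    ((0,0), (1,0), (2,0), (1,1), ...)."""
    m = np.zeros((n, n))
    rows, cols = np.triu_indices(n)  # upper row-major == lower column-major
    m[cols, rows] = lower
    m[rows, cols] = lower
    return m


class TestPointBiserial:
    def test_three_event_toy_against_brute_force(self):
        """3-event toy with lower-half similarities (1.0, 0.2, 0.1, 1.0, 0.2,
        1.0) against the episodic model (1, 0, 0, 1, 0, 1), both listed
        column-major; any consistent cell ordering gives the same r, so the
        row-major implementation must match the brute-force Pearson value."""
        sim = _sim_from_lower_half_colmajor([1.0, 0.2, 0.1, 1.0, 0.2, 1.0], 3)
        toy_design_model = ModelMatrix("episodic", np.eye(3, dtype=int))
        fit = point_biserial_fit(sim, toy_design_model)
        expected = _brute_pearson([1, 0, 0, 1, 0, 1], [1.0, 0.2, 0.1, 1.0, 0.2, 1.0])
        assert fit.r == pytest.approx(expected, abs=1e-12)
        assert fit.n_cells == 6

    def test_perfect_and_inverted_fit(self, design, models):
        m = models["context"]
        assert point_biserial_fit(m.values.astype(float), m).r == pytest.approx(1.0)
        assert point_biserial_fit(-m.values.astype(float), m).r == pytest.approx(-1.0)

    def test_affine_invariance(self, design, models, rng):
        sim = rng.normal(size=(8, 8))
        sim = sim + sim.T
        base = point_biserial_fit(sim, models["person"]).r
        shifted = point_biserial_fit(3.5 * sim + 2.0, models["person"]).r
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_constant_model_rejected(self, design):
        all_ones = ModelMatrix("schema", np.ones((8, 8), dtype=int))
        sim = np.zeros((8, 8))
        with pytest.raises(ValueError, match="constant"):
            point_biserial_fit(sim, all_ones)

    def test_p_value_matches_t_formula(self, design, models, rng):
        sim = rng.normal(size=(8, 8))
        sim = sim + sim.T
        fit = point_biserial_fit(sim, models["context"])
        t = fit.r * math.sqrt((fit.n_cells - 2) / (1 - fit.r**2))
        assert fit.p == pytest.approx(2 * stats.t.sf(abs(t), fit.n_cells - 2))


class TestGroupFit:
    def test_identical_subjects_equal_single(self, models, rng):
        sim = rng.normal(size=(8, 8))
        sim = sim + sim.T
        single = point_biserial_fit(sim, models["context"])
        group = group_fit([sim] * 5, models["context"])
        assert group.r == pytest.approx(single.r)

    def test_opposite_subjects_cancel(self, models, rng):
        sim = rng.normal(size=(8, 8))
        sim = sim + sim.T
        group = group_fit([sim, -sim], models["context"])
        assert group.r == pytest.approx(0.0, abs=1e-9)

    def test_averaging_reduces_noise(self, models, rng):
        """Group fit beats the median subject fit in most noisy replicates."""
        model = models["context"].values.astype(float)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            sims = [model + rng.normal(0, 1, size=(8, 8)) for _ in range(10)]
            sims = [(s + s.T) / 2 for s in sims]
            g = group_fit(sims, models["context"]).r
            med = np.median(
                [point_biserial_fit(s, models["context"]).r for s in sims]
            )
            wins += g >= med
        assert wins / n_rep >= 0.9


class TestRMAnova:
    def test_df_structure(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = rm_anova_fits(table)
        assert (res.df_num, res.df_den) == (3, 57)

    def test_identical_columns_give_zero_F(self, rng):
        col = rng.normal(size=12)
        table = pd.DataFrame({"a": col, "b": col, "c": col})
        res = rm_anova_fits(table)
        assert res.F == 0.0 and res.p == 1.0

    def test_shifted_column_highly_significant(self, rng):
        table = pd.DataFrame(rng.normal(0, 0.1, size=(15, 4)), columns=list("abcd"))
        table["d"] += 5.0
        assert rm_anova_fits(table).p < 1e-6

    def test_against_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        wide = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        long = wide.reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        )
        oracle = pingouin.rm_anova(
            data=long, dv="y", within="cond", subject="index"
        )
        res = rm_anova_fits(wide)
        pcol = "p_unc" if "p_unc" in oracle.columns else "p-unc"
        assert res.F == pytest.approx(float(oracle["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(oracle[pcol].iloc[0]), rel=1e-9)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            rm_anova_fits(table)


class TestTukeyHSD:
    def test_equal_means_give_p_one(self):
        res = tukey_hsd({"a": 1.0, "b": 1.0, "c": 1.0}, 0.5, 30, 10)
        assert np.allclose(res["p_adj"], 1.0)

    def test_adjusted_at_least_unadjusted(self, rng):
        """Tukey-adjusted p >= the unadjusted pairwise t p for every pair."""
        for _ in range(20):
            means = dict(zip("abcd", rng.normal(size=4)))
            ms, df, n = 1.3, 36, 10
            res = tukey_hsd(means, ms, df, n)
            for _, row in res.iterrows():
                t = abs(row.mean_diff) / np.sqrt(2 * ms / n)
                p_t = 2 * stats.t.sf(t, df)
                assert row.p_adj >= p_t - 1e-12

    def test_against_monte_carlo_studentized_range(self, rng):
        """Adjusted p matches a Monte-Carlo studentized-range null at a
        known configuration (k=3 groups)."""
        means, ms_error, df, n = {"a": 0.0, "b": 0.6, "c": 0.1}, 1.0, 27, 10
        res = tukey_hsd(means, ms_error, df, n).set_index(["group_a", "group_b"])
        draws = 200_000
        z = rng.normal(size=(draws, 3))
        s2 = rng.chisquare(df, size=draws) / df
        q_null = (z.max(axis=1) - z.min(axis=1)) / np.sqrt(s2)
        for (a, b), row in res.iterrows():
            mc_p = np.mean(q_null >= row.q)
            assert row.p_adj == pytest.approx(mc_p, abs=0.01)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError, match="at least 3"):
            tukey_hsd({"a": 0.0, "b": 1.0}, 1.0, 10, 5)


def test_subject_fit_table_shape_and_transform(models, rng):
    sims = []
    for _ in range(5):
        s = rng.normal(size=(8, 8))
        sims.append((s + s.T) / 2)
    table = subject_fit_table(sims, models)
    assert table.shape == (5, 4)
    fit = point_biserial_fit(sims[0], models["person"])
    assert table.iloc[0]["person"] == pytest.approx(math.atanh(fit.r))


def test_compare_model_fits_recovers_planted_context(design, models):
    """Context-planted synthetic data: the Context fit wins at group level
    and has the largest per-subject column mean."""
    from eventrsa import GeneratorConfig, ROIProfile, generate_dataset

    cfg = GeneratorConfig(
        n_subjects=8,
        n_voxels=150,
        seed=11,
        roi_profiles={"pm_like": ROIProfile(w_context=1.0, w_schema=0.4, w_episodic=0.4)},
    )
    ds = generate_dataset(cfg)
    sims = [encoding_similarity_matrix(ds.encoding["pm_like"][s]) for s in range(8)]
    res = compare_model_fits(sims, models, roi_name="pm_like")
    assert res.winning_model == "context"
    assert res.subject_table.mean(axis=0).idxmax() == "context"
    assert res.anova.df_num == 3 and res.anova.df_den == 21
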