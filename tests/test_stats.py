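"""Classical summary statistics: ANOVA, planned trend contrast, power."""

import numpy as np
import pytest

from gaindcm.stats import (
    beta_frame,
    planned_trend_contrast,
    run_stage3,
    simulate_trend_rejections,
    trend_power_oracle,
    two_way_anova,
)

LABELS = [f"{h}-{n}" for h in "LR" for n in ("IOG", "SOG", "IPC", "SOrbG")]


def make_frame(n_subjects=18, level_means=(0.4, 0.3, 0.2, 0.1), sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    levels = np.tile([1, 2, 3, 4], 2)
    betas = -(
        np.asarray(level_means)[levels - 1][None, :]
        + rng.normal(0, sd, (n_subjects, 8))
    )
    return beta_frame(betas, LABELS)


def test_beta_frame_layout():
    frame = make_frame(n_subjects=5)
    assert len(frame) == 40
    assert set(frame["level"]) == {1, 2, 3, 4}
    assert set(frame["hemisphere"]) == {"left", "right"}
    # gain is the negated modulation of self-inhibition
    assert np.allclose(frame["gain"], -frame["beta"])


def test_contrast_weights_are_centred():
    res = planned_trend_contrast(make_frame())
    assert res.weights == (1.5, 0.5, -0.5, -1.5)
    assert sum(res.weights) == 0.0
    raw = planned_trend_contrast(make_frame(), centre=False)
    assert raw.weights == (4.0, 3.0, 2.0, 1.0)


def test_equal_gains_give_zero_statistics():
    betas = np.full((6, 8), -0.3)
    frame = beta_frame(betas, LABELS)
    res = planned_trend_contrast(frame)
    assert res.t == 0.0
    anova = two_way_anova(frame)
    # no between-level variation at all (F itself is 0/0 here)
    assert anova.loc["C(level)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)


def test_perfect_decreasing_trend_detected_with_correct_sign():
    frame = make_frame(sd=1e-9)
    res = planned_trend_contrast(frame)
    assert res.t > 1e3  # decreasing gain with level, positive with (1.5..-1.5)
    assert res.p < 1e-12


def test_degrees_of_freedom_match_the_design():
    frame = make_frame(n_subjects=18)
    res = planned_trend_contrast(frame)
    assert res.df == 144 - 4  # one-way pooling over hemispheres
    anova = two_way_anova(frame)
    assert anova.loc["Residual", "df"] == 144 - 8  # 4 x 2 cells


def test_stage3_pools_hemispheres_when_no_side_effect():
    res = run_stage3(make_frame(seed=2))
    assert res.pooled_hemispheres
    assert res.per_hemisphere_trend is None
    assert res.trend.p < 0.05


def test_stage3_reports_per_hemisphere_when_side_effect_present():
    frame = make_frame(seed=3)
    frame.loc[frame["hemisphere"] == "left", "gain"] += 1.0
    res = run_stage3(frame)
    assert res.hemisphere_p < 0.05
    assert not res.pooled_hemispheres
    assert set(res.per_hemisphere_trend) == {"left", "right"}


def test_unbalanced_table_rejected():
    frame = make_frame().iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        run_stage3(frame)


def test_each_level_needs_two_observations():
    frame = make_frame(n_subjects=18).groupby("level").head(1)
    with pytest.raises(ValueError, match="at least 2"):
        planned_trend_contrast(frame)


def test_null_calibration_matches_alpha():
    rng = np.random.default_rng(17)
    rate = simulate_trend_rejections(
        level_means=(0.0, 0.0, 0.0, 0.0), noise_sd=0.15,
        n_subjects=18, n_replicates=500, rng=rng,
    )
    se = np.sqrt(0.05 * 0.95 / 500)
    assert abs(rate - 0.05) <= 3 * se + 1e-9


def test_monte_carlo_power_matches_noncentral_t_oracle():
    """Rejection rate under a medium-sized decreasing trend agrees with
    the closed-form noncentral-t power to within 5 points."""
    level_means = (0.12, 0.08, 0.04, 0.0)  # medium standardized trend
    sd, n = 0.25, 18
    oracle = trend_power_oracle(level_means, sd, n)
    rng = np.random.default_rng(1)
    rate = simulate_trend_rejections(level_means, sd, n, 500, rng)
    assert 0.1 < oracle < 0.95  # informative regime, not saturated
    assert abs(rate - oracle) <= 0.05
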