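"""Classical summary statistics over recovered gain modulations.

Stage 3 of the analysis treats the per-subject maximum-a-posteriori
modulation parameters (one per area and hemisphere) as summary
statistics: a two-way fixed-effects ANOVA with factors cortical source
(four hierarchical levels) and hemisphere, and a one-way ANOVA with a
planned linear contrast across levels, weighting the groups from the
bottom of the hierarchy to the top as 4, 3, 2, 1.  The raw weights do
not sum to zero, so by default they are centred to (1.5, 0.5, -0.5,
-1.5) — the same linear trend, but a valid contrast that does not
confound the grand mean; a fidelity flag applies the raw weights.
Equal group variances are assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_TREND_WEIGHTS = (4.0, 3.0, 2.0, 1.0)


def beta_frame(
    betas: np.ndarray,
    area_labels: Sequence[str],
    value_name: str = "gain",
    sign: float = -1.0,
) -> pd.DataFrame:
    """Long-format table of per-subject, per-area modulation effects.

    ``betas`` is (n_subjects, 8) over areas labelled like ``L-IOG``.
    ``sign=-1`` converts the log-scale change in self-inhibition into a
    gain change (gain up = self-inhibition down), so a contrast-dependent
    gain increase is a positive value that should decrease with level.
    """
    from .model_space import AREA_LEVEL

    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    rows = []
    for s in range(betas.shape[0]):
        for j, label in enumerate(area_labels):
            hemi, name = label.split("-", 1)
            rows.append(
                {
                    "subject": s,
                    "area": name,
                    "hemisphere": "left" if hemi == "L" else "right",
                    "level": AREA_LEVEL[name],
                    "beta": betas[s, j],
                    value_name: sign * betas[s, j],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TrendContrastResult:
    """Planned linear-trend contrast across hierarchical levels."""

    t: float
    df: int
    p: float
    estimate: float
    weights: Tuple[float, ...]
    group_means: np.ndarray


@dataclass
class Stage3Result:
    anova: pd.DataFrame
    hemisphere_p: float
    trend: TrendContrastResult
    pooled_hemispheres: bool
    per_hemisphere_trend: Optional[dict] = None


def two_way_anova(frame: pd.DataFrame, value: str = "gain") -> pd.DataFrame:
    """Fixed-effects two-way ANOVA: value ~ source level x hemisphere."""
    fit = smf.ols(f"{value} ~ C(level) * C(hemisphere)", data=frame).fit()
    return sm.stats.anova_lm(fit, typ=2)


def planned_trend_contrast(
    frame: pd.DataFrame,
    value: str = "gain",
    weights: Sequence[float] = DEFAULT_TREND_WEIGHTS,
    centre: bool = True,
) -> TrendContrastResult:
    """One-way ANOVA planned contrast over the four levels, equal variance.

    Pools hemispheres; the error term is the pooled within-group
    variance over the four level groups (df = N - 4).
    """
    w = np.asarray(weights, dtype=float)
    if centre:
        w = w - w.mean()
    levels = sorted(frame["level"].unique())
    if len(levels) != w.size:
        raise ValueError("one weight per hierarchical level required")
    groups = [frame.loc[frame["level"] == l, value].to_numpy() for l in levels]
    ns = np.array([g.size for g in groups])
    if np.any(ns < 2):
        raise ValueError("each level needs at least 2 observations")
    means = np.array([g.mean() for g in groups])
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = int(ns.sum() - len(groups))
    s2 = ss_within / df
    est = float(w @ means)
    se = float(np.sqrt(s2 * np.sum(w**2 / ns)))
    if se == 0.0:
        t = np.inf * np.sign(est) if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        t = est / se
        p = 2.0 * sstats.t.sf(abs(t), df)
    return TrendContrastResult(
        t=float(t), df=df, p=float(p), estimate=est,
        weights=tuple(float(x) for x in w), group_means=means,
    )


def run_stage3(
    frame: pd.DataFrame,
    value: str = "gain",
    weights: Sequence[float] = DEFAULT_TREND_WEIGHTS,
    centre_weights: bool = True,
    alpha: float = 0.05,
) -> Stage3Result:
    """ANOVA plus planned trend contrast on the gain-change table.

    Hemispheres are pooled for the trend contrast when the two-way ANOVA
    shows no hemisphere effect at ``alpha``; otherwise pooled and
    per-hemisphere contrasts are both reported.
    """
    counts = frame.groupby(["level", "hemisphere"])[value].count()
    if counts.min() != counts.max():
        missing = counts[counts < counts.max()]
        raise ValueError(f"unbalanced design; light cells: {missing.to_dict()}")
    anova = two_way_anova(frame, value)
    hemi_p = float(anova.loc["C(hemisphere)", "PR(>F)"])
    trend = planned_trend_contrast(frame, value, weights, centre_weights)
    per_hemi = None
    pooled = hemi_p >= alpha or np.isnan(hemi_p)
    if not pooled:
        per_hemi = {
            h: planned_trend_contrast(
                frame[frame["hemisphere"] == h], value, weights, centre_weights
            )
            for h in ("left", "right")
        }
    return Stage3Result(
        anova=anova,
        hemisphere_p=hemi_p,
        trend=trend,
        pooled_hemispheres=pooled,
        per_hemisphere_trend=per_hemi,
    )


# ---------------------------------------------------------------------------
# calibration / power utilities


def simulate_trend_rejections(
    level_means: Sequence[float],
    noise_sd: float,
    n_subjects: int,
    n_replicates: int,
    rng: np.random.Generator,
    weights: Sequence[float] = DEFAULT_TREND_WEIGHTS,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo rejection rate of the planned trend test.

    Each replicate draws a fresh (n_subjects x 8) table of gains with
    the given per-level means (both hemispheres) plus IID Gaussian
    noise, and applies the centred planned contrast.
    """
    level_means = np.asarray(level_means, dtype=float)
    levels = np.repeat(np.arange(4), 2)  # 8 areas: 4 levels x 2 hemispheres
    rejections = 0
    w = np.asarray(weights, dtype=float)
    w = w - w.mean()
    for _ in range(n_replicates):
        gains = level_means[levels][None, :] + rng.normal(
            0.0, noise_sd, size=(n_subjects, 8)
        )
        groups = [gains[:, levels == l].ravel() for l in range(4)]
        ns = np.array([g.size for g in groups])
        means = np.array([g.mean() for g in groups])
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df = ns.sum() - 4
        s2 = ss_within / df
        t = (w @ means) / np.sqrt(s2 * np.sum(w**2 / ns))
        if 2.0 * sstats.t.sf(abs(t), df) < alpha:
            rejections += 1
    return rejections / n_replicates


def trend_power_oracle(
    level_means: Sequence[float],
    noise_sd: float,
    n_subjects: int,
    weights: Sequence[float] = DEFAULT_TREND_WEIGHTS,
    alpha: float = 0.05,
) -> float:
    """Closed-form power of the two-sided planned contrast (noncentral t).

    Independent of the Monte-Carlo path above: uses the noncentral t
    distribution with noncentrality ``sum(w_l mu_l) / (sd *
    sqrt(sum(w_l^2 / n_l)))`` and df = N - 4.
    """
    mu = np.asarray(level_means, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w - w.mean()
    n_per_level = 2 * n_subjects  # two hemispheres per level
    ns = np.full(4, n_per_level)
    df = int(ns.sum() - 4)
    nc = float(w @ mu) / (noise_sd * np.sqrt(np.sum(w**2 / ns)))
    tcrit = sstats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        sstats.nct.sf(tcrit, df, nc) + sstats.nct.cdf(-tcrit, df, nc)
    )
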