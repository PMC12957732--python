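"""Length-weight allometry, Le Cren relative condition factor and
condition-variability contrasts.

The length-weight relationship is fit as an OLS regression of ln W on ln L
(natural logs), giving ``b`` (the allometric exponent) and ``a = exp(log a)``
in g mm^-b. Le Cren's relative condition factor is computed on the raw
measurement scale, ``K_n = W / (a L^b)``: the ratio of a fish's observed
weight to the length-specific mean weight of its population. Because OLS log
residuals sum to zero, the geometric mean of K_n over the fitting sample is 1.

Zone effects on the condition-length relationship are modelled as
``K_n ~ logL * zone`` with a sequential (Type I) ANOVA, partial eta-squared
effect sizes, per-zone marginal slopes and Tukey-adjusted pairwise slope
contrasts (studentized-range reference on the contrast set).

Variability contrasts use the log variance ratio
``lnVR = ln(SD1/SD2) + 1/(2(n1-1)) - 1/(2(n2-1))`` (the small-sample
bias-corrected form; the correction is toggleable) on residuals from the
interaction model, with percentile bootstrap CIs from within-group case
resampling. A contrast is flagged significant when its CI excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "LengthWeightFit",
    "InteractionFit",
    "VarianceComparison",
    "fit_length_weight",
    "compute_kn",
    "fit_condition_interaction",
    "lnvr_pairwise",
]


@dataclass
class LengthWeightFit:
    """OLS fit of ln W on ln L. ``a = exp(log_a)`` has units g mm^-b."""

    log_a: float
    b: float
    n: int
    resid_sd: float
    se_log_a: float
    se_b: float

    @property
    def a(self) -> float:
        return float(np.exp(self.log_a))

    def predict_weight(self, length) -> np.ndarray:
        """Length-specific mean weight a L^b (g)."""
        return self.a * np.asarray(length, dtype=float) ** self.b


def fit_length_weight(fish: pd.DataFrame, length_col: str = "length_mm",
                      weight_col: str = "weight_g") -> LengthWeightFit:
    """Fit the allometric length-weight regression for one population."""
    L = fish[length_col].to_numpy(float)
    W = fish[weight_col].to_numpy(float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("lengths and weights must be strictly positive")
    if L.size < 3:
        raise ValueError(f"need >= 3 fish, got {L.size}")
    if np.unique(L).size < 2:
        raise np.linalg.LinAlgError("all lengths equal: design is singular")
    X = sm.add_constant(np.log(L))
    res = sm.OLS(np.log(W), X).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return LengthWeightFit(
        log_a=float(res.params[0]), b=float(res.params[1]), n=int(L.size),
        resid_sd=resid_sd, se_log_a=float(res.bse[0]), se_b=float(res.bse[1]),
    )


def compute_kn(fish: pd.DataFrame, fit: LengthWeightFit,
               length_col: str = "length_mm", weight_col: str = "weight_g") -> pd.DataFrame:
    """Per-fish relative condition K_n = W / (a L^b), with zone/reef labels.

    K_n = 1 means average plumpness for that length; > 1 better-than-average
    condition. Returns a table with columns kn, zone, reef, length and logL.
    """
    L = fish[length_col].to_numpy(float)
    W = fish[weight_col].to_numpy(float)
    if np.any(L <= 0):
        raise ValueError("lengths must be strictly positive")
    kn = W / fit.predict_weight(L)
    out = pd.DataFrame({
        "id": fish["id"].to_numpy() if "id" in fish else np.arange(len(fish)),
        "kn": kn,
        "zone": fish["zone"].to_numpy() if "zone" in fish else "all",
        "reef": fish["reef"].to_numpy() if "reef" in fish else "all",
        "length_mm": L,
        "log_length": np.log(L),
    })
    return out


@dataclass
class InteractionFit:
    """Results of the K_n ~ logL * zone model."""

    coefficients: pd.Series
    anova: pd.DataFrame          # Type I table with partial eta squared
    slopes: pd.DataFrame         # per-zone marginal slope with SE
    slope_contrasts: pd.DataFrame  # pairwise diffs, raw and Tukey p
    residuals: pd.Series
    df_resid: int


def fit_condition_interaction(cond: pd.DataFrame) -> InteractionFit:
    """Fit K_n ~ logL * zone and test for slope heterogeneity.

    Sequential ANOVA assigns sums of squares in model order (zone, logL,
    interaction); partial eta^2 = SS_term / (SS_term + SS_resid). Marginal
    slopes and all pairwise slope differences are derived from the
    coefficient covariance; contrast p-values use the studentized-range
    distribution over the zone set (Tukey adjustment).
    """
    zones = list(dict.fromkeys(cond["zone"]))
    if len(zones) < 2:
        raise ValueError("need >= 2 zones")
    for z in zones:
        sub = cond[cond["zone"] == z]
        if len(sub) < 3:
            raise ValueError(f"zone {z}: need >= 3 fish")
        if sub["log_length"].nunique() < 2:
            raise np.linalg.LinAlgError(f"zone {z}: < 2 distinct lengths, singular design")
    df = cond.copy()
    df["zone"] = pd.Categorical(df["zone"], categories=zones)
    model = smf.ols("kn ~ log_length * zone", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    anova["partial_eta_sq"] = anova["sum_sq"] / (anova["sum_sq"] + ss_resid)
    anova.loc["Residual", "partial_eta_sq"] = np.nan

    # marginal slope per zone: d kn / d logL = base slope + interaction term
    cov = model.cov_params()
    names = model.params.index
    slope_vecs = {}
    for z in zones:
        vec = pd.Series(0.0, index=names)
        vec["log_length"] = 1.0
        inter = f"log_length:zone[T.{z}]"
        if inter in names:
            vec[inter] = 1.0
        slope_vecs[z] = vec
    slopes = pd.DataFrame([
        {
            "zone": z,
            "slope": float(model.params @ v),
            "se": float(np.sqrt(v @ cov @ v)),
        }
        for z, v in slope_vecs.items()
    ])

    k = len(zones)
    dfres = int(model.df_resid)
    rows = []
    for za, zb in combinations(zones, 2):
        v = slope_vecs[za] - slope_vecs[zb]
        diff = float(model.params @ v)
        se = float(np.sqrt(v @ cov @ v))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p_raw = 2 * stats.t.sf(abs(t), dfres)
        p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, dfres))
        rows.append({
            "zone_a": za, "zone_b": zb, "diff": diff, "se": se, "t": t,
            "p_raw": p_raw, "p_tukey": min(1.0, p_tukey),
        })
    contrasts = pd.DataFrame(rows)
    return InteractionFit(
        coefficients=model.params, anova=anova, slopes=slopes,
        slope_contrasts=contrasts,
        residuals=pd.Series(model.resid.to_numpy(), index=cond.index, name="resid"),
        df_resid=dfres,
    )


@dataclass
class VarianceComparison:
    zone_a: str
    zone_b: str
    lnvr: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    B: int
    significant: bool


def _lnvr(x: np.ndarray, y: np.ndarray, correct: bool) -> float:
    s1, s2 = np.std(x, ddof=1), np.std(y, ddof=1)
    if s1 == 0 or s2 == 0:
        raise ZeroDivisionError("zero variance in a group: lnVR undefined")
    val = np.log(s1 / s2)
    if correct:
        val += 1.0 / (2 * (len(x) - 1)) - 1.0 / (2 * (len(y) - 1))
    return float(val)


def lnvr_pairwise(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    bias_correction: bool = True,
    value_col: str = "resid",
    group_col: str = "zone",
) -> list[VarianceComparison]:
    """Pairwise log variance ratios with percentile-bootstrap 95% CIs.

    ``groups`` is either a mapping zone -> residual array or a long DataFrame
    with ``group_col``/``value_col``. Bootstrap resamples cases independently
    within each group. Antisymmetric: lnVR(a, b) = -lnVR(b, a).
    """
    if isinstance(groups, pd.DataFrame):
        groups = {
            str(z): sub[value_col].to_numpy(float)
            for z, sub in groups.groupby(group_col, sort=False)
        }
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for z, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {z}: need n >= 3")
    rng = np.random.default_rng(seed)
    out = []
    for za, zb in combinations(names, 2):
        x, y = np.asarray(groups[za], float), np.asarray(groups[zb], float)
        est = _lnvr(x, y, bias_correction)
        bx = x[rng.integers(0, len(x), size=(B, len(x)))]
        by = y[rng.integers(0, len(y), size=(B, len(y)))]
        sx = bx.std(axis=1, ddof=1)
        sy = by.std(axis=1, ddof=1)
        ok = (sx > 0) & (sy > 0)
        draws = np.log(sx[ok] / sy[ok])
        if bias_correction:
            draws = draws + 1.0 / (2 * (len(x) - 1)) - 1.0 / (2 * (len(y) - 1))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        out.append(VarianceComparison(
            zone_a=za, zone_b=zb, lnvr=est, ci_low=float(lo), ci_high=float(hi),
            n_a=len(x), n_b=len(y), B=B, significant=bool(lo > 0 or hi < 0),
        ))
    return out
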