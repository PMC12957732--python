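"""Shared univariate statistics for survey data: Kruskal-Wallis with the
rank epsilon-squared effect size, Dunn's post hoc test with Benjamini-
Hochberg adjustment, one-way ANOVA with Tukey HSD, Shannon diversity (nats)
and density summaries for belt-transect and quadrat counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "anova_tukey",
    "shannon",
    "densities",
    "benthic_summary",
]


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p_value: float
    effect_size: float
    effect_size_name: str
    posthoc: pd.DataFrame | None = None
    flag: str | None = None


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        raise TypeError("pass a mapping name -> values")
    return {str(k): np.asarray(v, dtype=float) for k, v in dict(groups).items()}


def kruskal_wallis(groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with epsilon-squared.

    epsilon^2 = H (n+1) / (n^2 - 1), the standard rank-based effect size.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) == 0 for v in g.values()):
        raise ValueError("empty group")
    n = sum(len(v) for v in g.values())
    if n < 5:
        raise ValueError("total n >= 5 required")
    vals = list(g.values())
    if all(np.all(v == vals[0][0]) for v in vals):
        # degenerate: all observations identical; H is 0 by convention
        return GroupTestResult(0.0, len(g) - 1, 1.0, 0.0, "epsilon_sq")
    H, p = stats.kruskal(*vals)
    eps2 = float(H * (n + 1) / (n ** 2 - 1))
    return GroupTestResult(float(H), len(g) - 1, float(p), eps2, "epsilon_sq")


def dunn_posthoc(groups, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's pairwise rank test with tie correction and BH adjustment.

    Z for a pair is the mean-rank difference over its pooled-rank standard
    error sqrt(V (1/n_i + 1/n_j)) with V = (N(N+1)/12 - T/(12(N-1))) where
    T = sum(t^3 - t) over tie groups; two-sided p from the normal.
    """
    g = _as_groups(groups)
    if len(g) < 3:
        raise ValueError("Dunn's test needs >= 3 groups (use the omnibus test otherwise)")
    names = list(g)
    all_vals = np.concatenate([g[k] for k in names])
    N = all_vals.size
    ranks = stats.rankdata(all_vals)
    splits = np.cumsum([len(g[k]) for k in names])[:-1]
    rank_groups = dict(zip(names, np.split(ranks, splits)))
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    V = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for a, b in combinations(names, 2):
        ra, rb = rank_groups[a], rank_groups[b]
        se = np.sqrt(V * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if adjust.lower() == "bh":
        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
        out["adjustment"] = "BH"
    else:
        raise ValueError(f"unsupported adjustment {adjust!r}")
    return out


def anova_tukey(groups) -> GroupTestResult:
    """One-way ANOVA with Tukey HSD post hoc comparisons.

    If the residual variance is exactly zero while group means differ, the
    F statistic is reported as infinity and flagged rather than erroring.
    """
    g = _as_groups(groups)
    if len(g) < 2 or any(len(v) < 2 for v in g.values()):
        raise ValueError("need >= 2 groups each with n >= 2")
    vals = list(g.values())
    names = list(g)
    n = sum(len(v) for v in vals)
    grand = np.concatenate(vals).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    df_b, df_w = len(g) - 1, n - len(g)
    if ss_within == 0:
        if ss_between == 0:
            return GroupTestResult(0.0, df_b, 1.0, 0.0, "partial_eta_sq")
        return GroupTestResult(float("inf"), df_b, 0.0, 1.0, "partial_eta_sq",
                               flag="zero residual variance: F reported as inf")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    eta = float(ss_between / (ss_between + ss_within))
    hsd = stats.tukey_hsd(*vals)
    ci = hsd.confidence_interval()
    rows = []
    for i, j in combinations(range(len(vals)), 2):
        rows.append({
            "group_a": names[i], "group_b": names[j],
            "diff": float(vals[i].mean() - vals[j].mean()),
            "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
            "p_adj": float(hsd.pvalue[i, j]), "adjustment": "Tukey",
        })
    return GroupTestResult(float(F), df_b, p, eta, "partial_eta_sq",
                           posthoc=pd.DataFrame(rows))


def shannon(counts) -> float:
    """Shannon diversity H' in nats: -sum p_i ln p_i over non-zero categories."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def densities(counts: pd.DataFrame, area_col: str = "area_m2",
              taxon_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-reef density summaries (individuals per m^2) from replicate counts.

    Each row of ``counts`` is one replicate unit (transect or quadrat) with a
    zone, reef, an area column and one count column per taxon. Density per
    replicate is count/area; the summary reports mean and SD across
    replicates within reef, and the zone mean across reefs.
    """
    if (counts[area_col] <= 0).any():
        raise ValueError("areas must be > 0")
    if taxon_cols is None:
        skip = {"zone", "reef", "transect", "quadrat", area_col}
        taxon_cols = [c for c in counts.columns if c not in skip]
    dens = counts[taxon_cols].div(counts[area_col], axis=0)
    dens = pd.concat([counts[["zone", "reef"]], dens], axis=1)
    reef = dens.groupby(["zone", "reef"], sort=False)[taxon_cols].agg(["mean", "std"])
    reef.columns = [f"{t}_{s}" for t, s in reef.columns]
    reef = reef.reset_index()
    zone = reef.groupby("zone", sort=False)[[f"{t}_mean" for t in taxon_cols]].mean()
    zone.columns = [f"{c}_zone" for c in zone.columns]
    return reef.merge(zone, on="zone")


def benthic_summary(benthic: pd.DataFrame, coral_prefix: str = "coral_") -> pd.DataFrame:
    """Reef-level benthic summary from photo-quadrat point counts.

    Percent live coral cover per reef is the two-stage mean: quadrat coral
    percentages averaged within transect, then averaged across transects.
    Shannon H' (nats) is computed on the pooled per-genus coral point counts.
    """
    coral_cols = [c for c in benthic.columns if c.startswith(coral_prefix)]
    if not coral_cols:
        raise ValueError(f"no columns with prefix {coral_prefix!r}")
    cat_cols = [c for c in benthic.columns
                if c not in ("zone", "reef", "transect", "quadrat")]
    df = benthic.copy()
    totals = df[cat_cols].sum(axis=1)
    df["coral_pct"] = 100.0 * df[coral_cols].sum(axis=1) / totals
    rows = []
    for (zone, reef), sub in df.groupby(["zone", "reef"], sort=False):
        per_transect = sub.groupby("transect")["coral_pct"].mean()
        genus_counts = sub[coral_cols].sum()
        h = shannon(genus_counts) if genus_counts.sum() > 0 else 0.0
        rows.append({
            "zone": zone, "reef": reef,
            "coral_cover_pct": float(per_transect.mean()),
            "coral_cover_sd": float(per_transect.std(ddof=1)),
            "coral_shannon": h,
        })
    return pd.DataFrame(rows)
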