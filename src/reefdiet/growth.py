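"""Von Bertalanffy growth: prediction, nonlinear fitting and bootstrap
comparison of growth parameters between habitat zones.

The growth model is ``L(t) = L_inf * (1 - exp(-K (t - t0)))`` with asymptotic
length ``L_inf`` (mm), growth coefficient ``K`` (1/yr) and ``t0`` the
hypothetical age (yr) at zero length. Fits minimize the residual sum of
squares over age-length pairs by Levenberg-Marquardt least squares with a
restart ladder of start values. ``t0`` may be fixed (the default, at -2.0,
matching fits where all zones share a printed t0) or estimated freely.

Zone comparison follows the common CI-overlap convention: fish are
case-resampled within zone, the model refit per resample, and two zones are
declared different for a parameter iff their percentile 95% intervals are
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VBGFParams",
    "VBGFFit",
    "VBGFBootstrap",
    "vbgf_predict",
    "fit_vbgf",
    "bootstrap_vbgf",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when the optimizer fails to converge after all restarts."""


@dataclass(frozen=True)
class VBGFParams:
    """Growth parameters: asymptotic length (mm), growth rate (1/yr), and the
    hypothetical age at length zero (yr)."""

    linf: float
    k: float
    t0: float
    t0_fixed: bool = True


@dataclass
class VBGFFit:
    params: VBGFParams
    rss: float
    n: int
    converged: bool
    n_restarts_used: int = 0


@dataclass
class VBGFBootstrap:
    """Per-zone bootstrap summary for one parameter set."""

    zone: str
    point: VBGFParams
    boot_mean: dict[str, float]
    ci: dict[str, tuple[float, float]]
    B: int
    seed: int
    n_failed: int = 0
    samples: pd.DataFrame | None = field(default=None, repr=False)


def vbgf_predict(p: VBGFParams, t) -> np.ndarray | float:
    """Length at age ``t`` (years). Monotone increasing in t for K > 0;
    negative below t0 by construction (the caller decides how to treat it)."""
    t = np.asarray(t, dtype=float)
    out = p.linf * (1.0 - np.exp(-p.k * (t - p.t0)))
    return float(out) if out.ndim == 0 else out


def _start_values(age: np.ndarray, length: np.ndarray, t0: float) -> list[tuple[float, float]]:
    """Start ladder: Ford-Walford-flavoured K guess first, then a spread."""
    linf0 = float(length.max()) * 1.1
    # crude K from the mean-length gradient between youngest and oldest ages
    t_lo, t_hi = age.min(), age.max()
    l_lo = float(length[age == t_lo].mean())
    l_hi = float(length[age == t_hi].mean())
    with np.errstate(all="ignore"):
        frac_lo = np.clip(1 - l_lo / linf0, 1e-6, 1)
        frac_hi = np.clip(1 - l_hi / linf0, 1e-6, 1)
        k0 = float((np.log(frac_lo) - np.log(frac_hi)) / max(t_hi - t_lo, 1e-9))
    k0 = k0 if np.isfinite(k0) and k0 > 0 else 0.3
    return [(linf0, k0), (linf0, 0.1), (linf0 * 1.5, 0.3), (linf0, 0.8), (2 * linf0, 0.05)]


def fit_vbgf(
    age,
    length,
    t0_mode: tuple[str, float] | str = ("fixed", -2.0),
    start: VBGFParams | None = None,
) -> VBGFFit:
    """Fit the growth curve to age-length pairs by nonlinear least squares.

    Parameters
    ----------
    age, length : array-like
        Ages (yr) and total lengths (mm), one entry per fish.
    t0_mode : ("fixed", value) or "free"
        Whether t0 is pinned (default -2.0 yr) or estimated.
    start : VBGFParams, optional
        Explicit start values; otherwise an analytic ladder is used.
    """
    age = np.asarray(age, dtype=float)
    length = np.asarray(length, dtype=float)
    if age.shape != length.shape or age.ndim != 1:
        raise ValueError("age and length must be equal-length 1-D arrays")
    free_t0 = t0_mode == "free"
    n_param = 3 if free_t0 else 2
    n_distinct = np.unique(age).size
    if n_distinct < n_param + 1:
        raise ValueError(
            f"need at least {n_param + 1} distinct ages for a {n_param}-parameter fit, "
            f"got {n_distinct}"
        )
    t0_fixed_val = -2.0 if free_t0 else float(t0_mode[1])

    def residuals(theta):
        if free_t0:
            linf, k, t0 = theta
        else:
            (linf, k), t0 = theta, t0_fixed_val
        return length - linf * (1.0 - np.exp(-k * (age - t0)))

    starts: list[np.ndarray] = []
    if start is not None:
        base = [start.linf, start.k] + ([start.t0] if free_t0 else [])
        starts.append(np.array(base, dtype=float))
    for linf0, k0 in _start_values(age, length, t0_fixed_val):
        starts.append(np.array([linf0, k0] + ([-1.0] if free_t0 else [])))

    best = None
    for i, x0 in enumerate(starts):
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=20_000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol, i)
        if sol.success and rss <= (best[0] + 1e-12):
            break
    if best is None:
        raise FitError("VBGF fit failed to converge from every start value")
    rss, sol, i_start = best
    if free_t0:
        linf, k, t0 = sol.x
        params = VBGFParams(float(linf), float(k), float(t0), t0_fixed=False)
    else:
        linf, k = sol.x
        params = VBGFParams(float(linf), float(k), t0_fixed_val, t0_fixed=True)
    return VBGFFit(params=params, rss=rss, n=age.size, converged=bool(sol.success),
                   n_restarts_used=i_start)


def bootstrap_vbgf(
    fish: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    t0_mode: tuple[str, float] | str = ("fixed", -2.0),
    zone_col: str = "zone",
    age_col: str = "age_yr",
    length_col: str = "length_mm",
    max_fail_frac: float = 0.2,
) -> tuple[dict[str, VBGFBootstrap], pd.DataFrame]:
    """Bootstrap growth parameters per zone and compare zones by CI overlap.

    Fish are resampled with replacement within zone; each resample is refit.
    Returns per-zone summaries and a pairwise table with a ``differs`` flag per
    parameter (True iff the two percentile 95% CIs are disjoint).
    """
    if B < 100:
        raise ValueError("B >= 100 required for reported CIs")
    rng = np.random.default_rng(seed)
    free = t0_mode == "free"
    par_names = ["linf", "k"] + (["t0"] if free else [])
    zones = list(dict.fromkeys(fish[zone_col]))
    results: dict[str, VBGFBootstrap] = {}
    for zone in zones:
        sub = fish[fish[zone_col] == zone]
        age = sub[age_col].to_numpy(float)
        length = sub[length_col].to_numpy(float)
        point = fit_vbgf(age, length, t0_mode=t0_mode).params
        draws = {p: [] for p in par_names}
        failed = 0
        for _ in range(B):
            idx = rng.integers(0, len(sub), len(sub))
            try:
                f = fit_vbgf(age[idx], length[idx], t0_mode=t0_mode,
                             start=point)
            except (FitError, ValueError):
                failed += 1
                continue
            for p in par_names:
                draws[p].append(getattr(f.params, p if p != "linf" else "linf"))
        if failed > max_fail_frac * B:
            raise FitError(
                f"zone {zone}: {failed}/{B} bootstrap refits failed (> {max_fail_frac:.0%})"
            )
        samples = pd.DataFrame(draws)
        ci = {p: tuple(np.percentile(samples[p], [2.5, 97.5])) for p in par_names}
        results[zone] = VBGFBootstrap(
            zone=zone, point=point,
            boot_mean={p: float(samples[p].mean()) for p in par_names},
            ci=ci, B=B, seed=seed, n_failed=failed, samples=samples,
        )
    rows = []
    for i, za in enumerate(zones):
        for zb in zones[i + 1:]:
            for p in par_names:
                lo_a, hi_a = results[za].ci[p]
                lo_b, hi_b = results[zb].ci[p]
                rows.append({
                    "zone_a": za, "zone_b": zb, "parameter": p,
                    "ci_a_low": lo_a, "ci_a_high": hi_a,
                    "ci_b_low": lo_b, "ci_b_high": hi_b,
                    "differs": bool(hi_a < lo_b or hi_b < lo_a),
                })
    return results, pd.DataFrame(rows)
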