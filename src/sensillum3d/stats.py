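"""Group comparison of sensillum shape: mixed-effects profiles and rank tests.

The width-vs-height relationship is modelled per chamber as a linear mixed
model: ``width ~ group + height + height:group`` with a random intercept per
sensillum, fitted by REML. The height:group interaction is the quantity of
interest — it measures how the taper rate differs between humidity
conditions. Half-height width distributions are compared with a two-sided
Mann–Whitney U test (exact for small groups).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps

from .morpho import FwhmRecord

__all__ = [
    "MixedModelResult",
    "GroupComparison",
    "fit_mixed",
    "compare_fwhm",
    "summarize_conditions",
    "records_to_frame",
]

log = logging.getLogger(__name__)

Z95 = sps.norm.ppf(0.975)


@dataclass
class MixedModelResult:
    """Per-group fixed-effect estimates with 95% CIs and variance components."""

    slopes: dict[str, float]
    intercepts: dict[str, float]
    slope_ci: dict[str, tuple[float, float]]
    random_intercept_sd: float
    residual_sd: float
    prediction: pd.DataFrame  # columns: group, height, predicted, ci_low, ci_high
    converged: bool
    diagnostics: str = ""


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann–Whitney U comparison of half-height widths."""

    chamber: int
    statistic_U: float
    p_value: float
    median_diff: float
    n_high: int
    n_low: int
    method: str = "exact"


def _group_contrast(design_info, group: str, groups: list[str], heights: np.ndarray,
                    ) -> np.ndarray:
    """Design rows for a prediction grid of one group."""
    df = pd.DataFrame({"group": pd.Categorical([group] * len(heights), categories=groups),
                       "height": heights})
    return np.asarray(build_design_matrices([design_info], df)[0])


def fit_mixed(profiles: pd.DataFrame, heights_grid: np.ndarray | None = None,
              ) -> MixedModelResult:
    """Fit width ~ group * height with a per-sensillum random intercept (REML).

    ``profiles`` is long-format with columns ``sensillum_id, group, height,
    width``. Returns per-group slopes (reference slope plus interaction), 95%
    CIs from the fixed-effects covariance, variance components, and a
    prediction grid with 95% confidence bands. Non-convergence is flagged on
    the result, not raised.
    """
    req = {"sensillum_id", "group", "height", "width"}
    if not req.issubset(profiles.columns):
        raise ValueError(f"profiles must have columns {sorted(req)}")
    counts = profiles.groupby("group")["sensillum_id"].nunique()
    if (counts < 2).any():
        raise ValueError(f"need >= 2 sensilla per group, got {counts.to_dict()}")
    per_sens = profiles.groupby("sensillum_id")["height"].count()
    if (per_sens < 3).any():
        raise ValueError("need >= 3 height samples per sensillum")
    data = profiles.copy()
    groups = sorted(data["group"].unique())
    data["group"] = pd.Categorical(data["group"], categories=groups)
    model = smf.mixedlm("width ~ group * height", data, groups=data["sensillum_id"])
    converged = True
    diagnostics = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(reml=True)
        except Exception as exc:  # singular fits etc.
            log.warning("mixed model failed: %s", exc)
            raise
        conv_msgs = [str(w.message) for w in caught
                     if "converge" in str(w.message).lower()
                     or "singular" in str(w.message).lower()]
        if conv_msgs or not res.converged:
            converged = False
            diagnostics = "; ".join(conv_msgs) or "optimizer reported non-convergence"

    fe = res.fe_params
    k_fe = len(fe)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    names = list(fe.index)
    ref = groups[0]
    slopes, intercepts, slope_ci = {}, {}, {}
    for g in groups:
        c_slope = np.zeros(k_fe)
        c_slope[names.index("height")] = 1.0
        c_int = np.zeros(k_fe)
        c_int[names.index("Intercept")] = 1.0
        if g != ref:
            inter_name = f"group[T.{g}]:height"
            main_name = f"group[T.{g}]"
            c_slope[names.index(inter_name)] = 1.0
            c_int[names.index(main_name)] = 1.0
        est = float(c_slope @ fe.values)
        se = float(np.sqrt(max(c_slope @ cov_fe @ c_slope, 0.0)))
        slopes[g] = est
        slope_ci[g] = (est - Z95 * se, est + Z95 * se)
        intercepts[g] = float(c_int @ fe.values)

    if heights_grid is None:
        heights_grid = np.linspace(data["height"].min(), data["height"].max(), 50)
    heights_grid = np.asarray(heights_grid, dtype=float)
    rows = []
    design_info = model.data.design_info
    for g in groups:
        x = _group_contrast(design_info, g, groups, heights_grid)
        pred = x @ fe.values
        # variance clipped at 0: singular (noise-free) fits can yield tiny
        # negative diagonals in the REML fixed-effects covariance
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", x, cov_fe, x), 0.0, None))
        for h, p, s in zip(heights_grid, pred, se):
            rows.append((g, float(h), float(p), float(p - Z95 * s), float(p + Z95 * s)))
    prediction = pd.DataFrame(rows, columns=["group", "height", "predicted",
                                             "ci_low", "ci_high"])
    return MixedModelResult(
        slopes=slopes, intercepts=intercepts, slope_ci=slope_ci,
        random_intercept_sd=float(np.sqrt(res.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(res.scale)),
        prediction=prediction, converged=converged, diagnostics=diagnostics)


def records_to_frame(records: list[FwhmRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"sensillum_id": r.sensillum_id, "chamber": r.chamber,
                          "condition": r.condition, "height_total": r.height_total,
                          "width_at_half_height": r.width_at_half_height}
                         for r in records])


def compare_fwhm(records: list[FwhmRecord] | pd.DataFrame, chamber: int | None = None,
                 high: str = "high_RH", low: str = "low_RH",
                 exact_max_n: int = 8) -> GroupComparison:
    """Two-sided Mann–Whitney U on half-height widths, high vs low condition.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and the data are tie-free; otherwise the
    normal approximation with tie correction.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if chamber is not None:
        df = df[df["chamber"] == chamber]
    x = df.loc[df["condition"] == high, "width_at_half_height"].to_numpy()
    y = df.loc[df["condition"] == low, "width_at_half_height"].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"both conditions must be nonempty (n_high={len(x)}, n_low={len(y)})")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(chamber=int(chamber) if chamber is not None else 0,
                           statistic_U=float(res.statistic), p_value=float(res.pvalue),
                           median_diff=float(np.median(x) - np.median(y)),
                           n_high=len(x), n_low=len(y), method=method)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_conditions(profiles: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per chamber × condition summary with significance stars.

    ``mean_width``/``sd_width`` aggregate the per-sensillum base width (the
    maximum of the smoothed profile); ``median_fwhm`` is the median
    half-height width. The SD is NaN for singleton cells; chambers with no
    data are omitted (logged).
    """
    if profiles.empty or records.empty:
        raise ValueError("profiles and records must be nonempty")
    base = (profiles.groupby(["chamber", "condition", "sensillum_id"])["width"]
            .max().rename("base_width").reset_index())
    rows = []
    for chamber in sorted(records["chamber"].unique()):
        rec_c = records[records["chamber"] == chamber]
        conditions = sorted(rec_c["condition"].unique())
        try:
            comp = compare_fwhm(rec_c, chamber=chamber)
            p, stars = comp.p_value, _stars(comp.p_value)
        except ValueError:
            p, stars = np.nan, ""
        for cond in conditions:
            b = base[(base["chamber"] == chamber) & (base["condition"] == cond)]
            r = rec_c[rec_c["condition"] == cond]
            if b.empty and r.empty:
                log.info("chamber %s condition %s empty; omitted", chamber, cond)
                continue
            n = len(r)
            rows.append({
                "chamber": chamber, "condition": cond, "n": n,
                "mean_width": float(b["base_width"].mean()) if not b.empty else np.nan,
                "sd_width": float(b["base_width"].std(ddof=1)) if len(b) > 1 else np.nan,
                "median_fwhm": float(r["width_at_half_height"].median()) if n else np.nan,
                "p_value": p, "significance": stars,
            })
    return pd.DataFrame(rows)
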