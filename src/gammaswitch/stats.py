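"""Permutation inference, FDR, mixed models, and trial-type specificity.

Two permutation schemes are used on high-gamma percent-change time
courses.  The one-sample test asks, per 10-ms bin, whether the mean
percent change across units (electrode sites within an ROI) differs
from zero; the null is built by randomly flipping the sign of each
unit's whole time course (sign flips respect the within-unit temporal
correlation).  The two-sample test contrasts per-trial ROI series
between two trial types; the null shuffles trial labels.  Both use
1000 permutations by default, two-sided p-values with the (b+1)/(m+1)
convention, and Benjamini-Hochberg FDR across time bins.  Significant
windows are maximal runs of FDR-significant bins; the peak difference
and its latency are reported within significant bins.

Mixed models (random intercept per patient) assess whether trial-type
effects on response time or trial-wise high-gamma amplitude survive
adjustment for the other trial features.  An ROI-level fit is corrected
across ROIs per predictor (BH-FDR).  "Trial-type specificity" is the
conjunction of the permutation window and the mixed-model predictor
surviving FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    LatencySummary,
    MixedModelResult,
    PermTestResult,
    SpecificityVerdict,
)

logger = logging.getLogger(__name__)

RT_PREDICTORS = [
    "switch",
    "moving",
    "incongruent",
    "prior_incorrect",
    "log10_trial",
    "session",
]

#: Mapping from contrast name to the mixed-model predictor and trial flag.
CONTRAST_PREDICTOR = {
    "switch": "switch",
    "rule": "moving",
    "congruency": "incongruent",
    "prior_error": "prior_incorrect",
}


@dataclass
class PermConfig:
    n_permutations: int = 1000
    alpha: float = 0.05  # two-sided
    fdr_scope: Optional[int] = None  # bins corrected together; None = all given
    seed: int = 0


def fdr_adjust(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """NaN-aware t statistic per column of units x bins.

    Columns with fewer than 2 finite values get t = 0 (and hence p = 1
    in the permutation scheme).  Zero-variance columns get t = 0 when
    the mean is also zero and +-inf otherwise (a nonzero constant is
    maximally significant).
    """
    finite = np.isfinite(x)
    x0 = np.where(finite, x, 0.0)
    n = finite.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = x0.sum(axis=0) / n
        var = (np.square(x0).sum(axis=0) - n * m**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t = m / np.sqrt(var / n)
        t = np.where(var == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
        return np.where(n >= 2, t, 0.0)


def _windows_from_mask(sig: np.ndarray, times: np.ndarray) -> list[tuple[float, float]]:
    windows = []
    in_run = False
    start = 0
    for i, s in enumerate(sig):
        if s and not in_run:
            in_run, start = True, i
        elif not s and in_run:
            windows.append((float(times[start]), float(times[i - 1])))
            in_run = False
    if in_run:
        windows.append((float(times[start]), float(times[len(sig) - 1])))
    return windows


def _finalize(
    times: np.ndarray,
    t_obs: np.ndarray,
    effect: np.ndarray,
    p_raw: np.ndarray,
    config: PermConfig,
) -> PermTestResult:
    scope = config.fdr_scope or p_raw.size
    p_adj = np.empty_like(p_raw)
    for a in range(0, p_raw.size, scope):
        p_adj[a : a + scope] = fdr_adjust(p_raw[a : a + scope], config.alpha)
    sig = p_adj < config.alpha
    windows = _windows_from_mask(sig, times)
    peak_value = peak_latency = None
    if sig.any():
        idx = np.where(sig)[0]
        best = idx[np.argmax(np.abs(effect[idx]))]
        peak_value = float(effect[best])
        peak_latency = float(times[best])
    return PermTestResult(
        times_ms=np.asarray(times, dtype=float),
        observed_t=t_obs,
        effect=effect,
        p_raw=p_raw,
        p_adj=p_adj,
        alpha=config.alpha,
        windows=windows,
        peak_value=peak_value,
        peak_latency_ms=peak_latency,
    )


def permutation_one_sample(
    values: np.ndarray,
    times_ms: np.ndarray,
    config: Optional[PermConfig] = None,
) -> PermTestResult:
    """Sign-swap permutation one-sample t-test per time bin.

    ``values`` is units x bins (each unit: one site's trial-averaged
    percent-change series).  Sign flips are drawn per unit and applied
    to the unit's entire series.
    """
    if config is None:
        config = PermConfig()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a units x bins array with >= 2 units")
    rng = np.random.default_rng(config.seed)
    t_obs = _one_sample_t(values)
    n_units = values.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n_units))
    exceed = np.zeros(values.shape[1])
    for s in signs:
        t_perm = _one_sample_t(s[:, None] * values)
        exceed += np.abs(t_perm) >= np.abs(t_obs)
    p_raw = (1.0 + exceed) / (config.n_permutations + 1.0)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        effect = np.nanmean(values, axis=0)
    return _finalize(np.asarray(times_ms), t_obs, effect, p_raw, config)


def _two_sample_t(x: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware pooled-variance two-sample t per bin.

    Returns (t, mean difference).  Bins where either group has fewer
    than 2 finite values get t = 0 and difference NaN.
    """
    finite = np.isfinite(x)
    x0 = np.where(finite, x, 0.0)
    sq = np.square(x0)
    with np.errstate(divide="ignore", invalid="ignore"):
        na = finite[g].sum(axis=0)
        nb = finite[~g].sum(axis=0)
        ma = x0[g].sum(axis=0) / na
        mb = x0[~g].sum(axis=0) / nb
        va = np.maximum(sq[g].sum(axis=0) - na * ma**2, 0.0)
        vb = np.maximum(sq[~g].sum(axis=0) - nb * mb**2, 0.0)
        sp2 = (va + vb) / (na + nb - 2)
        d = ma - mb
        t = d / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = np.where(sp2 == 0, np.where(d == 0, 0.0, np.sign(d) * np.inf), t)
        t = np.where((na >= 2) & (nb >= 2), t, 0.0)
    return t, d


def permutation_two_sample(
    series_by_trial: np.ndarray,
    labels: np.ndarray,
    times_ms: np.ndarray,
    config: Optional[PermConfig] = None,
) -> PermTestResult:
    """Label-shuffling permutation two-sample t-test per time bin.

    ``series_by_trial`` is trials x bins; ``labels`` marks group A
    (e.g. switch) as True.  The effect is mean(A) - mean(B) in percent
    change; trial labels are exchangeable under the null.
    """
    if config is None:
        config = PermConfig()
    x = np.asarray(series_by_trial, dtype=float)
    g = np.asarray(labels, dtype=bool)
    if x.ndim != 2 or g.shape != (x.shape[0],):
        raise ValueError("series_by_trial must be trials x bins, labels per trial")
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("each group needs >= 2 trials")
    rng = np.random.default_rng(config.seed)
    t_obs, diff = _two_sample_t(x, g)
    exceed = np.zeros(x.shape[1])
    for _ in range(config.n_permutations):
        t_perm, _ = _two_sample_t(x, rng.permutation(g))
        exceed += np.abs(t_perm) >= np.abs(t_obs)
    p_raw = (1.0 + exceed) / (config.n_permutations + 1.0)
    return _finalize(np.asarray(times_ms), t_obs, diff, p_raw, config)


def extract_latencies(perm: PermTestResult) -> LatencySummary:
    """Onset/offset of the earliest significant window plus the peak.

    The peak is the maximum absolute effect across all significant bins
    (it therefore lies inside one of the windows whenever any exists).
    """
    if not perm.windows:
        return LatencySummary(None, None, None, None, [])
    onset, offset = perm.windows[0]
    return LatencySummary(
        onset_ms=onset,
        offset_ms=offset,
        peak_value=perm.peak_value,
        peak_latency_ms=perm.peak_latency_ms,
        windows=list(perm.windows),
    )


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix; derives moving/log10_trial if missing and
    drops rows with missing congruency."""
    d = df.copy()
    if "moving" not in d.columns and "rule" in d.columns:
        d["moving"] = (d["rule"] == "moving").astype(int)
    if "log10_trial" not in d.columns and "trial_index" in d.columns:
        d["log10_trial"] = np.log10(d["trial_index"].astype(float))
    if "switch" not in d.columns and "is_switch" in d.columns:
        d["switch"] = d["is_switch"].astype(int)
    if "incongruent" not in d.columns and "is_incongruent" in d.columns:
        d["incongruent"] = d["is_incongruent"]
    d = d.dropna(subset=[p for p in predictors if p in d.columns])
    for p in predictors:
        d[p] = d[p].astype(float)
    return d


def _mixed_fit(
    df: pd.DataFrame,
    endog_col: str,
    predictors: Sequence[str],
    group_col: str = "patient_id",
) -> MixedModelResult:
    """Random-intercept mixed model via statsmodels MixedLM (REML).

    A singular fit (random-intercept variance collapsing to zero) falls
    back to the corresponding OLS fixed-effects model with a logged
    warning.  Wald statistics are reported; the df column is the
    residual degrees of freedom of the fixed-effects design.
    """
    d = _design(df, predictors).dropna(subset=[endog_col])
    if d[group_col].nunique() < 2:
        raise ValueError("need >= 2 patients for a patient random intercept")
    exog = d[list(predictors)].copy()
    exog.insert(0, "intercept", 1.0)
    endog = d[endog_col].astype(float)
    n_obs = len(d)
    dof = max(n_obs - exog.shape[1], 1)
    backend = "statsmodels MixedLM (REML, patient random intercept)"
    converged = True
    re_var = res_var = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(endog.values, exog.values, groups=d[group_col].values)
            fit = model.fit(reml=True, method=["lbfgs", "bfgs"])
            re_var = float(np.squeeze(fit.cov_re))
            res_var = float(fit.scale)
            params = np.asarray(fit.fe_params)
            bse = np.asarray(fit.bse_fe)
            converged = bool(fit.converged)
        singular = (
            (not converged)
            or re_var < 1e-10 * max(res_var, 1e-12)
            or not np.all(np.isfinite(bse))
        )
    except Exception:  # pragma: no cover - defensive
        singular = True
    if singular:
        logger.warning("singular mixed fit for %s; falling back to OLS", endog_col)
        import statsmodels.api as sm

        fit = sm.OLS(endog.values, exog.values).fit()
        params, bse = fit.params, fit.bse
        backend = "statsmodels OLS fallback (singular random intercept)"
        re_var, res_var = 0.0, float(fit.mse_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.asarray(params) / np.asarray(bse)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    crit = sps.t.ppf(0.975, dof)
    names = ["intercept"] + list(predictors)
    table = pd.DataFrame(
        {
            "predictor": names,
            "estimate": np.asarray(params),
            "se": np.asarray(bse),
            "df": float(dof),
            "t": tvals,
            "p": pvals,
            "ci_low": np.asarray(params) - crit * np.asarray(bse),
            "ci_high": np.asarray(params) + crit * np.asarray(bse),
        }
    )
    return MixedModelResult(
        table=table,
        random_intercept_var=re_var,
        residual_var=res_var,
        n_obs=n_obs,
        n_groups=int(d[group_col].nunique()),
        backend=backend,
        converged=converged,
    )


def fit_rt_mixed_model(trial_table: pd.DataFrame) -> MixedModelResult:
    """Response-time mixed model: RT ~ trial features + (1 | patient).

    Fixed effects: switch, moving rule, incongruency, prior incorrect
    response, log10 trial number, game session.  Trials with missing
    congruency are dropped.
    """
    return _mixed_fit(trial_table, "response_time_ms", RT_PREDICTORS)


def fit_roi_mixed_model(
    hga_table: pd.DataFrame,
    roi_col: str = "roi",
    hga_col: str = "hga",
    fdr_q: float = 0.05,
) -> dict[str, MixedModelResult]:
    """Per-ROI mixed models of trial-wise high-gamma amplitude.

    ``hga_table`` is long format: one row per (trial, ROI) with the
    trial features and the trial's ROI high-gamma summary.  Per
    predictor, p-values are BH-FDR corrected across ROIs and stored in
    the ``p_fdr`` column of each ROI's table.
    """
    results: dict[str, MixedModelResult] = {}
    for roi, sub in hga_table.groupby(roi_col):
        results[roi] = _mixed_fit(sub, hga_col, RT_PREDICTORS)
    rois = sorted(results)
    for predictor in ["intercept"] + RT_PREDICTORS:
        p = np.array(
            [
                results[r].table.set_index("predictor").loc[predictor, "p"]
                for r in rois
            ]
        )
        p_adj = fdr_adjust(p, fdr_q)
        for r, pa in zip(rois, p_adj):
            tbl = results[r].table
            if "p_fdr" not in tbl.columns:
                tbl["p_fdr"] = np.nan
            tbl.loc[tbl["predictor"] == predictor, "p_fdr"] = pa
    return results


def classify_specificity(
    perm: PermTestResult,
    mm: MixedModelResult,
    roi: str,
    contrast: str,
    alpha: float = 0.05,
) -> SpecificityVerdict:
    """Dual-criterion trial-type specificity for one ROI and contrast.

    ``specific`` requires both a significant permutation window and the
    contrast's mixed-model predictor surviving the across-ROI FDR.
    """
    predictor = CONTRAST_PREDICTOR[contrast]
    perm_sig = len(perm.windows) > 0
    mm_sig = bool(mm.p_value(predictor, adjusted=True) < alpha)
    return SpecificityVerdict(
        roi=roi,
        contrast=contrast,
        permutation_significant=perm_sig,
        mixed_model_significant=mm_sig,
    )


def contingency_chi_square(
    correct_a: int, total_a: int, correct_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table
    of correct/incorrect counts for a trial type and its complement."""
    table = np.array(
        [
            [correct_a, total_a - correct_a],
            [correct_b, total_b - correct_b],
        ]
    )
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)
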