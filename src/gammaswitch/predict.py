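"""Trial-wise logistic prediction of upcoming response accuracy.

Among switch trials, a multivariate logistic regression predicts
whether the upcoming response will be correct from (a) the trial's ROI
high-gamma percent change, (b) task rule, (c) stimulus incongruency and
(d) game session.  Prior-response accuracy and trial number are
deliberately excluded to avoid circularity with the post-error and
practice effects.  Discrimination is assessed by 5-fold stratified
cross-validation: each trial is scored exactly once out-of-fold, the
pooled scores give the ROC curve and AUC, and the AUC confidence
interval comes from a stratified bootstrap of the pooled out-of-fold
scores.  The coefficient table (odds ratios with Wald CIs) comes from
an unpenalized full-data fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datatypes import PredictionResult

PREDICTORS = ["hga", "moving", "incongruent", "session"]


@dataclass
class PredictConfig:
    n_folds: int = 5
    seed: int = 0
    n_bootstrap: int = 2000
    restrict_to_switch: bool = True
    max_fold_retries: int = 5


def _fit_logit(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


def predict_accuracy(
    trial_table: pd.DataFrame,
    config: Optional[PredictConfig] = None,
    predictors: Sequence[str] = tuple(PREDICTORS),
) -> PredictionResult:
    """Cross-validated logistic prediction of response correctness.

    ``trial_table`` needs columns ``correct`` plus the predictors
    (``hga`` = the trial's ROI high-gamma percent change summarized
    over the ROI's significant post-cue window, ``moving``,
    ``incongruent``, ``session``) and, if ``restrict_to_switch``,
    ``is_switch`` or ``switch``.
    """
    if config is None:
        config = PredictConfig()
    df = trial_table.copy()
    if "moving" not in df.columns and "rule" in df.columns:
        df["moving"] = (df["rule"] == "moving").astype(int)
    if "incongruent" not in df.columns and "is_incongruent" in df.columns:
        df["incongruent"] = df["is_incongruent"]
    if config.restrict_to_switch:
        flag = df["switch"] if "switch" in df.columns else df["is_switch"]
        df = df[flag.astype(bool)]
    df = df.dropna(subset=[*predictors, "correct"])
    y = df["correct"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; nothing to classify")
    X = df[list(predictors)].astype(float).to_numpy()
    Xc = np.column_stack([np.ones(len(df)), X])

    full = _fit_logit(Xc, y)
    names = ["intercept"] + list(predictors)
    ci = full.conf_int()
    coef_table = pd.DataFrame(
        {
            "predictor": names,
            "coef": np.asarray(full.params),
            "se": np.asarray(full.bse),
            "p": np.asarray(full.pvalues),
            "odds_ratio": np.exp(np.asarray(full.params)),
            "or_ci_low": np.exp(np.asarray(ci)[:, 0]),
            "or_ci_high": np.exp(np.asarray(ci)[:, 1]),
        }
    )

    oof = np.full(len(y), np.nan)
    folds = np.full(len(y), -1)
    seed = config.seed
    for attempt in range(config.max_fold_retries):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
        try:
            for k, (tr, te) in enumerate(skf.split(Xc, y)):
                if len(np.unique(y[tr])) < 2:
                    raise np.linalg.LinAlgError("constant outcome in training fold")
                fit = _fit_logit(Xc[tr], y[tr])
                oof[te] = fit.predict(Xc[te])
                folds[te] = k
            break
        except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
            seed += 1
    else:
        raise RuntimeError("stratified folding failed repeatedly; outcome too unbalanced")

    fpr, tpr, _ = roc_curve(y, oof)
    auc = float(roc_auc_score(y, oof))
    auc_ci = _bootstrap_auc_ci(y, oof, config.n_bootstrap, config.seed)
    return PredictionResult(
        coef_table=coef_table,
        auc=auc,
        auc_ci=auc_ci,
        roc_fpr=fpr,
        roc_tpr=tpr,
        n_trials=len(y),
        fold_assignments=folds,
        oof_probabilities=oof,
    )


def _bootstrap_auc_ci(
    y: np.ndarray, scores: np.ndarray, n_boot: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the out-of-fold AUC."""
    rng = np.random.default_rng(seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        aucs[b] = roc_auc_score(y[idx], scores[idx])
    lo = (1.0 - level) / 2.0
    return float(np.quantile(aucs, lo)), float(np.quantile(aucs, 1.0 - lo))
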