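"""Core data containers for the task-switching high-gamma pipeline.

The containers mirror the stages of the analysis: trial bookkeeping
(:class:`TrialRecord`), electrode metadata (:class:`ElectrodeSite`),
continuous signals (:class:`Recording`), epoched signals
(:class:`EpochSet`), time-frequency results (:class:`TFRResult`,
:class:`HGASeries`), and statistical outputs (:class:`PermTestResult`,
:class:`MixedModelResult`, :class:`SpecificityVerdict`,
:class:`PredictionResult`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RULES = ("moving", "pointing")

TRIAL_COLUMNS = [
    "patient_id",
    "session",
    "trial_index",
    "rule",
    "is_switch",
    "is_incongruent",
    "prior_incorrect",
    "response_time_ms",
    "correct",
    "cue_onset",
]


@dataclass
class TrialRecord:
    """One trial's labels, timing and behavioral outcome.

    ``cue_onset`` is the sample index of the response-detection /
    feedback-sound onset that serves as the zero time point of all
    event-related analyses.  ``is_incongruent`` may be ``None``
    (missing; such trials are dropped from mixed-model fits).
    """

    patient_id: str
    session: int
    trial_index: int
    rule: str
    is_switch: bool
    is_incongruent: Optional[bool]
    prior_incorrect: bool = False
    response_time_ms: Optional[float] = None
    correct: Optional[bool] = None
    cue_onset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index starts at 1")
        if self.response_time_ms is not None and self.response_time_ms <= 0:
            raise ValueError("response_time_ms must be positive")


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate trials; adds the derived ``moving`` and ``log10_trial`` columns."""
    df = pd.DataFrame(
        [{c: getattr(t, c) for c in TRIAL_COLUMNS} for t in trials],
        columns=TRIAL_COLUMNS,
    )
    df["moving"] = (df["rule"] == "moving").astype(int)
    df["log10_trial"] = np.log10(df["trial_index"].astype(float))
    return df


@dataclass
class ElectrodeSite:
    """A subdural electrode contact with its atlas assignment."""

    label: str
    coordinates: tuple[float, float, float]
    roi: str
    hemisphere: str
    exclusion_reason: str = "none"

    VALID_REASONS = ("none", "seizure_onset", "lesion", "artifact")

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.exclusion_reason not in self.VALID_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.included and not self.roi:
            raise ValueError("included sites need a non-empty roi")

    @property
    def included(self) -> bool:
        return self.exclusion_reason == "none"


def montage_to_frame(montage: Sequence[ElectrodeSite]) -> pd.DataFrame:
    rows = []
    for s in montage:
        x, y, z = s.coordinates
        rows.append(
            {
                "name": s.label,
                "x": x,
                "y": y,
                "z": z,
                "hemisphere": s.hemisphere,
                "roi": s.roi,
                "included": s.included,
                "exclusion_reason": s.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Recording:
    """Continuous multichannel iEEG with event markers.

    ``session_bounds`` gives the [start, stop) sample range of each game
    session so that epoching can refuse windows that cross a session
    boundary.  ``events`` holds one cue-onset sample index per trial, in
    trial order.
    """

    data: np.ndarray  # channels x samples, microvolts
    sfreq: float
    ch_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    session_bounds: list[tuple[int, int]] = field(default_factory=list)
    kind: str = "gameplay"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names must match data rows")
        self.events = np.asarray(self.events, dtype=int)
        if self.events.size and (
            self.events.min() < 0 or self.events.max() >= self.n_samples
        ):
            raise ValueError("event sample indices must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def session_of_sample(self, sample: int) -> Optional[int]:
        for i, (a, b) in enumerate(self.session_bounds):
            if a <= sample < b:
                return i
        return None


@dataclass
class EpochSet:
    """Fixed-length signal epochs (trials x channels x samples).

    Gameplay epochs are centered on cue onsets; reference epochs are
    sampled from a non-gameplay rest recording.  ``alignment`` is the
    in-epoch sample index of the zero time point.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    alignment: int
    kind: str  # "gameplay" | "reference"
    trial_rows: Optional[pd.DataFrame] = None  # gameplay only
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample times relative to the zero point, in ms."""
        idx = np.arange(self.n_samples) - self.alignment
        return idx * 1000.0 / self.sfreq


@dataclass
class TFRResult:
    """Morlet amplitude, epochs x channels x frequencies x time bins.

    ``artifact_mask`` is True where a bin is excluded (edge bins where
    the wavelet support leaves the epoch, and bins failing the 30-85 Hz
    z-score artifact criterion).
    """

    amplitude: np.ndarray
    artifact_mask: np.ndarray
    freqs: np.ndarray  # Hz
    times_ms: np.ndarray  # relative to cue onset
    ch_names: list[str]

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.artifact_mask.shape:
            raise ValueError("amplitude and artifact_mask shapes differ")

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.amplitude, mask=self.artifact_mask)


@dataclass
class HGASeries:
    """Percent-change high-gamma amplitude time series.

    ``data`` is epochs x units x time bins where units are channels or
    ROIs depending on the aggregation level.  ``mode`` records the
    normalization baseline.
    """

    data: np.ndarray
    times_ms: np.ndarray
    labels: list[str]
    mode: str  # "vs_reference" | "vs_gameplay_mean"
    unit_counts: Optional[dict[str, int]] = None  # channels per ROI

    def trial_mean(self) -> np.ndarray:
        """units x time bins, averaged over epochs (NaN-aware).

        Bins masked in every epoch (e.g. wavelet edge bins) stay NaN.
        """
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", "Mean of empty slice")
            return np.nanmean(self.data, axis=0)


@dataclass
class PermTestResult:
    """Per-bin permutation test with BH-FDR and window extraction."""

    times_ms: np.ndarray
    observed_t: np.ndarray
    effect: np.ndarray  # per-bin mean (one-sample) or group difference, in %
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float
    windows: list[tuple[float, float]]
    peak_value: Optional[float]
    peak_latency_ms: Optional[float]

    @property
    def significant(self) -> np.ndarray:
        return self.p_adj < self.alpha


@dataclass
class LatencySummary:
    onset_ms: Optional[float]
    offset_ms: Optional[float]
    peak_value: Optional[float]
    peak_latency_ms: Optional[float]
    windows: list[tuple[float, float]]


@dataclass
class MixedModelResult:
    """Fixed-effect table of a random-intercept mixed model.

    ``table`` columns: predictor, estimate, se, df, t, p, ci_low,
    ci_high and (after ROI-level correction) p_fdr.  ``backend`` records
    the fitting engine and whether a fixed-effects fallback was used.
    """

    table: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_groups: int
    backend: str
    converged: bool

    def estimate(self, predictor: str) -> float:
        return float(self.table.set_index("predictor").loc[predictor, "estimate"])

    def ci(self, predictor: str) -> tuple[float, float]:
        row = self.table.set_index("predictor").loc[predictor]
        return float(row["ci_low"]), float(row["ci_high"])

    def p_value(self, predictor: str, adjusted: bool = False) -> float:
        col = "p_fdr" if adjusted and "p_fdr" in self.table.columns else "p"
        return float(self.table.set_index("predictor").loc[predictor, col])


@dataclass
class SpecificityVerdict:
    """Dual-criterion trial-type specificity call for one ROI/contrast."""

    roi: str
    contrast: str
    permutation_significant: bool
    mixed_model_significant: bool

    @property
    def specific(self) -> bool:
        return self.permutation_significant and self.mixed_model_significant


@dataclass
class PredictionResult:
    """Cross-validated logistic prediction of response accuracy."""

    coef_table: pd.DataFrame  # predictor, coef, se, p, odds_ratio, or_ci_low, or_ci_high
    auc: float
    auc_ci: tuple[float, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_trials: int
    fold_assignments: np.ndarray
    oof_probabilities: np.ndarray

    def odds_ratio(self, predictor: str) -> float:
        return float(self.coef_table.set_index("predictor").loc[predictor, "odds_ratio"])

    def or_ci(self, predictor: str) -> tuple[float, float]:
        row = self.coef_table.set_index("predictor").loc[predictor]
        return float(row["or_ci_low"]), float(row["or_ci_high"])
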