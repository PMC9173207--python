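"""Synthetic task sequences, behavior, and iEEG for the task-switch paradigm.

Emulates a self-paced color-rule switching game: on each trial the
player swipes in the direction a set of leaves is *pointing* (green
leaves) or *moving* (orange leaves).  The rule switches unpredictably,
with same-rule run lengths drawn i.i.d. from an empirical probability
mass function over lengths 1..10.  Response detection immediately
triggers the next cue, so inter-response intervals equal response
times and trial counts per fixed-length session are RT-limited.

Behavior follows a linear mixed model for response time (fixed effects:
switch, moving rule, stimulus incongruency, prior incorrect response,
log10 trial number, session; random intercept per patient) and a
logistic model for response accuracy, both with defaults matching the
published behavioral effect sizes of the paradigm.

Continuous iEEG is 1/f background noise plus event-locked narrowband
high-gamma tone bursts at configured ROIs, scaled per trial type and
per practice trend, plus occasional broadband spike artifacts to
exercise downstream artifact rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import ElectrodeSite, Recording, TrialRecord

logger = logging.getLogger(__name__)

#: Empirical pmf of same-rule run lengths 1..10 in the deployed game.
RUN_LENGTH_PMF = np.array(
    [0.064, 0.106, 0.135, 0.148, 0.143, 0.126, 0.100, 0.073, 0.048, 0.057]
)

#: Behavioral fixed effects on response time, ms per unit predictor
#: (switch cost +161 ms, moving-rule cost +176 ms, incongruency +92 ms,
#: post-error slowing +151 ms, log10-trial +13 ms, per-session practice
#: speedup -29 ms).
RT_FIXED_EFFECTS = {
    "switch": 161.0,
    "moving": 176.0,
    "incongruent": 92.0,
    "prior_incorrect": 151.0,
    "log10_trial": 13.0,
    "session": -29.0,
}

#: Observed accuracy contingencies (correct, total) for each trial type
#: and its complement, used to calibrate the logistic accuracy model.
ACCURACY_CONTINGENCIES = {
    "switch": ((243, 336), (1285, 1648)),
    "moving": ((673, 1000), (809, 917)),
    "incongruent": ((615, 933), (867, 984)),
    "prior_incorrect": ((262, 450), (1279, 1542)),
}

#: Marginal proportion of correct responses across all trials.
OVERALL_ACCURACY = 0.776

#: Mean response time across all trials, ms.
MEAN_RT_MS = 1360.0


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass
class RTModel:
    """Linear mixed model generating response times, in ms."""

    intercept: float
    coefs: dict[str, float] = field(default_factory=lambda: dict(RT_FIXED_EFFECTS))
    patient_sd: float = 150.0
    residual_sd: float = 400.0
    floor_ms: float = 300.0


@dataclass
class AccuracyModel:
    """Logistic model generating response correctness (logit scale)."""

    intercept: float
    coefs: dict[str, float] = field(default_factory=dict)


@dataclass
class BurstSpec:
    """An event-locked narrowband high-gamma burst at one ROI.

    The envelope is a boxcar over [onset, onset + duration] post-cue,
    smoothed with a 25-ms-sigma Gaussian so edges are gradual but the
    nominal window stays well defined (envelope = 0.5 at onset/offset).
    ``multipliers`` scale the amplitude on trials matching a contrast
    flag (keys: switch, moving, incongruent, prior_incorrect);
    ``trend_log10_trial`` / ``trend_session`` add multiplicative
    practice trends: factor = 1 + trend_log10_trial*log10(trial)
    + trend_session*(session-1).
    """

    roi: str
    onset_ms: float
    duration_ms: float
    freq_hz: float
    amplitude_uv: float
    multipliers: dict[str, float] = field(default_factory=dict)
    trend_log10_trial: float = 0.0
    trend_session: float = 0.0
    edge_sigma_ms: float = 25.0

    def __post_init__(self) -> None:
        if not (70.0 <= self.freq_hz <= 110.0):
            raise ValueError("burst center frequency must lie in [70, 110] Hz")


@dataclass
class NoiseSpec:
    """Background and artifact model for synthetic channels."""

    background_rms_uv: float = 15.0
    one_over_f_exponent: float = 1.0
    spike_rate_hz: float = 0.1
    spike_duration_ms: float = 50.0
    spike_amplitude_uv: float = 80.0
    #: spikes are lowpassed here so their energy falls in the 30-85 Hz
    #: artifact-detection band rather than the high-gamma band, as for
    #: real interictal discharges
    spike_lowpass_hz: float = 45.0


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic dataset, given a seed."""

    run_length_pmf: np.ndarray = field(default_factory=lambda: RUN_LENGTH_PMF.copy())
    p_incongruent: float = 0.47
    rt_model: RTModel = None  # type: ignore[assignment]
    accuracy_model: AccuracyModel = None  # type: ignore[assignment]
    tap_lead_ms: float = 333.0
    n_sessions: int = 5
    session_duration_s: float = 60.0
    rest_duration_s: float = 600.0
    sampling_rate: float = 1000.0
    burst_specs: list[BurstSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.run_length_pmf = np.asarray(self.run_length_pmf, dtype=float)
        validate_pmf(self.run_length_pmf)
        if self.rt_model is None:
            self.rt_model = RTModel(intercept=calibrate_rt_intercept(self))
        if self.accuracy_model is None:
            self.accuracy_model = default_accuracy_model(
                p_switch=self.expected_switch_fraction(),
                p_incongruent=self.p_incongruent,
            )

    def expected_switch_fraction(self) -> float:
        """Long-run switch fraction: (runs-1)/trials -> 1 / E[run length]."""
        k = np.arange(1, len(self.run_length_pmf) + 1)
        return float(1.0 / np.sum(k * self.run_length_pmf))


def validate_pmf(pmf: np.ndarray, tol: float = 1e-6) -> None:
    pmf = np.asarray(pmf, dtype=float)
    if pmf.ndim != 1 or pmf.size == 0:
        raise ValueError("run_length_pmf must be a non-empty vector")
    if np.any(pmf < 0):
        raise ValueError("run_length_pmf entries must be non-negative")
    if abs(pmf.sum() - 1.0) > tol:
        raise ValueError(f"run_length_pmf must sum to 1 (got {pmf.sum():.6f})")


def calibrate_rt_intercept(
    config: "GeneratorConfig",
    target_mean_ms: float = MEAN_RT_MS,
    coefs: Optional[dict[str, float]] = None,
) -> float:
    """Intercept such that the marginal mean RT matches ``target_mean_ms``.

    Uses the analytic expectation of each predictor under the task
    model: switch fraction from the run-length pmf, moving rule 1/2,
    incongruency base rate, prior-error rate = 1 - overall accuracy,
    E[log10 trial] over the RT-limited trials per session, and mean
    session (n_sessions+1)/2.
    """
    coefs = dict(RT_FIXED_EFFECTS) if coefs is None else coefs
    n_per_session = max(
        2, int(round(config.session_duration_s * 1000.0 / target_mean_ms))
    )
    e_log10 = float(np.mean(np.log10(np.arange(1, n_per_session + 1))))
    e_x = {
        "switch": config.expected_switch_fraction(),
        "moving": 0.5,
        "incongruent": config.p_incongruent,
        "prior_incorrect": 1.0 - OVERALL_ACCURACY,
        "log10_trial": e_log10,
        "session": (config.n_sessions + 1) / 2.0,
    }
    return target_mean_ms - sum(coefs[k] * e_x[k] for k in coefs)


def default_accuracy_model(
    p_switch: float = 0.172,
    p_incongruent: float = 0.47,
    target_overall: float = OVERALL_ACCURACY,
) -> AccuracyModel:
    """Logistic accuracy model calibrated to the observed contingencies.

    Each binary predictor's coefficient is the logit difference between
    its two marginal accuracy rates; the intercept is solved so that the
    expected overall accuracy (over independent predictor draws) matches
    the observed marginal rate.
    """
    coefs = {}
    for name, ((ca, na), (cb, nb)) in ACCURACY_CONTINGENCIES.items():
        coefs[name] = _logit(ca / na) - _logit(cb / nb)
    rates = {
        "switch": p_switch,
        "moving": 0.5,
        "incongruent": p_incongruent,
        "prior_incorrect": 1.0 - target_overall,
    }
    intercept = calibrate_accuracy_intercept(coefs, rates, target_overall)
    return AccuracyModel(intercept=intercept, coefs=coefs)


def calibrate_accuracy_intercept(
    coefs: dict[str, float], rates: dict[str, float], target: float
) -> float:
    """Solve for the intercept giving marginal P(correct) = target.

    Treats the binary predictors as independent Bernoulli draws with the
    supplied base rates and enumerates all combinations exactly.
    """
    names = [k for k in coefs if k in rates]
    combos = []
    for bits in range(2 ** len(names)):
        x = [(bits >> i) & 1 for i in range(len(names))]
        w = np.prod(
            [rates[n] if xi else 1.0 - rates[n] for n, xi in zip(names, x)]
        )
        eta = sum(coefs[n] * xi for n, xi in zip(names, x))
        combos.append((w, eta))
    w = np.array([c[0] for c in combos])
    eta = np.array([c[1] for c in combos])

    def marginal(b0: float) -> float:
        return float(np.sum(w * expit(b0 + eta)) - target)

    return brentq(marginal, -10.0, 10.0)


# ---------------------------------------------------------------------------
# Task sequence
# ---------------------------------------------------------------------------

def draw_run_lengths(n_trials: int, pmf: np.ndarray, rng: np.random.Generator):
    """Draw i.i.d. run lengths until they cover at least n_trials."""
    lengths = []
    covered = 0
    support = np.arange(1, len(pmf) + 1)
    while covered < n_trials:
        batch = rng.choice(support, size=max(16, n_trials // 4), p=pmf)
        for k in batch:
            lengths.append(int(k))
            covered += k
            if covered >= n_trials:
                break
    return lengths


def generate_task_sequence(
    n_trials: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    patient_id: str = "P01",
    session: int = 1,
) -> list[TrialRecord]:
    """Labels-only trial sequence for one session.

    The rule sequence is a concatenation of same-rule runs whose lengths
    are i.i.d. draws from ``run_length_pmf`` (the run process restarts
    at each session); congruency is i.i.d. Bernoulli(p_incongruent).
    The first trial of a session is neither a switch nor
    prior-incorrect.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    validate_pmf(config.run_length_pmf)
    lengths = draw_run_lengths(n_trials, config.run_length_pmf, rng)
    start_rule = rng.integers(2)
    rules: list[str] = []
    for i, k in enumerate(lengths):
        rules.extend([("moving", "pointing")[(start_rule + i) % 2]] * k)
    rules = rules[:n_trials]
    incong = rng.random(n_trials) < config.p_incongruent
    trials = []
    for i in range(n_trials):
        trials.append(
            TrialRecord(
                patient_id=patient_id,
                session=session,
                trial_index=i + 1,
                rule=rules[i],
                is_switch=(i > 0 and rules[i] != rules[i - 1]),
                is_incongruent=bool(incong[i]),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _predictors(trial: TrialRecord) -> dict[str, float]:
    return {
        "switch": float(trial.is_switch),
        "moving": float(trial.rule == "moving"),
        "incongruent": float(bool(trial.is_incongruent)),
        "prior_incorrect": float(trial.prior_incorrect),
        "log10_trial": float(np.log10(trial.trial_index)),
        "session": float(trial.session),
    }


def generate_behavior(
    trials: Sequence[TrialRecord],
    config: GeneratorConfig,
    rng: np.random.Generator,
    patient_intercepts: Optional[dict[str, float]] = None,
    session_start_sample: int = 0,
    enforce_session_cap: bool = True,
) -> list[TrialRecord]:
    """Fill response times, correctness and cue onsets for one session.

    Trials are processed sequentially: the prior-incorrect flag of trial
    n is recomputed from the drawn correctness of trial n-1, response
    time is the mixed-model linear predictor plus patient intercept and
    Gaussian residual (truncated below at the configured floor), and cue
    onsets accumulate response times from the session start.  Trials
    whose response would complete after the session ends are dropped.
    """
    rt = config.rt_model
    acc = config.accuracy_model
    if patient_intercepts is None:
        patient_intercepts = {}
    out: list[TrialRecord] = []
    session_samples = int(round(config.session_duration_s * config.sampling_rate))
    t_ms = 0.0
    prev_correct = True
    for trial in trials:
        b_pat = patient_intercepts.setdefault(
            trial.patient_id, float(rng.normal(0.0, rt.patient_sd)) if rt.patient_sd > 0 else 0.0
        )
        trial = replace(trial, prior_incorrect=(len(out) > 0 and not prev_correct))
        x = _predictors(trial)
        mu = rt.intercept + sum(rt.coefs.get(k, 0.0) * v for k, v in x.items())
        resp = mu + b_pat + (rng.normal(0.0, rt.residual_sd) if rt.residual_sd > 0 else 0.0)
        resp = max(resp, rt.floor_ms)
        if enforce_session_cap:
            if (t_ms + resp) / 1000.0 > config.session_duration_s:
                break  # partial trial dropped; session over
            cue = session_start_sample + int(
                round(t_ms * config.sampling_rate / 1000.0)
            )
            if cue >= session_start_sample + session_samples:
                break
        else:
            cue = session_start_sample + int(
                round(t_ms * config.sampling_rate / 1000.0)
            )
        eta = acc.intercept + sum(acc.coefs.get(k, 0.0) * v for k, v in x.items())
        correct = bool(rng.random() < expit(eta))
        out.append(
            replace(trial, response_time_ms=float(resp), correct=correct, cue_onset=cue)
        )
        t_ms += resp
        prev_correct = correct
    return out


def generate_patient_trials(
    patient_id: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trials_per_session: Optional[int] = None,
) -> list[TrialRecord]:
    """All completed trials for one patient across the configured sessions.

    By default each session is capped at its configured duration and
    yields however many trials the response times allow.  With
    ``trials_per_session`` set, exactly that many trials are generated
    per session with no time cap - the design for parameter-recovery
    experiments, where the time cap would otherwise select against slow
    trials and attenuate fitted effects.
    """
    rt = config.rt_model
    intercepts = {
        patient_id: float(rng.normal(0.0, rt.patient_sd)) if rt.patient_sd > 0 else 0.0
    }
    session_samples = int(round(config.session_duration_s * config.sampling_rate))
    # Generous upper bound on trials per session: session length over the RT floor.
    n_max = trials_per_session or (
        int(np.ceil(config.session_duration_s * 1000.0 / rt.floor_ms)) + 1
    )
    all_trials: list[TrialRecord] = []
    for sess in range(1, config.n_sessions + 1):
        labels = generate_task_sequence(
            n_max, config, rng, patient_id=patient_id, session=sess
        )
        done = generate_behavior(
            labels,
            config,
            rng,
            patient_intercepts=intercepts,
            session_start_sample=(sess - 1) * session_samples,
            enforce_session_cap=trials_per_session is None,
        )
        all_trials.extend(done)
    return all_trials


def generate_cohort_trials(
    n_patients: int,
    config: GeneratorConfig,
    seed: Optional[int] = None,
    trials_per_session: Optional[int] = None,
) -> list[TrialRecord]:
    """Completed trials for a cohort; one child RNG stream per patient."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    out: list[TrialRecord] = []
    for i, ss in enumerate(root.spawn(n_patients)):
        out.extend(
            generate_patient_trials(
                f"P{i + 1:02d}",
                config,
                np.random.default_rng(ss),
                trials_per_session=trials_per_session,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def simulate_switch_prediction_trials(
    n_trials: int,
    coef_hga: float,
    coef_session: float,
    rng: np.random.Generator,
    hga_sd: float = 20.0,
    coef_moving: float = 0.0,
    coef_incongruent: float = 0.0,
    target_accuracy: float = 243.0 / 336.0,
    n_sessions: int = 5,
) -> "pd.DataFrame":
    """Switch-trial table for the accuracy-prediction stage.

    Per-trial high-gamma percent change is Gaussian with the given SD;
    correctness follows a logistic model with the supplied
    log-odds-ratio coefficients for HGA (per 1% change) and session,
    with the intercept calibrated so marginal accuracy matches the
    switch-trial rate.  Rule, congruency and session are drawn
    independently (rule/congruency Bernoulli(1/2), session uniform).
    """
    import pandas as pd

    hga = rng.normal(0.0, hga_sd, size=n_trials)
    moving = rng.integers(2, size=n_trials).astype(float)
    incong = rng.integers(2, size=n_trials).astype(float)
    session = rng.integers(1, n_sessions + 1, size=n_trials).astype(float)
    eta_x = (
        coef_hga * hga
        + coef_session * session
        + coef_moving * moving
        + coef_incongruent * incong
    )

    def marginal(b0: float) -> float:
        return float(np.mean(expit(b0 + eta_x)) - target_accuracy)

    b0 = brentq(marginal, -20.0, 20.0)
    correct = rng.random(n_trials) < expit(b0 + eta_x)
    return pd.DataFrame(
        {
            "hga": hga,
            "moving": moving,
            "incongruent": incong,
            "session": session,
            "correct": correct,
            "is_switch": True,
        }
    )


def build_montage(
    roi_channels: dict[str, int],
    hemisphere: str = "right",
    n_excluded: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[ElectrodeSite]:
    """A simple synthetic montage: ``roi_channels`` maps ROI -> channel count.

    Coordinates are placeholders on a 10-mm grid (the pipeline only uses
    the ROI labels).  ``n_excluded`` appends artifact-excluded channels.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sites: list[ElectrodeSite] = []
    idx = 0
    for roi, n in roi_channels.items():
        hemi = hemisphere
        if roi.endswith("_left"):
            hemi = "left"
        elif roi.endswith("_right"):
            hemi = "right"
        for _ in range(n):
            sites.append(
                ElectrodeSite(
                    label=f"CH{idx + 1:03d}",
                    coordinates=(float(10 * idx), 0.0, 0.0),
                    roi=roi,
                    hemisphere=hemi,
                )
            )
            idx += 1
    for _ in range(n_excluded):
        sites.append(
            ElectrodeSite(
                label=f"CH{idx + 1:03d}",
                coordinates=(float(10 * idx), 0.0, 0.0),
                roi="excluded",
                hemisphere=hemisphere,
                exclusion_reason="artifact",
            )
        )
        idx += 1
    return sites


def default_burst_specs() -> list[BurstSpec]:
    """Event-locked burst layout mirroring the ROI findings the pipeline targets.

    A visual response common to all trials plus a precuneus burst whose
    amplitude is 1.5x on switch trials in a 330-780 ms window with a
    positive practice trend (repetition enhancement), and a calcarine
    burst with a switch effect and a negative log10-trial trend
    (repetition suppression).
    """
    return [
        BurstSpec(
            roi="calcarine_right",
            onset_ms=80.0,
            duration_ms=250.0,
            freq_hz=85.0,
            amplitude_uv=0.5,
        ),
        BurstSpec(
            roi="calcarine_right",
            onset_ms=260.0,
            duration_ms=460.0,
            freq_hz=85.0,
            amplitude_uv=0.35,
            multipliers={"switch": 1.4},
            trend_log10_trial=-0.15,
        ),
        BurstSpec(
            roi="precuneus_right",
            onset_ms=330.0,
            duration_ms=450.0,
            freq_hz=90.0,
            amplitude_uv=0.3,
            multipliers={"switch": 1.5},
            trend_log10_trial=0.1,
        ),
    ]


# ---------------------------------------------------------------------------
# Continuous signal synthesis
# ---------------------------------------------------------------------------

def one_over_f_noise(
    n_samples: int,
    sfreq: float,
    rms_uv: float,
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, given RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.power(f[nz], exponent)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    if sd > 0:
        x *= rms_uv / sd
    return x


def _burst_envelope(
    spec: BurstSpec, sfreq: float, rng_phase: float
) -> tuple[np.ndarray, int]:
    """Unit-peak smoothed-boxcar envelope times the carrier; returns
    (waveform, offset in samples of waveform start relative to cue)."""
    sigma = spec.edge_sigma_ms / 1000.0 * sfreq
    pad = int(round(4 * sigma))
    n_on = int(round(spec.onset_ms / 1000.0 * sfreq))
    n_dur = int(round(spec.duration_ms / 1000.0 * sfreq))
    n = n_dur + 2 * pad
    t = np.arange(n)
    box = ((t >= pad) & (t < pad + n_dur)).astype(float)
    if sigma > 0:
        k = np.exp(-0.5 * ((np.arange(-pad, pad + 1)) / sigma) ** 2)
        k /= k.sum()
        env = np.convolve(box, k, mode="same")
    else:
        env = box
    carrier = np.sin(2 * np.pi * spec.freq_hz * t / sfreq + rng_phase)
    return env * carrier, n_on - pad


def _trial_gain(spec: BurstSpec, trial: TrialRecord) -> float:
    g = 1.0
    flags = {
        "switch": trial.is_switch,
        "moving": trial.rule == "moving",
        "incongruent": bool(trial.is_incongruent),
        "prior_incorrect": trial.prior_incorrect,
    }
    for key, mult in spec.multipliers.items():
        if flags.get(key, False):
            g *= mult
    g *= 1.0 + spec.trend_log10_trial * np.log10(trial.trial_index)
    g *= 1.0 + spec.trend_session * (trial.session - 1)
    return max(g, 0.0)


def synthesize_ieeg(
    trials: Sequence[TrialRecord],
    montage: Sequence[ElectrodeSite],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Recording:
    """Continuous gameplay iEEG for one patient.

    Each channel is 1/f background noise; for every burst spec whose ROI
    matches the channel, a smoothed tone burst is added at
    cue_onset + onset for each trial, scaled by the trial-type
    multipliers and practice trend.  Broadband spike artifacts are
    inserted at the configured Poisson rate per channel.
    """
    if not montage:
        raise ValueError("montage must be non-empty")
    rois = {s.roi for s in montage}
    for spec in config.burst_specs:
        if spec.roi not in rois:
            raise ValueError(f"burst spec ROI {spec.roi!r} absent from montage")
    if any(t.cue_onset is None for t in trials):
        raise ValueError("trials must carry cue_onset (run generate_behavior first)")
    sfreq = config.sampling_rate
    session_samples = int(round(config.session_duration_s * sfreq))
    n_samples = config.n_sessions * session_samples
    data = np.empty((len(montage), n_samples))
    noise = config.noise
    for ci, site in enumerate(montage):
        chan = one_over_f_noise(
            n_samples, sfreq, noise.background_rms_uv, noise.one_over_f_exponent, rng
        )
        for spec in config.burst_specs:
            if spec.roi != site.roi:
                continue
            wave, rel0 = _burst_envelope(spec, sfreq, rng_phase=rng.uniform(0, 2 * np.pi))
            for trial in trials:
                a = int(trial.cue_onset) + rel0
                b = a + wave.size
                if a < 0 or b > n_samples:
                    continue
                chan[a:b] += spec.amplitude_uv * _trial_gain(spec, trial) * wave
        # Spike artifacts: Gaussian-envelope lowpassed-noise transients
        # (energy concentrated below spike_lowpass_hz, like interictal
        # discharges, so the 30-85 Hz z-score rule can catch them).
        n_spikes = rng.poisson(noise.spike_rate_hz * n_samples / sfreq)
        half = int(round(noise.spike_duration_ms / 1000.0 * sfreq / 2))
        if n_spikes and half > 0:
            sos = signal.butter(
                6, noise.spike_lowpass_hz, btype="low", fs=sfreq, output="sos"
            )
            for center in rng.integers(half, n_samples - half, size=n_spikes):
                w = np.arange(-half, half + 1)
                env = np.exp(-0.5 * (w / (half / 2.5)) ** 2)
                burst = signal.sosfiltfilt(sos, rng.standard_normal(w.size * 4))[
                    : w.size
                ]
                sd = burst.std()
                if sd > 0:
                    burst /= sd
                chan[center - half : center + half + 1] += (
                    noise.spike_amplitude_uv * env * burst
                )
        data[ci] = chan
    return Recording(
        data=data,
        sfreq=sfreq,
        ch_names=[s.label for s in montage],
        events=np.array([t.cue_onset for t in trials], dtype=int),
        session_bounds=[
            (s * session_samples, (s + 1) * session_samples)
            for s in range(config.n_sessions)
        ],
        kind="gameplay",
    )


def synthesize_rest(
    montage: Sequence[ElectrodeSite],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Recording:
    """Non-gameplay resting recording (background noise only)."""
    sfreq = config.sampling_rate
    n_samples = int(round(config.rest_duration_s * sfreq))
    noise = config.noise
    data = np.stack(
        [
            one_over_f_noise(
                n_samples, sfreq, noise.background_rms_uv, noise.one_over_f_exponent, rng
            )
            for _ in montage
        ]
    )
    return Recording(
        data=data,
        sfreq=sfreq,
        ch_names=[s.label for s in montage],
        kind="rest",
        session_bounds=[(0, n_samples)],
    )


@dataclass
class PatientData:
    """One synthetic patient: trials, montage, gameplay and rest recordings."""

    patient_id: str
    trials: list[TrialRecord]
    montage: list[ElectrodeSite]
    gameplay: Recording
    rest: Recording


def generate_patient(
    patient_id: str,
    config: GeneratorConfig,
    montage: Sequence[ElectrodeSite],
    seed_sequence: np.random.SeedSequence,
) -> PatientData:
    """Full synthetic dataset for one patient from one seed stream."""
    ss_beh, ss_sig, ss_rest = seed_sequence.spawn(3)
    trials = generate_patient_trials(patient_id, config, np.random.default_rng(ss_beh))
    gameplay = synthesize_ieeg(trials, montage, config, np.random.default_rng(ss_sig))
    rest = synthesize_rest(montage, config, np.random.default_rng(ss_rest))
    return PatientData(patient_id, trials, list(montage), gameplay, rest)


def generate_cohort(
    n_patients: int,
    config: GeneratorConfig,
    montage: Sequence[ElectrodeSite],
    seed: Optional[int] = None,
) -> list[PatientData]:
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    return [
        generate_patient(f"P{i + 1:02d}", config, montage, ss)
        for i, ss in enumerate(root.spawn(n_patients))
    ]
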