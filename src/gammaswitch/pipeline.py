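"""End-to-end orchestration: simulate -> preprocess -> TFR -> stats -> predict.

The cohort analysis mirrors the event-related high-gamma workflow:
common-average referencing, 2400-ms cue-centered epochs, Morlet
amplitude with artifact-bin rejection, percent-change normalization
(vs. rest for the overall response, vs. the gameplay mean for
trial-type contrasts), ROI aggregation, permutation statistics with
BH-FDR, per-ROI mixed models of trial-wise high-gamma amplitude, the
dual-criterion specificity call, and cross-validated logistic
prediction of response accuracy among switch trials.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gsio
from .datatypes import (
    HGASeries,
    MixedModelResult,
    PermTestResult,
    SpecificityVerdict,
)
from .predict import PredictConfig, predict_accuracy
from .preprocess import common_average_reference, extract_epochs, sample_reference_epochs
from .stats import (
    CONTRAST_PREDICTOR,
    PermConfig,
    classify_specificity,
    contingency_chi_square,
    extract_latencies,
    fit_roi_mixed_model,
    fit_rt_mixed_model,
    permutation_one_sample,
    permutation_two_sample,
)
from .synth import GeneratorConfig, PatientData, build_montage, default_burst_specs, generate_cohort
from .timefreq import TFRConfig, mark_artifact_bins, morlet_amplitude, percent_change, roi_aggregate

logger = logging.getLogger(__name__)

CONTRAST_FLAG = {
    "switch": "is_switch",
    "rule": "moving",
    "congruency": "is_incongruent",
    "prior_error": "prior_incorrect",
}


@dataclass
class PipelineConfig:
    generator: GeneratorConfig
    n_patients: int = 3
    roi_channels: dict[str, int] = field(
        default_factory=lambda: {"precuneus_right": 3, "calcarine_right": 3}
    )
    n_excluded_channels: int = 1
    tfr: TFRConfig = field(default_factory=TFRConfig)
    perm: PermConfig = field(default_factory=PermConfig)
    contrasts: tuple[str, ...] = ("switch", "rule", "congruency", "prior_error")
    predict_roi: str = "precuneus_right"
    predict_window_ms: tuple[float, float] = (330.0, 780.0)
    seed: int = 0


def default_pipeline_config(seed: int = 0) -> PipelineConfig:
    gen = GeneratorConfig(burst_specs=default_burst_specs(), seed=seed)
    return PipelineConfig(generator=gen, seed=seed)


@dataclass
class PatientAnalysis:
    patient_id: str
    trial_rows: pd.DataFrame
    roi_series_ref: HGASeries  # per-trial ROI series vs rest
    roi_series_game: HGASeries  # per-trial ROI series vs gameplay mean
    site_mean_ref: pd.DataFrame  # per-site trial-averaged series vs rest
    n_dropped: int
    n_masked_bins: int


def analyze_patient(
    p: PatientData, cfg: PipelineConfig, rng: np.random.Generator
) -> PatientAnalysis:
    """Preprocess and time-frequency stages for one patient."""
    car = common_average_reference(p.gameplay, p.montage)
    car_rest = common_average_reference(p.rest, p.montage)
    epochs = extract_epochs(car, p.trials)
    ref = sample_reference_epochs(car_rest, epochs.n_epochs, rng)
    tfr_game = mark_artifact_bins(morlet_amplitude(epochs, cfg.tfr), cfg.tfr)
    tfr_ref = mark_artifact_bins(morlet_amplitude(ref, cfg.tfr), cfg.tfr)
    pct_ref = percent_change(tfr_game, tfr_ref, "vs_reference", cfg.tfr)
    pct_game = percent_change(tfr_game, mode="vs_gameplay_mean", config=cfg.tfr)
    site_mean = pd.DataFrame(
        pct_ref.trial_mean(), index=pct_ref.labels, columns=pct_ref.times_ms
    )
    return PatientAnalysis(
        patient_id=p.patient_id,
        trial_rows=epochs.trial_rows,
        roi_series_ref=roi_aggregate(pct_ref, p.montage),
        roi_series_game=roi_aggregate(pct_game, p.montage),
        site_mean_ref=site_mean,
        n_dropped=epochs.n_dropped,
        n_masked_bins=int(tfr_game.artifact_mask.sum()),
    )


@dataclass
class CohortResults:
    trial_table: pd.DataFrame  # pooled trials with per-ROI HGA summaries
    times_ms: np.ndarray
    rois: list[str]
    one_sample: dict[str, PermTestResult]
    contrasts: dict[tuple[str, str], PermTestResult]  # (roi, contrast)
    roi_models: dict[str, MixedModelResult]
    rt_model: MixedModelResult
    chi_square: pd.DataFrame
    verdicts: list[SpecificityVerdict]
    prediction: Optional[object]
    counts: dict


def analyze_cohort(
    patients: Sequence[PatientData], cfg: PipelineConfig
) -> CohortResults:
    """Cohort-level statistics over per-patient analyses."""
    root = np.random.SeedSequence(cfg.seed)
    ss = root.spawn(len(patients) + 2)
    analyses = [
        analyze_patient(p, cfg, np.random.default_rng(s))
        for p, s in zip(patients, ss[: len(patients)])
    ]
    times = analyses[0].roi_series_game.times_ms
    rois = list(analyses[0].roi_series_game.labels)
    post = times >= 0

    # Pooled per-trial table with one HGA summary column per ROI
    # (mean percent change over the post-cue window, vs gameplay mean)
    frames = []
    for a in analyses:
        df = a.trial_rows.copy()
        for ri, roi in enumerate(rois):
            df[f"hga_{roi}"] = np.nanmean(
                a.roi_series_game.data[:, ri, :][:, post], axis=1
            )
        frames.append(df)
    trial_table = pd.concat(frames, ignore_index=True)

    # One-sample test vs rest: units = electrode sites pooled across patients
    one_sample: dict[str, PermTestResult] = {}
    site_rois = {}
    for p in patients:
        for s in p.montage:
            if s.included:
                site_rois[(p.patient_id, s.label)] = s.roi
    perm_cfg = cfg.perm
    for roi in rois:
        units = []
        for a in analyses:
            for label in a.site_mean_ref.index:
                if site_rois.get((a.patient_id, label)) == roi:
                    units.append(a.site_mean_ref.loc[label].to_numpy())
        if len(units) >= 2:
            one_sample[roi] = permutation_one_sample(
                np.vstack(units), times, perm_cfg
            )

    # Two-sample contrasts on per-trial ROI series, post-cue window
    contrasts: dict[tuple[str, str], PermTestResult] = {}
    series_all = np.concatenate([a.roi_series_game.data for a in analyses], axis=0)
    for roi_i, roi in enumerate(rois):
        x = series_all[:, roi_i, :][:, post]
        for contrast in cfg.contrasts:
            flag = CONTRAST_FLAG[contrast]
            lab = trial_table[flag].fillna(False).astype(bool).to_numpy()
            if lab.sum() < 2 or (~lab).sum() < 2:
                continue
            contrasts[(roi, contrast)] = permutation_two_sample(
                x, lab, times[post], perm_cfg
            )

    # Mixed models
    long = trial_table.melt(
        id_vars=[c for c in trial_table.columns if not c.startswith("hga_")],
        value_vars=[f"hga_{r}" for r in rois],
        var_name="roi",
        value_name="hga",
    )
    long["roi"] = long["roi"].str.removeprefix("hga_")
    roi_models = fit_roi_mixed_model(long)
    rt_model = fit_rt_mixed_model(trial_table)

    # Behavioral contingencies
    chi_rows = []
    for contrast in cfg.contrasts:
        flag = CONTRAST_FLAG[contrast]
        lab = trial_table[flag].fillna(False).astype(bool)
        corr = trial_table["correct"].astype(bool)
        ca, na = int((corr & lab).sum()), int(lab.sum())
        cb, nb = int((corr & ~lab).sum()), int((~lab).sum())
        if na == 0 or nb == 0:
            continue
        stat, pval = contingency_chi_square(ca, na, cb, nb)
        chi_rows.append(
            {
                "contrast": contrast,
                "correct_type": ca,
                "total_type": na,
                "correct_complement": cb,
                "total_complement": nb,
                "chi_square": stat,
                "p": pval,
            }
        )
    chi_square = pd.DataFrame(chi_rows)

    # Specificity verdicts
    verdicts = [
        classify_specificity(perm, roi_models[roi], roi, contrast, perm_cfg.alpha)
        for (roi, contrast), perm in contrasts.items()
    ]

    # Prediction at the configured ROI over its significant window
    prediction = None
    if cfg.predict_roi in rois:
        ri = rois.index(cfg.predict_roi)
        w0, w1 = cfg.predict_window_ms
        wsel = (times >= w0) & (times <= w1)
        ptab = trial_table.copy()
        ptab["hga"] = np.nanmean(series_all[:, ri, :][:, wsel], axis=1)
        try:
            prediction = predict_accuracy(
                ptab, PredictConfig(seed=cfg.seed)
            )
        except (ValueError, RuntimeError) as e:
            logger.warning("prediction skipped: %s", e)

    counts = {
        "n_patients": len(patients),
        "n_trials": int(len(trial_table)),
        "n_dropped_trials": int(sum(a.n_dropped for a in analyses)),
        "n_masked_bins": int(sum(a.n_masked_bins for a in analyses)),
        "n_rois": len(rois),
    }
    return CohortResults(
        trial_table=trial_table,
        times_ms=times,
        rois=rois,
        one_sample=one_sample,
        contrasts=contrasts,
        roi_models=roi_models,
        rt_model=rt_model,
        chi_square=chi_square,
        verdicts=verdicts,
        prediction=prediction,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(results: CohortResults, cfg: PipelineConfig, out_dir: Path) -> dict:
    """Write tabular outputs, plots, a JSON summary and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results.rt_model.table.to_csv(out / "rt_mixed_model.tsv", sep="\t", index=False)
    results.chi_square.to_csv(out / "accuracy_chi_square.tsv", sep="\t", index=False)

    lat_rows = []
    for (roi, contrast), perm in results.contrasts.items():
        lat = extract_latencies(perm)
        lat_rows.append(
            {
                "roi": roi,
                "contrast": contrast,
                "onset_ms": lat.onset_ms,
                "offset_ms": lat.offset_ms,
                "peak_pct": lat.peak_value,
                "peak_latency_ms": lat.peak_latency_ms,
                "n_windows": len(lat.windows),
            }
        )
    pd.DataFrame(lat_rows).to_csv(out / "contrast_latencies.tsv", sep="\t", index=False)

    mm_rows = []
    for roi, mm in results.roi_models.items():
        t = mm.table.copy()
        t.insert(0, "roi", roi)
        mm_rows.append(t)
    pd.concat(mm_rows, ignore_index=True).to_csv(
        out / "roi_mixed_models.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [
            {
                "roi": v.roi,
                "contrast": v.contrast,
                "permutation_significant": v.permutation_significant,
                "mixed_model_significant": v.mixed_model_significant,
                "specific": v.specific,
            }
            for v in results.verdicts
        ]
    ).to_csv(out / "specificity.tsv", sep="\t", index=False)

    summary = {"counts": results.counts}
    if results.prediction is not None:
        pr = results.prediction
        pr.coef_table.to_csv(out / "prediction_coefficients.tsv", sep="\t", index=False)
        pd.DataFrame({"fpr": pr.roc_fpr, "tpr": pr.roc_tpr}).to_csv(
            out / "prediction_roc.tsv", sep="\t", index=False
        )
        summary["prediction"] = {
            "roi": cfg.predict_roi,
            "auc": pr.auc,
            "auc_ci": list(pr.auc_ci),
            "n_trials": pr.n_trials,
        }
    summary["specific_rois"] = [
        {"roi": v.roi, "contrast": v.contrast} for v in results.verdicts if v.specific
    ]
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    _plot_roi_timecourses(results, out / "roi_timecourses.png")

    manifest = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "config": gsio.config_to_dict(cfg.generator),
        "tfr": dataclasses.asdict(cfg.tfr),
        "perm": dataclasses.asdict(cfg.perm),
        "counts": results.counts,
        "outputs": {
            f.name: _hash_file(f) for f in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def _plot_roi_timecourses(results: CohortResults, path: Path) -> None:
    """Per-ROI switch/repeat time courses with significance bars (advisory)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rois = results.rois
    fig, axes = plt.subplots(
        1, max(len(rois), 1), figsize=(4 * max(len(rois), 1), 3), squeeze=False
    )
    for ax, roi in zip(axes[0], rois):
        key = (roi, "switch")
        if key not in results.contrasts:
            continue
        perm = results.contrasts[key]
        ax.plot(perm.times_ms, perm.effect, color="crimson", lw=1)
        ax.axhline(0, color="0.6", lw=0.5)
        for w0, w1 in perm.windows:
            ax.plot([w0, w1], [ax.get_ylim()[0]] * 2, color="k", lw=3)
        ax.set_title(roi, fontsize=9)
        ax.set_xlabel("time post-cue (ms)")
        ax.set_ylabel("switch - repeat HGA (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, out_dir: Path) -> dict:
    """simulate -> analyze -> report; returns the JSON summary dict."""
    out = Path(out_dir)
    montage = build_montage(cfg.roi_channels, n_excluded=cfg.n_excluded_channels)
    patients = generate_cohort(cfg.n_patients, cfg.generator, montage, seed=cfg.seed)
    gsio.save_dataset(patients, cfg.generator, out / "dataset")
    results = analyze_cohort(patients, cfg)
    return write_report(results, cfg, out / "report")
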