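"""End-to-end orchestration: config, per-subject processing, cohort analysis.

The cohort pipeline runs: EEG QC -> zero-phase broadband+notch filtering
fused with band envelope extraction -> (optional) ICA cleaning ->
temporal PCA global envelopes -> HRF-convolved GLM with short-channel
nuisances -> six per-subject coupling metrics and unimodal powers ->
group t-tests -> leave-one-out linear classification with ROC/AUC,
bootstrap loadings, and recording-time / channel-count sweeps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import classify as _clf
from . import nc as _nc
from . import stats as _stats
from ._filters import butter_bandpass_sos, butter_bandstop_sos
from .eeg import (
    BandDefinition,
    BandEnvelopes,
    EEGRecording,
    band_power_envelopes,
    filter_eeg,
    qc_channels,
    remove_artifacts_ica,
)
from .errors import ParameterError
from .fnirs import (
    HemoglobinTimecourses,
    OpticalIntensity,
    filter_od,
    intensity_to_od,
    od_to_hemoglobin,
    qc_od,
    wavelet_motion_correct,
)
from .synthetic import CouplingSpec, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PreprocessedSubject",
    "CohortResult",
    "preprocess_subject",
    "nc_for_subject",
    "process_cohort",
    "run_pipeline",
    "sweep_recording_time",
    "sweep_channel_count",
]


@dataclass
class PipelineConfig:
    """All tunable parameters with study-default values."""

    # band definitions (Hz)
    bands: dict = field(default_factory=lambda: {"theta": (3.5, 8.2), "alpha": (7.4, 13.0), "beta": (13.0, 30.0)})
    # EEG cleaning
    eeg_filter_low_hz: float = 1.0
    eeg_filter_high_hz: float = 80.0
    notch_hz: float = 50.0
    eeg_filter_order: int = 2
    eeg_amp_limit_uv: float = 500.0
    run_ica: bool = False
    ica_kurtosis_threshold: float = 5.0
    ica_ref_corr_threshold: float = 0.7
    # analytic band envelopes are exact on a grid decimated by this factor
    # as long as fs/decim >= 2.5x the highest band edge (83.3 Hz for the
    # default 30 Hz beta edge at 250 Hz); set to 1 for full-rate envelopes
    envelope_decim: int = 3
    # fNIRS cleaning
    motion_correct: bool = True
    wavelet: str = "sym8"
    wavelet_kurtosis_threshold: float = 3.3
    wavelet_k_mad: float = 3.0
    od_low_hz: float = 0.01
    od_high_hz: float = 0.4
    od_filter_order: int = 4
    od_sd_ceiling: float = 0.2
    # GLM
    resample_hz: float = 1.0
    edge_trim_s: float = 5.0
    transient_trim_s: float = 30.0
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_undershoot_ratio: float = 6.0
    hrf_duration_s: float = 32.0
    # classification
    n_boot: int = 10000
    # sweeps
    sweep_time_step_s: float = 15.0
    sweep_time_max_s: float = 300.0
    sweep_channel_step: int = 4
    sweep_channel_max: int = 128
    # synthetic cohort
    n_ad: int = 17
    n_hc: int = 18
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi):
                raise ParameterError(f"band {name!r}: edges ({lo}, {hi}) must satisfy 0 < low < high")
        for name in ("eeg_filter_low_hz", "od_low_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.eeg_filter_low_hz >= self.eeg_filter_high_hz:
            raise ParameterError("EEG filter low edge must be below the high edge")
        if self.od_low_hz >= self.od_high_hz:
            raise ParameterError("OD filter low edge must be below the high edge")
        if self.duration_s < 30:
            raise ParameterError("recording duration must be >= 30 s")
        if self.n_boot < 0 or self.resample_hz <= 0:
            raise ParameterError("n_boot must be >= 0 and resample_hz positive")

    def band_definitions(self) -> list[BandDefinition]:
        return [BandDefinition(n, lo, hi) for n, (lo, hi) in self.bands.items()]

    def hrf_params(self) -> dict:
        return {
            "peak_delay_s": self.hrf_peak_delay_s,
            "undershoot_delay_s": self.hrf_undershoot_delay_s,
            "undershoot_ratio": self.hrf_undershoot_ratio,
            "duration_s": self.hrf_duration_s,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PreprocessedSubject:
    """Artifact-corrected band envelopes and hemoglobin for one subject."""

    envelopes: dict  # band name -> BandEnvelopes
    hb: HemoglobinTimecourses
    age: float
    label: int
    excluded_channels: list[int] = field(default_factory=list)
    rejected_eeg: list[str] = field(default_factory=list)


def preprocess_eeg(rec: EEGRecording, cfg: PipelineConfig):
    """EEG QC, cleaning and band envelopes (single fused FFT when ICA is off)."""
    rec, rejected = qc_channels(rec, cfg.eeg_amp_limit_uv)
    bands = cfg.band_definitions()
    pre_sos = [
        butter_bandpass_sos(cfg.eeg_filter_low_hz, cfg.eeg_filter_high_hz, rec.fs, cfg.eeg_filter_order)
    ]
    if cfg.notch_hz:
        pre_sos.append(butter_bandstop_sos(cfg.notch_hz - 2, cfg.notch_hz + 2, rec.fs, cfg.eeg_filter_order))
    if cfg.run_ica:
        filtered = filter_eeg(
            rec, cfg.eeg_filter_low_hz, cfg.eeg_filter_high_hz, cfg.notch_hz, order=cfg.eeg_filter_order
        )
        cleaned, report = remove_artifacts_ica(
            filtered, cfg.ica_kurtosis_threshold, cfg.ica_ref_corr_threshold, seed=cfg.seed
        )
        if report.flagged:
            logger.info("ICA removed components %s", report.flagged)
        envelopes = band_power_envelopes(cleaned, bands, decim=cfg.envelope_decim)
    else:
        envelopes = band_power_envelopes(rec, bands, pre_sos=pre_sos, decim=cfg.envelope_decim)
    return envelopes, rejected


def preprocess_fnirs(intensity: OpticalIntensity, age: float, cfg: PipelineConfig):
    """Intensities -> OD -> motion correction -> band filter -> hemoglobin + QC flags."""
    od = intensity_to_od(intensity)
    if cfg.motion_correct:
        od = wavelet_motion_correct(
            od, cfg.wavelet_kurtosis_threshold, wavelet=cfg.wavelet, k_mad=cfg.wavelet_k_mad
        )
    od = filter_od(od, cfg.od_low_hz, cfg.od_high_hz, cfg.od_filter_order)
    flagged = qc_od(od, cfg.od_sd_ceiling)
    if flagged:
        logger.info("OD QC flagged channels %s", flagged)
    hb = od_to_hemoglobin(od, age_years=age, model=None)
    return hb, flagged


def preprocess_subject(eeg: EEGRecording, intensity: OpticalIntensity, age: float, label: int,
                       cfg: PipelineConfig) -> PreprocessedSubject:
    envelopes, rejected = preprocess_eeg(eeg, cfg)
    hb, flagged = preprocess_fnirs(intensity, age, cfg)
    return PreprocessedSubject(
        envelopes=envelopes, hb=hb, age=age, label=label,
        excluded_channels=flagged, rejected_eeg=rejected,
    )


def _crop_centered(x: np.ndarray, fs: float, window_s: float, total_s: float) -> np.ndarray:
    start = (total_s - window_s) / 2.0
    i0 = int(round(start * fs))
    i1 = i0 + int(round(window_s * fs))
    return x[..., i0:i1]


def nc_for_subject(
    pre: PreprocessedSubject,
    cfg: PipelineConfig,
    channel_subset: np.ndarray | None = None,
    window_s: float | None = None,
):
    """Coupling metrics for one preprocessed subject.

    ``channel_subset`` restricts the EEG channels entering the per-band
    PCA; ``window_s`` crops a centered window out of envelopes and
    hemoglobin before estimation (recording-time sweep).  With neither
    argument this is the full analysis.
    """
    envelopes = pre.envelopes
    hb = pre.hb
    if channel_subset is not None:
        idx = np.asarray(channel_subset, dtype=int)
        envelopes = {
            name: BandEnvelopes(envelope=be.envelope[idx], fs=be.fs, band=be.band)
            for name, be in envelopes.items()
        }
    if window_s is not None:
        any_env = next(iter(envelopes.values()))
        total_s = any_env.envelope.shape[-1] / any_env.fs
        if window_s > total_s + 1e-9:
            raise ParameterError(f"window {window_s} s exceeds recording length {total_s:.1f} s")
        if window_s < total_s:
            envelopes = {
                name: BandEnvelopes(
                    envelope=_crop_centered(be.envelope, be.fs, window_s, total_s), fs=be.fs, band=be.band
                )
                for name, be in envelopes.items()
            }
            hb = HemoglobinTimecourses(
                hbo=_crop_centered(hb.hbo, hb.fs, window_s, total_s),
                hbr=_crop_centered(hb.hbr, hb.fs, window_s, total_s),
                fs=hb.fs,
                geometry=hb.geometry,
            )
    return _nc.estimate_subject_nc(
        envelopes,
        hb,
        edge_trim_s=cfg.edge_trim_s,
        transient_trim_s=cfg.transient_trim_s,
        target_fs=cfg.resample_hz,
        excluded_channels=pre.excluded_channels,
        hrf_params=cfg.hrf_params(),
    )


FEATURE_SETS = {
    "nc": ["theta-hbo", "alpha-hbo", "beta-hbo", "theta-hbr", "alpha-hbr", "beta-hbr"],
    "eeg": ["power-theta", "power-alpha", "power-beta"],
    "fnirs": ["power-hbo", "power-hbr"],
}


@dataclass
class CohortResult:
    features: pd.DataFrame  # subjects x (6 NC + 3 EEG powers + 2 fNIRS powers + variance fractions)
    labels: np.ndarray
    stats: pd.DataFrame
    classification: dict  # feature-set name -> dict of ROC/confusion/loadings
    provenance: dict


def subject_feature_row(metrics: _nc.SubjectNCMetrics, powers: _nc.UnimodalPowers) -> dict:
    row = {f"{b}-{c}": metrics.nc[(b, c)] for (b, c) in metrics.nc}
    row.update({f"power-{b}": v for b, v in powers.eeg_power.items()})
    row.update({f"power-{c}": v for c, v in powers.fnirs_power.items()})
    row.update({f"varfrac-{b}": v for b, v in metrics.variance_fractions.items()})
    return row


def cohort_features(cohort: SyntheticCohort, cfg: PipelineConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Process every subject (sequentially, bounded memory) into a feature table."""
    rows = []
    for i, subj in enumerate(cohort.subjects):
        pre = preprocess_subject(subj.eeg, subj.intensities, subj.age, subj.label, cfg)
        metrics, _, powers = nc_for_subject(pre, cfg)
        rows.append(subject_feature_row(metrics, powers))
        logger.debug("subject %d/%d processed", i + 1, len(cohort.subjects))
    return pd.DataFrame(rows), cohort.labels


def classify_features(features: pd.DataFrame, labels: np.ndarray, cfg: PipelineConfig,
                      feature_sets: dict | None = None) -> dict:
    """LOO-CV linear classification + ROC for each feature set."""
    out = {}
    for name, cols in (feature_sets or FEATURE_SETS).items():
        data = _clf.LabeledFeatures(features[cols].to_numpy(), labels, feature_names=cols)
        scores, fold_loadings = _clf.loocv_scores(data)
        roc = _clf.roc_analysis(scores, labels)
        cm = _clf.confusion_at_threshold(scores, labels)
        entry = {
            "scores": scores,
            "roc": roc,
            "confusion": cm,
            "loadings": fold_loadings.mean(axis=0),
            "feature_names": cols,
        }
        if cfg.n_boot:
            entry["bootstrap"] = _clf.bootstrap_loading_z(data, n_boot=cfg.n_boot, seed=cfg.seed)
        out[name] = entry
    return out


def process_cohort(cohort: SyntheticCohort, cfg: PipelineConfig) -> CohortResult:
    features, labels = cohort_features(cohort, cfg)
    metric_cols = FEATURE_SETS["nc"] + FEATURE_SETS["eeg"] + FEATURE_SETS["fnirs"]
    stats_table = _stats.group_comparison_table(features[metric_cols], labels)
    classification = classify_features(features, labels, cfg)
    provenance = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "n_subjects": len(labels)}
    return CohortResult(
        features=features, labels=labels, stats=stats_table, classification=classification, provenance=provenance
    )


def sweep_recording_time(
    cohort: SyntheticCohort,
    cfg: PipelineConfig,
    windows=None,
    n_boot: int | None = None,
) -> _clf.SweepResult:
    """AUC/loadings as a function of centered recording-time windows.

    Each subject is preprocessed once; coupling metrics are recomputed
    per window from the cropped envelopes and hemoglobin, then the
    LOO-CV classification is re-run per window.  The full-duration window
    reproduces the full analysis exactly.
    """
    if windows is None:
        windows = np.arange(cfg.sweep_time_step_s, cfg.sweep_time_max_s + 1e-9, cfg.sweep_time_step_s)
    windows = np.asarray(sorted(windows), dtype=float)
    per_window_rows = {w: [] for w in windows}
    labels = []
    for subj in cohort.subjects:
        pre = preprocess_subject(subj.eeg, subj.intensities, subj.age, subj.label, cfg)
        labels.append(subj.label)
        any_env = next(iter(pre.envelopes.values()))
        total_s = any_env.envelope.shape[-1] / any_env.fs
        for w in windows:
            if w > total_s + 1e-9:
                logger.warning("window %.0f s exceeds recording (%.0f s); skipped", w, total_s)
                continue
            metrics, _, _ = nc_for_subject(pre, cfg, window_s=float(w))
            per_window_rows[w].append(metrics.as_vector())
    labels = np.asarray(labels)
    return _evaluate_sweep(per_window_rows, windows, labels, cfg, n_boot, axis_name="recording_time_s")


def sweep_channel_count(
    cohort: SyntheticCohort,
    cfg: PipelineConfig,
    counts=None,
    seed: int | None = None,
    n_boot: int | None = None,
) -> _clf.SweepResult:
    """AUC/loadings as a function of the number of (randomly drawn) EEG channels.

    One channel subset is drawn per count (seeded) and applied to every
    subject; the full-count subset is the identity so that point
    reproduces the full analysis exactly.
    """
    n_total = cohort.subjects[0].eeg.n_channels
    if counts is None:
        counts = np.arange(cfg.sweep_channel_step, min(cfg.sweep_channel_max, n_total) + 1, cfg.sweep_channel_step)
    counts = np.asarray(sorted(counts), dtype=int)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    subsets = {}
    for c in counts:
        if c > n_total:
            logger.warning("channel count %d exceeds available %d; skipped", c, n_total)
            continue
        subsets[c] = np.arange(n_total) if c == n_total else np.sort(rng.choice(n_total, size=c, replace=False))
    per_count_rows = {c: [] for c in subsets}
    labels = []
    for subj in cohort.subjects:
        pre = preprocess_subject(subj.eeg, subj.intensities, subj.age, subj.label, cfg)
        labels.append(subj.label)
        for c, idx in subsets.items():
            metrics, _, _ = nc_for_subject(pre, cfg, channel_subset=idx)
            per_count_rows[c].append(metrics.as_vector())
    labels = np.asarray(labels)
    return _evaluate_sweep(per_count_rows, np.array(sorted(subsets)), labels, cfg, n_boot,
                           axis_name="n_channels", seed=seed)


def _evaluate_sweep(rows_by_value, axis, labels, cfg, n_boot, axis_name, seed=None):
    feature_names = _nc.SubjectNCMetrics.feature_names()
    n_boot = cfg.n_boot if n_boot is None else n_boot
    aucs, loadings, zs = [], [], []
    kept_axis = []
    for v in axis:
        rows = rows_by_value.get(v) or rows_by_value.get(int(v))
        if not rows or len(rows) != len(labels):
            continue
        data = _clf.LabeledFeatures(np.vstack(rows), labels, feature_names=feature_names)
        scores, fold_loadings = _clf.loocv_scores(data)
        aucs.append(_clf.roc_analysis(scores, labels).auc)
        loadings.append(fold_loadings.mean(axis=0))
        if n_boot:
            zs.append(_clf.bootstrap_loading_z(data, n_boot=n_boot, seed=cfg.seed).z)
        else:
            zs.append(np.full(len(feature_names), np.nan))
        kept_axis.append(v)
    return _clf.SweepResult(
        axis=np.asarray(kept_axis),
        auc=np.asarray(aucs),
        loadings=np.vstack(loadings),
        z=np.vstack(zs),
        seed=cfg.seed if seed is None else seed,
        axis_name=axis_name,
    )


def run_pipeline(cfg: PipelineConfig, out_dir=None, stages=("simulate", "nc", "stats", "classify"),
                 cohort: SyntheticCohort | None = None) -> CohortResult:
    """Run the configured analysis end to end and (optionally) write a results bundle.

    The bundle contains tidy CSVs (features, statistics, scores, ROC
    points, loadings) plus ``results.json`` with the headline numbers and
    full provenance (config hash, seed).  Re-running with the same config
    and seed reproduces it bit for bit.
    """
    if cohort is None:
        cohort = generate_cohort(
            n_ad=cfg.n_ad, n_hc=cfg.n_hc, duration_s=cfg.duration_s, seed=cfg.seed
        )
    result = process_cohort(cohort, cfg)
    if out_dir is not None:
        write_results_bundle(result, cfg, out_dir)
    return result


def write_results_bundle(result: CohortResult, cfg: PipelineConfig, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = dict(result.provenance)
    result.features.assign(
        label=result.labels, config_hash=prov.get("config_hash"), seed=prov.get("seed")
    ).to_csv(out / "features.csv", index=False)
    result.stats.assign(
        config_hash=prov.get("config_hash"), seed=prov.get("seed")
    ).to_csv(out / "statistics.csv", index=False)
    summary = {"provenance": prov, "classification": {}}
    for name, entry in result.classification.items():
        roc, cm = entry["roc"], entry["confusion"]
        pd.DataFrame({"subject": np.arange(len(entry["scores"])), "score": entry["scores"],
                      "label": result.labels}).to_csv(out / f"scores_{name}.csv", index=False)
        pd.DataFrame({"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                      "specificity": roc.specificity}).to_csv(out / f"roc_{name}.csv", index=False)
        load_df = pd.DataFrame({"feature": entry["feature_names"], "loading": entry["loadings"]})
        if "bootstrap" in entry:
            load_df["sd_boot"] = entry["bootstrap"].sd_boot
            load_df["z"] = entry["bootstrap"].z
        load_df.to_csv(out / f"loadings_{name}.csv", index=False)
        summary["classification"][name] = {
            "auc": roc.auc, "z": roc.z, "p": roc.p,
            "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn,
                          "threshold": cm.threshold,
                          "sensitivity": cm.sensitivity, "specificity": cm.specificity},
        }
    (out / "results.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
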