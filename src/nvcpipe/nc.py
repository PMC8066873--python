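"""Neurovascular coupling estimation.

Per subject and band, the z-scored channel envelopes feed a temporal PCA
whose first component is a volume-conduction-robust global band
envelope.  Each global envelope is convolved with a canonical
double-gamma hemodynamic response function, resampled to 1 Hz and
z-scored; together with the four z-scored short-separation hemoglobin
series (scalp nuisance) and an intercept they form the GLM design.  The
dependent variable is each long channel's z-scored hemoglobin series, so
every band beta is a standardized regression coefficient; the six
subject-level coupling metrics are the band betas averaged over long
channels, for HbO and HbR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln

from .eeg import BandDefinition, BandEnvelopes
from .errors import DataError, NumericalError, ParameterError
from .fnirs import HemoglobinTimecourses

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalEnvelope",
    "HRFKernel",
    "DesignMatrix",
    "ChannelBetas",
    "SubjectNCMetrics",
    "UnimodalPowers",
    "global_envelope_pca",
    "canonical_hrf",
    "block_resample",
    "build_design",
    "prepare_target",
    "fit_glm_channel",
    "subject_nc_metrics",
    "unimodal_powers",
    "estimate_subject_nc",
]

BAND_NAMES = ("theta", "alpha", "beta")
CHROMOPHORES = ("hbo", "hbr")


@dataclass
class GlobalEnvelope:
    """First temporal principal component of the z-scored band envelopes."""

    timecourse: np.ndarray
    fs: float
    variance_fraction: float
    band: BandDefinition


@dataclass
class HRFKernel:
    """Sampled canonical double-gamma hemodynamic response, peak-normalized."""

    kernel: np.ndarray
    fs: float
    peak_time_s: float
    undershoot_ratio: float


@dataclass
class DesignMatrix:
    """GLM design at 1 Hz: 3 band predictors + short-channel nuisances + intercept."""

    X: np.ndarray
    column_labels: list[str]
    fs: float
    trim_rows: int  # rows dropped at the start (convolution transient)
    n_rows_total: int  # rows before trimming (for target alignment)


@dataclass
class ChannelBetas:
    """Standardized band betas per long channel and chromophore."""

    beta: dict  # (band, chromophore) -> array over long channels
    residual_sd: dict  # (channel_id, chromophore) -> float
    channel_ids: list[int]


@dataclass
class SubjectNCMetrics:
    """The six global coupling metrics: (theta, alpha, beta) x (HbO, HbR)."""

    nc: dict  # (band, chromophore) -> float
    variance_fractions: dict = field(default_factory=dict)  # band -> float

    def as_vector(self, bands=BAND_NAMES, chromophores=CHROMOPHORES) -> np.ndarray:
        return np.array([self.nc[(b, c)] for c in chromophores for b in bands])

    @staticmethod
    def feature_names(bands=BAND_NAMES, chromophores=CHROMOPHORES) -> list[str]:
        return [f"{b}-{c}" for c in chromophores for b in bands]


@dataclass
class UnimodalPowers:
    """Standalone-modality metrics: mean band envelope power, hemoglobin SDs."""

    eeg_power: dict  # band -> mean squared envelope
    fnirs_power: dict  # chromophore -> mean over long channels of per-channel SD


def global_envelope_pca(envelopes: BandEnvelopes) -> GlobalEnvelope:
    """Temporal PCA across channels of the z-scored envelopes; returns PC1.

    The PC1 sign is fixed so the mean channel loading is positive, making
    betas comparable across subjects.  Zero-variance channels are dropped
    with a warning; all-zero input is an error.
    """
    env = np.asarray(envelopes.envelope)
    if env.ndim != 2 or env.shape[0] < 2:
        raise ParameterError("need a channels x samples envelope matrix with >= 2 channels")
    sd = env.std(axis=1)
    if (sd == 0).all():
        raise DataError("all envelope channels have zero variance")
    if (sd == 0).any():
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance envelope channel(s) from PCA")
        env = env[sd > 0]
        sd = sd[sd > 0]
    z = (env - env.mean(axis=1, keepdims=True)) / sd[:, None]
    n_ch, n_s = z.shape
    cov = (z @ z.T) / n_s
    eigval, eigvec = np.linalg.eigh(cov)
    v1 = eigvec[:, -1]
    if v1.mean() < 0:
        v1 = -v1
    pc1 = v1 @ z
    var_frac = float(eigval[-1] / eigval.sum())
    return GlobalEnvelope(
        timecourse=pc1.astype(np.float64),
        fs=envelopes.fs,
        variance_fraction=var_frac,
        band=envelopes.band,
    )


def canonical_hrf(
    fs: float,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    dispersion_s: float = 1.0,
    undershoot_ratio: float = 6.0,
    duration_s: float = 32.0,
) -> HRFKernel:
    """Canonical double-gamma HRF (peak ~5-6 s, undershoot ~16 s), max 1.

    h(t) = g(t; peak_delay, dispersion) - g(t; undershoot_delay, dispersion) / ratio
    with g a gamma density; h(0) = 0 and the kernel is peak-normalized.
    """
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    t = np.arange(0.0, duration_s, 1.0 / fs)

    def gamma_pdf(t, shape, scale):
        with np.errstate(divide="ignore"):
            logpdf = (shape - 1) * np.log(np.maximum(t, 1e-300)) - t / scale
        logpdf -= gammaln(shape) + shape * np.log(scale)
        pdf = np.exp(logpdf)
        pdf[t <= 0] = 0.0
        return pdf

    h = gamma_pdf(t, peak_delay_s / dispersion_s, dispersion_s)
    h -= gamma_pdf(t, undershoot_delay_s / dispersion_s, dispersion_s) / undershoot_ratio
    h /= np.abs(h).max()
    return HRFKernel(kernel=h, fs=fs, peak_time_s=float(t[np.argmax(h)]), undershoot_ratio=undershoot_ratio)


def block_resample(x: np.ndarray, fs: float, target_fs: float = 1.0) -> np.ndarray:
    """Resample by averaging non-overlapping time blocks (anti-alias by construction).

    Sample i (time i/fs) is assigned to bin floor(i * target_fs / fs);
    incomplete trailing bins are dropped.  Works for non-integer
    fs/target_fs ratios (e.g. 10.42 Hz -> 1 Hz).
    """
    x = np.asarray(x)
    n = x.shape[-1]
    bins = np.floor(np.arange(n) * (target_fs / fs)).astype(np.int64)
    n_bins = int(np.floor(n * target_fs / fs))
    if n_bins < 1:
        raise ParameterError("series too short to resample at the target rate")
    boundaries = np.searchsorted(bins, np.arange(n_bins))
    counts = np.diff(np.append(boundaries, np.searchsorted(bins, n_bins)))
    flat = x.reshape(-1, n)
    sums = np.add.reduceat(flat, boundaries, axis=-1)[:, :n_bins]
    out = sums / counts
    return out.reshape(x.shape[:-1] + (n_bins,))


def _zscore(x: np.ndarray, axis=-1) -> np.ndarray:
    sd = x.std(axis=axis, keepdims=True)
    return (x - x.mean(axis=axis, keepdims=True)) / sd


def _hrf_band_columns(globals_by_band, hrf_params, target_fs) -> dict:
    """HRF-convolved, block-resampled (not yet z-scored) band predictor columns."""
    cols = {}
    for name, g in globals_by_band.items():
        hrf_native = canonical_hrf(g.fs, **(hrf_params or {}))
        conv = fftconvolve(np.asarray(g.timecourse, dtype=np.float64), hrf_native.kernel)[: len(g.timecourse)]
        cols[name] = block_resample(conv, g.fs, target_fs)
    return cols


def build_design(
    globals_by_band: dict[str, GlobalEnvelope],
    short_hb: np.ndarray,
    short_fs: float,
    hrf_params: dict | None = None,
    target_fs: float = 1.0,
    trim_s: float = 30.0,
    include_short: bool = True,
    _band_columns: dict | None = None,
) -> DesignMatrix:
    """Assemble the GLM design matrix at ``target_fs``.

    Each global band envelope is convolved with the HRF at its native
    rate, block-resampled, and z-scored; the short-separation hemoglobin
    series (rows of ``short_hb`` at ``short_fs``, matching chromophore)
    are resampled and z-scored likewise.  The first ``trim_s`` seconds
    are dropped to absorb the convolution transient, and an intercept is
    appended last.  Raises on rank deficiency, naming the degenerate
    columns.
    """
    if _band_columns is None:
        _band_columns = _hrf_band_columns(globals_by_band, hrf_params, target_fs)
    cols, labels = [], []
    n_bins = None
    for name, col in _band_columns.items():
        cols.append(col)
        labels.append(name)
        n_bins = len(col) if n_bins is None else min(n_bins, len(col))
    if include_short and short_hb is not None and len(short_hb) > 0:
        for i, series in enumerate(np.atleast_2d(short_hb)):
            col = block_resample(series, short_fs, target_fs)
            cols.append(col)
            labels.append(f"short{i + 1}")
            n_bins = min(n_bins, len(col))
    trim = int(round(trim_s * target_fs))
    if n_bins - trim < 2:
        raise ParameterError(
            f"only {n_bins} rows at {target_fs} Hz; cannot trim {trim} transient rows"
        )
    X = np.column_stack([c[:n_bins] for c in cols])[trim:]
    sd = X.std(axis=0)
    mean = X.mean(axis=0)
    # a column is degenerate when it is (numerically) constant: exactly
    # zero spread, or spread negligible against its offset (e.g. the
    # convolution ramp of a constant envelope surviving the trim)
    degenerate = [
        lab
        for lab, s, m in zip(labels, sd, mean)
        if not np.isfinite(s) or s == 0 or s < 1e-3 * abs(m)
    ]
    if degenerate:
        raise DataError(f"degenerate (zero-variance) design column(s): {degenerate}")
    X = _zscore(X, axis=0)
    X = np.column_stack([X, np.ones(X.shape[0])])
    labels.append("intercept")
    r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    if (r < 1e-8 * r.max()).any():
        bad = [labels[i] for i in np.flatnonzero(r < 1e-8 * r.max())]
        raise NumericalError(f"design matrix rank deficient; collinear column(s): {bad}")
    return DesignMatrix(
        X=X, column_labels=labels, fs=target_fs, trim_rows=trim, n_rows_total=n_bins
    )


def prepare_target(y: np.ndarray, fs: float, design: DesignMatrix) -> np.ndarray:
    """Resample, align and z-score a long-channel hemoglobin series for the GLM."""
    col = block_resample(np.asarray(y, dtype=float), fs, design.fs)
    col = col[: design.n_rows_total][design.trim_rows :]
    if len(col) != design.X.shape[0]:
        raise DataError(
            f"target has {len(col)} rows after alignment, design has {design.X.shape[0]}"
        )
    sd = col.std()
    if sd == 0:
        raise DataError("target hemoglobin series has zero variance")
    return (col - col.mean()) / sd


def fit_glm_channel(design: DesignMatrix, y: np.ndarray, band_names=BAND_NAMES):
    """Ordinary least squares of one z-scored channel on the design.

    Returns ``(band_betas, all_betas, residual_sd)`` where ``band_betas``
    maps band name -> standardized coefficient.
    """
    X = design.X
    n, p = X.shape
    if len(y) != n:
        raise ParameterError(f"y has {len(y)} rows, design has {n}")
    if n <= p:
        raise ParameterError(f"need more rows ({n}) than columns ({p}) to fit the GLM")
    if n < 3 * p:
        logger.warning("GLM fit with only %d rows for %d columns; betas will be noisy", n, p)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise NumericalError("singular normal equations in GLM fit")
    resid = y - X @ beta
    residual_sd = float(resid.std(ddof=p))
    by_label = dict(zip(design.column_labels, beta))
    band_betas = {b: float(by_label[b]) for b in band_names if b in by_label}
    return band_betas, by_label, residual_sd


def subject_nc_metrics(betas: ChannelBetas, variance_fractions=None) -> SubjectNCMetrics:
    """Unweighted mean of the channel betas over long channels, per (band, chromophore)."""
    nc = {}
    for key, values in betas.beta.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise DataError(f"no long-channel betas for {key}")
        nc[key] = float(values.mean())
    return SubjectNCMetrics(nc=nc, variance_fractions=dict(variance_fractions or {}))


def unimodal_powers(
    envelopes_by_band: dict[str, BandEnvelopes], hb: HemoglobinTimecourses
) -> UnimodalPowers:
    """Standalone EEG/fNIRS activity metrics.

    EEG: mean over channels and time of the squared band envelope.
    fNIRS: per-channel standard deviation of HbO (and HbR), averaged over
    long channels.
    """
    if not envelopes_by_band:
        raise ParameterError("no band envelopes given")
    eeg_power = {
        name: float(np.mean(np.square(be.envelope), dtype=np.float64))
        for name, be in envelopes_by_band.items()
    }
    idx = hb.long_idx
    if idx.size == 0:
        raise DataError("no long channels in hemoglobin timecourses")
    fnirs_power = {
        "hbo": float(hb.hbo[idx].std(axis=-1).mean()),
        "hbr": float(hb.hbr[idx].std(axis=-1).mean()),
    }
    return UnimodalPowers(eeg_power=eeg_power, fnirs_power=fnirs_power)


def estimate_subject_nc(
    envelopes_by_band: dict[str, BandEnvelopes],
    hb: HemoglobinTimecourses,
    edge_trim_s: float = 5.0,
    transient_trim_s: float = 30.0,
    target_fs: float = 1.0,
    include_short: bool = True,
    excluded_channels: list[int] | None = None,
    hrf_params: dict | None = None,
):
    """Full per-subject coupling estimation.

    Trims filter/Hilbert edge transients from envelopes and hemoglobin,
    extracts the global envelope per band (PCA), builds one design per
    chromophore (matching-species short-channel nuisances) and fits each
    long channel, returning ``(SubjectNCMetrics, ChannelBetas,
    UnimodalPowers)``.  ``excluded_channels`` (QC) are left out of the
    channel average.

    Trims adapt to short records (windows in the recording-time sweep):
    the edge trim is capped at 5% of the duration per side and the
    transient trim at 20%.
    """
    any_env = next(iter(envelopes_by_band.values()))
    duration = any_env.envelope.shape[-1] / any_env.fs
    edge = min(edge_trim_s, 0.05 * duration)
    transient = min(transient_trim_s, 0.2 * duration)

    def trim_edges(x, fs):
        k = int(round(edge * fs))
        return x[..., k : x.shape[-1] - k] if k else x

    envs = {
        name: BandEnvelopes(
            envelope=trim_edges(be.envelope, be.fs), fs=be.fs, band=be.band, channel_labels=be.channel_labels
        )
        for name, be in envelopes_by_band.items()
    }
    globals_by_band = {name: global_envelope_pca(be) for name, be in envs.items()}
    variance_fractions = {name: g.variance_fraction for name, g in globals_by_band.items()}

    hbo = trim_edges(hb.hbo, hb.fs)
    hbr = trim_edges(hb.hbr, hb.fs)
    long_idx, short_idx = hb.long_idx, hb.short_idx
    if long_idx.size == 0 or (include_short and short_idx.size == 0):
        raise DataError("coupling estimation needs both long and short channels")
    excluded = set(excluded_channels or [])
    kept_long = [int(i) for i in long_idx if i not in excluded]
    if not kept_long:
        raise DataError("all long channels excluded by QC")
    if excluded:
        logger.info("QC excluded channels %s; averaging over %d long channels", sorted(excluded), len(kept_long))

    beta = {}
    residual_sd = {}
    band_columns = _hrf_band_columns(globals_by_band, hrf_params, target_fs)
    for chrom, series in (("hbo", hbo), ("hbr", hbr)):
        design = build_design(
            globals_by_band,
            short_hb=series[short_idx] if include_short else None,
            short_fs=hb.fs,
            target_fs=target_fs,
            trim_s=transient,
            include_short=include_short,
            hrf_params=hrf_params,
            _band_columns=band_columns,
        )
        per_band = {b: [] for b in globals_by_band}
        for ch in kept_long:
            y = prepare_target(series[ch], hb.fs, design)
            band_betas, _, rsd = fit_glm_channel(design, y, band_names=tuple(globals_by_band))
            residual_sd[(ch, chrom)] = rsd
            for b, v in band_betas.items():
                per_band[b].append(v)
        for b, vals in per_band.items():
            beta[(b, chrom)] = np.array(vals)

    channel_betas = ChannelBetas(beta=beta, residual_sd=residual_sd, channel_ids=kept_long)
    metrics = subject_nc_metrics(channel_betas, variance_fractions)
    powers = unimodal_powers(envs, HemoglobinTimecourses(hbo=hbo, hbr=hbr, fs=hb.fs, geometry=hb.geometry))
    return metrics, channel_betas, powers
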