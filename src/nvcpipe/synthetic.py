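"""Synthetic resting-state EEG-fNIRS subjects with known couplings.

The generator emulates the study design this pipeline targets: ~300 s of
128-channel EEG at 250 Hz plus 16 long (35 mm) and 4 short (15 mm)
dual-wavelength (690/830 nm) optical channels at 10.42 Hz, with a
patient-like and a control-like group distinguished by signed
band-to-chromophore couplings.

Forward model per subject:

1. Three band-limited Gaussian neural latents (theta/alpha/beta edges).
2. EEG = spatially smooth all-positive random mixing of the latents
   across channels (a crude stand-in for volume conduction) + sensor
   noise.
3. Each latent's Hilbert envelope, convolved with the canonical HRF and
   variance-normalized, drives long-channel HbO/HbR with the spec's
   signed coupling weights; a systemic scalp signal (narrowband ~0.1 Hz
   vasomotion plus a 0.2-0.3 Hz respiration component) leaks into long
   channels and fully occupies short channels.
4. Hemoglobin is pushed through the same Beer-Lambert extinction/DPF
   tables the analysis inverts, giving optical densities, then
   intensities I = I_m * exp(-OD); optional motion artifacts
   (exponentially decaying steps of random sign) are injected in OD
   space; white OD noise models the photon/electronics noise floor.

Everything is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve as _fftconvolve
from scipy.signal import hilbert as _hilbert

from ._filters import butter_bandpass_sos, zero_phase_filter
from .eeg import BAND_EDGES, EEGRecording
from .errors import ParameterError
from .fnirs import (
    ChannelGeometry,
    OpticalIntensity,
    PathlengthModel,
    default_geometry,
    hemoglobin_to_od,
)
from .nc import canonical_hrf

__all__ = [
    "CouplingSpec",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_latent_band_activity",
    "generate_subject",
    "generate_cohort",
]

BANDS = tuple(BAND_EDGES)
CHROMOPHORES = ("hbo", "hbr")


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth generator parameters for one group.

    ``beta_true`` maps (band, chromophore) to the dimensionless signed
    coupling between the HRF-convolved, unit-variance band envelope and
    the hemoglobin series.  Couplings are signed rather than fixed to a
    physiological convention because the sign of e.g. the alpha-HbR
    association is itself an empirical question.
    """

    beta_true: dict = field(default_factory=dict)
    scalp_gain_long: float = 0.3  # fraction of the systemic signal leaking into long channels
    noise_sd_eeg: float = 5.0  # sensor noise SD, uV
    noise_sd_od: float = 0.002  # optical-density noise SD (dimensionless)
    motion_spike_rate: float = 0.0  # artifacts per minute

    def __post_init__(self):
        full = {(b, c): 0.0 for b in BANDS for c in CHROMOPHORES}
        for key, v in self.beta_true.items():
            if key not in full:
                raise ParameterError(f"unknown coupling key {key!r}; use (band, 'hbo'|'hbr')")
            if not np.isfinite(v):
                raise ParameterError(f"coupling {key} must be finite, got {v}")
            full[key] = float(v)
        object.__setattr__(self, "beta_true", full)
        for name in ("scalp_gain_long", "noise_sd_eeg", "noise_sd_od", "motion_spike_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @staticmethod
    def hc_default() -> "CouplingSpec":
        """Control-like group: positive theta-HbO and alpha-HbR couplings."""
        return CouplingSpec(beta_true={("theta", "hbo"): 0.4, ("alpha", "hbr"): 0.4})

    @staticmethod
    def ad_default() -> "CouplingSpec":
        """Patient-like group: neurovascular un-coupling (all couplings zero)."""
        return CouplingSpec()


@dataclass
class SyntheticSubject:
    eeg: EEGRecording
    intensities: OpticalIntensity
    age: float
    label: int  # 1 patient-like, 0 control-like
    truth: CouplingSpec
    seed: int | None = None
    truth_hb: dict | None = None  # noise-free injected hemoglobin, uM ('hbo'/'hbr')


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    seed: int
    group_specs: dict  # {"ad": CouplingSpec, "hc": CouplingSpec}

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])


def generate_latent_band_activity(
    band_low_hz: float, band_high_hz: float, duration_s: float, fs_hz: float, seed
) -> np.ndarray:
    """Zero-mean unit-variance band-limited Gaussian series (deterministic per seed)."""
    if not (0 < band_low_hz < band_high_hz < fs_hz / 2):
        raise ParameterError(
            f"band ({band_low_hz}, {band_high_hz}) Hz invalid for fs = {fs_hz} Hz"
        )
    if duration_s <= 0:
        raise ParameterError(f"duration must be positive, got {duration_s}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    white = rng.standard_normal(n)
    sos = butter_bandpass_sos(band_low_hz, band_high_hz, fs_hz, order=4)
    x = zero_phase_filter(white, sos, fs_hz, method="filtfilt")
    return (x - x.mean()) / x.std()


def _channel_layout(n_channels: int) -> np.ndarray:
    """Deterministic sunflower layout on the unit disc; +y is anterior."""
    k = np.arange(n_channels) + 0.5
    r = np.sqrt(k / n_channels)
    theta = k * (np.pi * (3.0 - np.sqrt(5.0)))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _systemic_signal(n: int, fs: float, rng) -> np.ndarray:
    """Scalp confound: ~0.1 Hz vasomotion plus a respiration-band component."""
    vaso = zero_phase_filter(rng.standard_normal(n), butter_bandpass_sos(0.08, 0.12, fs, 4), fs, "filtfilt")
    resp = zero_phase_filter(rng.standard_normal(n), butter_bandpass_sos(0.2, 0.3, fs, 4), fs, "filtfilt")
    s = vaso / vaso.std() + 0.5 * resp / resp.std()
    return (s - s.mean()) / s.std()


def _motion_spikes(n: int, fs: float, rate_per_min: float, sd_ref: float, rng) -> np.ndarray:
    """Exponentially decaying steps of random sign, amplitudes 5-10 x sd_ref."""
    art = np.zeros(n)
    n_spikes = rng.poisson(rate_per_min * (n / fs) / 60.0)
    t = np.arange(n) / fs
    for _ in range(n_spikes):
        t0 = rng.uniform(0, n / fs)
        amp = rng.uniform(5.0, 10.0) * sd_ref * rng.choice([-1.0, 1.0])
        tau = rng.uniform(0.3, 1.0)
        art += np.where(t >= t0, amp * np.exp(-(t - t0) / tau), 0.0)
    return art


def generate_subject(
    spec: CouplingSpec,
    age: float,
    label: int,
    duration_s: float = 300.0,
    seed=0,
    n_eeg_channels: int = 128,
    fs_eeg: float = 250.0,
    fs_od: float = 10.42,
    n_long: int = 16,
    n_short: int = 4,
    hemo_scale_um: float = 0.5,
    background_gain: float = 0.3,
    model: PathlengthModel | None = None,
) -> SyntheticSubject:
    """Generate one raw-format subject from a coupling specification.

    ``hemo_scale_um`` sets the physical scale (uM per unit-variance
    component) of the hemoglobin fluctuations; it cancels in the
    standardized analysis but controls the signal-to-noise ratio against
    the OD noise floor.  ``background_gain`` weights a spontaneous
    hemodynamic background (an HRF-convolved envelope of a latent that
    does *not* appear in the EEG) shared by all groups: resting
    hemodynamics fluctuate whether or not they track the recorded
    electrical activity, and without this term the groups would differ
    in hemoglobin spectral content rather than only in coupling.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration must be positive, got {duration_s}")
    if duration_s < 30:
        raise ParameterError(f"duration must be >= 30 s, got {duration_s}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(7)]
    rng_latent, rng_mix, rng_eegnoise, rng_sys, rng_odnoise, rng_motion, rng_bg = rngs

    n_eeg = int(round(duration_s * fs_eeg))
    n_od = int(round(duration_s * fs_od))
    model = model or PathlengthModel()

    # --- neural latents and EEG -----------------------------------------
    latents = {
        band: generate_latent_band_activity(lo, hi, duration_s, fs_eeg, rng_latent)
        for band, (lo, hi) in BAND_EDGES.items()
    }
    positions = _channel_layout(n_eeg_channels)
    mixing = np.empty((n_eeg_channels, len(latents)))
    for j in range(len(latents)):
        center = rng_mix.uniform(-0.7, 0.7, size=2)
        amp = rng_mix.uniform(8.0, 12.0)  # uV scale of the rhythm
        d2 = ((positions - center) ** 2).sum(axis=1)
        mixing[:, j] = amp * np.exp(-d2 / (2 * 0.35**2))
    latent_mat = np.stack([latents[b] for b in BAND_EDGES], axis=0).astype(np.float32)
    eeg_data = mixing.astype(np.float32) @ latent_mat
    eeg_data += spec.noise_sd_eeg * rng_eegnoise.standard_normal((n_eeg_channels, n_eeg), dtype=np.float32)
    eeg = EEGRecording(data=eeg_data, fs=fs_eeg, channel_positions=positions)

    # --- hemodynamic drive ----------------------------------------------
    hrf = canonical_hrf(fs_od)
    t_od = np.arange(n_od) / fs_od
    t_eeg = np.arange(n_eeg) / fs_eeg
    drives = {}
    for band, x in latents.items():
        env = np.abs(_hilbert(x))
        env_od = np.interp(t_od, t_eeg, env)
        conv = np.convolve(env_od, hrf.kernel)[:n_od]
        drives[band] = (conv - conv.mean()) / conv.std()

    systemic = _systemic_signal(n_od, fs_od, rng_sys)
    systemic_hbr = 0.4 * systemic  # scalp HbR swings are smaller, same waveform

    # spontaneous cortical hemodynamics uncoupled from the recorded EEG:
    # same spectral recipe as the neural drives, independent latent
    bg_latent = generate_latent_band_activity(7.4, 13.0, duration_s, fs_eeg, rng_bg)
    bg_env = np.interp(t_od, t_eeg, np.abs(_hilbert(bg_latent)))
    bg = _fftconvolve(bg_env, hrf.kernel)[:n_od]
    background_hbo = (bg - bg.mean()) / bg.std()
    background_hbr = -0.5 * background_hbo  # spontaneous HbR anticorrelates

    geometry = default_geometry(n_long, n_short)
    n_ch = n_long + n_short
    hbo = np.zeros((n_ch, n_od))
    hbr = np.zeros((n_ch, n_od))
    gain = rng_sys.uniform(0.8, 1.2, size=n_long)  # mild channel-to-channel coupling variation
    neural_hbo = sum(spec.beta_true[(b, "hbo")] * drives[b] for b in BAND_EDGES)
    neural_hbr = sum(spec.beta_true[(b, "hbr")] * drives[b] for b in BAND_EDGES)
    for c in range(n_long):
        hbo[c] = gain[c] * neural_hbo + background_gain * background_hbo + spec.scalp_gain_long * systemic
        hbr[c] = gain[c] * neural_hbr + background_gain * background_hbr + spec.scalp_gain_long * systemic_hbr
    for c in range(n_long, n_ch):
        hbo[c] = systemic
        hbr[c] = systemic_hbr
    # normalize each channel to a fixed physical scale: coupling changes the
    # correlation structure of the hemodynamics, not their overall power
    # (group differences in raw fluctuation amplitude are not part of the
    # emulated physiology)
    sd = hbo.std(axis=1, keepdims=True)
    hbo = np.where(sd > 0, hbo / np.where(sd > 0, sd, 1.0), hbo)
    sd = hbr.std(axis=1, keepdims=True)
    hbr = np.where(sd > 0, hbr / np.where(sd > 0, sd, 1.0), hbr)
    hbo *= hemo_scale_um
    hbr *= hemo_scale_um

    # --- forward optics ---------------------------------------------------
    od = hemoglobin_to_od(hbo, hbr, geometry, age, model=model)
    if spec.motion_spike_rate > 0:
        for c in range(n_ch):
            sd_ref = max(od[c].std(), 1e-6)
            art = _motion_spikes(n_od, fs_od, spec.motion_spike_rate, sd_ref, rng_motion)
            od[c] += art[None, :]  # same artifact on both wavelengths of the pair
    if spec.noise_sd_od > 0:
        od += spec.noise_sd_od * rng_odnoise.standard_normal(od.shape)
    i_m = rng_odnoise.uniform(0.5, 2.0, size=(n_ch, od.shape[1], 1))
    intensities = OpticalIntensity(
        data=i_m * np.exp(-od), fs=fs_od, wavelengths=(690.0, 830.0), geometry=geometry
    )
    return SyntheticSubject(
        eeg=eeg,
        intensities=intensities,
        age=float(age),
        label=int(label),
        truth=spec,
        seed=seed if isinstance(seed, int) else None,
        truth_hb={"hbo": hbo, "hbr": hbr},
    )


def generate_cohort(
    spec_ad: CouplingSpec | None = None,
    spec_hc: CouplingSpec | None = None,
    n_ad: int = 17,
    n_hc: int = 18,
    duration_s: float = 300.0,
    seed: int = 0,
    age_mean: float = 73.0,
    age_sd: float = 7.5,
    age_min: float = 50.0,
    **subject_kwargs,
) -> SyntheticCohort:
    """Generate a two-group cohort (defaults mirror a 17 patient / 18 control design).

    Per-subject seeds are spawned deterministically from the cohort seed;
    ages are normal(73, 7.5) truncated at 50 years.
    """
    if n_ad < 0 or n_hc < 0:
        raise ParameterError("group sizes must be >= 0")
    if n_ad + n_hc == 0:
        raise ParameterError("at least one group must be non-empty")
    spec_ad = spec_ad or CouplingSpec.ad_default()
    spec_hc = spec_hc or CouplingSpec.hc_default()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_ad + n_hc)

    def draw_age():
        while True:
            a = rng.normal(age_mean, age_sd)
            if a >= age_min:
                return float(a)

    subjects = []
    for i in range(n_ad + n_hc):
        label = 1 if i < n_ad else 0
        spec = spec_ad if label == 1 else spec_hc
        subjects.append(
            generate_subject(
                spec, age=draw_age(), label=label, duration_s=duration_s,
                seed=child_seeds[i], **subject_kwargs,
            )
        )
    return SyntheticCohort(subjects=subjects, seed=seed, group_specs={"ad": spec_ad, "hc": spec_hc})
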