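"""File formats: interchange bundle, SNIRF (HDF5) optics, EDF reading.

The interchange bundle is a single ``.npz`` container of named arrays
plus one JSON metadata entry (sampling rates, geometry, labels, the
generator's ground-truth coupling spec).  It is the canonical storage
for synthetic subjects because it can round-trip ground truth that the
acquisition formats have no slot for.  Optical data can additionally be
written/read as SNIRF; EEG in EDF is read through :mod:`mne`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .eeg import EEGRecording
from .errors import DataError
from .fnirs import ChannelGeometry, OpticalIntensity
from .synthetic import CouplingSpec, SyntheticCohort, SyntheticSubject

__all__ = [
    "write_bundle",
    "read_bundle",
    "write_cohort",
    "read_cohort",
    "write_snirf",
    "read_snirf",
    "read_edf",
    "load_subject",
]

BUNDLE_VERSION = 1


def _spec_to_dict(spec: CouplingSpec) -> dict:
    return {
        "beta_true": {f"{b}:{c}": v for (b, c), v in spec.beta_true.items()},
        "scalp_gain_long": spec.scalp_gain_long,
        "noise_sd_eeg": spec.noise_sd_eeg,
        "noise_sd_od": spec.noise_sd_od,
        "motion_spike_rate": spec.motion_spike_rate,
    }


def _spec_from_dict(d: dict) -> CouplingSpec:
    beta = {tuple(k.split(":")): v for k, v in d["beta_true"].items()}
    return CouplingSpec(
        beta_true=beta,
        scalp_gain_long=d["scalp_gain_long"],
        noise_sd_eeg=d["noise_sd_eeg"],
        noise_sd_od=d["noise_sd_od"],
        motion_spike_rate=d["motion_spike_rate"],
    )


def write_bundle(subject: SyntheticSubject, path) -> None:
    """Write one subject (raw EEG + intensities + ground truth) to a ``.npz`` bundle."""
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "fs_eeg": subject.eeg.fs,
        "fs_od": subject.intensities.fs,
        "eeg_labels": subject.eeg.channel_labels,
        "wavelengths": list(subject.intensities.wavelengths),
        "geometry": [
            {"channel_id": g.channel_id, "rho_mm": g.rho_mm, "role": g.role}
            for g in subject.intensities.geometry
        ],
        "age": subject.age,
        "label": subject.label,
        "seed": subject.seed,
        "truth": _spec_to_dict(subject.truth),
    }
    arrays = {
        "eeg": subject.eeg.data,
        "intensities": subject.intensities.data,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if subject.eeg.channel_positions is not None:
        arrays["eeg_positions"] = subject.eeg.channel_positions
    if subject.truth_hb is not None:
        arrays["truth_hbo"] = subject.truth_hb["hbo"]
        arrays["truth_hbr"] = subject.truth_hb["hbr"]
    np.savez(path, **arrays)


def read_bundle(path) -> SyntheticSubject:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        eeg = EEGRecording(
            data=z["eeg"],
            fs=meta["fs_eeg"],
            channel_labels=meta["eeg_labels"],
            channel_positions=z["eeg_positions"] if "eeg_positions" in z else None,
        )
        geometry = [ChannelGeometry(g["channel_id"], g["rho_mm"], g["role"]) for g in meta["geometry"]]
        intensities = OpticalIntensity(
            data=z["intensities"], fs=meta["fs_od"], wavelengths=tuple(meta["wavelengths"]), geometry=geometry
        )
        truth_hb = None
        if "truth_hbo" in z:
            truth_hb = {"hbo": z["truth_hbo"], "hbr": z["truth_hbr"]}
    return SyntheticSubject(
        eeg=eeg, intensities=intensities, age=meta["age"], label=meta["label"],
        truth=_spec_from_dict(meta["truth"]), seed=meta["seed"], truth_hb=truth_hb,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write per-subject bundles plus a JSON manifest recording seeds and specs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, subj in enumerate(cohort.subjects):
        name = f"subject_{i:03d}.npz"
        write_bundle(subj, out / name)
        files.append({"file": name, "label": subj.label, "age": subj.age})
    manifest = {
        "seed": cohort.seed,
        "n_subjects": len(cohort.subjects),
        "group_specs": {k: _spec_to_dict(v) for k, v in cohort.group_specs.items()},
        "subjects": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def read_cohort(in_dir) -> SyntheticCohort:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    subjects = [read_bundle(in_dir / entry["file"]) for entry in manifest["subjects"]]
    specs = {k: _spec_from_dict(v) for k, v in manifest["group_specs"].items()}
    return SyntheticCohort(subjects=subjects, seed=manifest["seed"], group_specs=specs)


# --------------------------------------------------------------------------
# SNIRF (Shared Near Infrared Spectroscopy Format, an HDF5 layout)
# --------------------------------------------------------------------------

def write_snirf(intensity: OpticalIntensity, path) -> None:
    """Write continuous-wave intensities as a minimal valid SNIRF file.

    One source/detector pair per channel; optode positions are laid out
    so the source-detector distance equals the channel's rho, letting
    readers recover the long/short role geometrically.
    """
    import h5py

    n_ch, n_wl, n_s = intensity.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(intensity.wavelengths, dtype=float))
        src = np.zeros((n_ch, 3))
        det = np.zeros((n_ch, 3))
        for i, g in enumerate(intensity.geometry):
            src[i] = (i * 50.0, 0.0, 0.0)
            det[i] = (i * 50.0 + g.rho_mm, 0.0, 0.0)
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)
        data = nirs.create_group("data1")
        series = intensity.data.transpose(2, 0, 1).reshape(n_s, n_ch * n_wl)
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_s) / intensity.fs)
        k = 1
        for c in range(n_ch):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=c + 1)
                ml.create_dataset("detectorIndex", data=c + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")


def read_snirf(path, long_threshold_mm: float = 25.0) -> OpticalIntensity:
    """Read a continuous-wave SNIRF file into an :class:`OpticalIntensity`.

    Channels are (source, detector) pairs; every channel must carry both
    probe wavelengths.  Pairs with source-detector distance below
    ``long_threshold_mm`` are classified as short-separation.
    """
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        wavelengths = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
        src = nirs["probe"]["sourcePos3D"][()]
        det = nirs["probe"]["detectorPos3D"][()]
        data = nirs["data1"]
        series = data["dataTimeSeries"][()]
        time = data["time"][()]
        fs = 1.0 / np.median(np.diff(time)) if len(time) > 2 else 1.0 / (time[1] - time[0])
        columns = {}
        keys = sorted((k for k in data.keys() if k.startswith("measurementList")),
                      key=lambda s: int(s[len("measurementList"):]))
        for col, key in enumerate(keys):
            ml = data[key]
            pair = (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]))
            wl = wavelengths[int(ml["wavelengthIndex"][()]) - 1]
            columns.setdefault(pair, {})[wl] = col
    pairs = sorted(columns)
    arrays = []
    geometry = []
    for i, pair in enumerate(pairs):
        cols = columns[pair]
        missing = [wl for wl in wavelengths if wl not in cols]
        if missing:
            raise DataError(
                f"SNIRF channel source {pair[0]}/detector {pair[1]} missing wavelength(s) {missing} nm"
            )
        arrays.append(np.stack([series[:, cols[wl]] for wl in wavelengths]))
        rho = float(np.linalg.norm(src[pair[0] - 1] - det[pair[1] - 1]))
        role = "long" if rho >= long_threshold_mm else "short"
        geometry.append(ChannelGeometry(i, rho, role))
    return OpticalIntensity(
        data=np.stack(arrays), fs=float(fs), wavelengths=wavelengths, geometry=geometry
    )


def read_edf(path) -> EEGRecording:
    """Read an EDF EEG file (voltages returned in microvolt)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names)
    )


def load_subject(eeg_path, fnirs_path, meta: dict | None = None,
                 max_duration_mismatch_s: float = 5.0):
    """Load and align one subject's EEG and optical recordings.

    Accepts ``.edf``/``.npz`` for EEG and ``.snirf``/``.npz`` for optics
    (``.npz`` meaning the interchange bundle, in which case both paths may
    point at the same file).  The two recordings are trimmed to their
    common duration; a mismatch above ``max_duration_mismatch_s`` is an
    error.  Returns ``(EEGRecording, OpticalIntensity, meta)``.
    """
    meta = dict(meta or {})
    eeg_path, fnirs_path = Path(eeg_path), Path(fnirs_path)
    if eeg_path.suffix == ".edf":
        eeg = read_edf(eeg_path)
    elif eeg_path.suffix == ".npz":
        subj = read_bundle(eeg_path)
        eeg = subj.eeg
        meta.setdefault("age", subj.age)
        meta.setdefault("label", subj.label)
    else:
        raise DataError(f"unsupported EEG format {eeg_path.suffix!r} (use .edf or .npz)")
    if fnirs_path.suffix == ".snirf":
        optics = read_snirf(fnirs_path)
    elif fnirs_path.suffix == ".npz":
        optics = read_bundle(fnirs_path).intensities
    else:
        raise DataError(f"unsupported fNIRS format {fnirs_path.suffix!r} (use .snirf or .npz)")

    dur_eeg = eeg.n_samples / eeg.fs
    dur_opt = optics.n_samples / optics.fs
    if abs(dur_eeg - dur_opt) > max_duration_mismatch_s:
        raise DataError(
            f"EEG ({dur_eeg:.1f} s) and fNIRS ({dur_opt:.1f} s) durations differ by more than "
            f"{max_duration_mismatch_s} s"
        )
    common = min(dur_eeg, dur_opt)
    if dur_eeg > common:
        eeg = EEGRecording(eeg.data[:, : int(round(common * eeg.fs))], eeg.fs,
                           eeg.channel_labels, eeg.channel_positions)
    if dur_opt > common:
        optics = OpticalIntensity(optics.data[:, :, : int(round(common * optics.fs))],
                                  optics.fs, optics.wavelengths, optics.geometry)
    return eeg, optics, meta
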