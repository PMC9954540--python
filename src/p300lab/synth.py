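"""Synthetic P300 oddball sessions.

Emulates a visual oddball ("Brain Invaders"-style) recording: 16-channel EEG
at 128 Hz where, for each of 8 target symbols, 8 repetitions of 12 flashes
are presented and exactly 2 flashes per repetition contain the target.
TARGET flashes evoke a positive deflection peaking 240-600 ms post-stimulus;
noise is pink (1/f) Gaussian plus a small common-mode component, identical
for both classes, so the only class difference is the evoked template.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, ParameterError

#: integer class codes used throughout the package
TARGET = 1
NONTARGET = 0


def default_spatial_profile(n_channels: int) -> np.ndarray:
    """Per-channel weight vector concentrated on parieto-central channels.

    A smooth bump centred at ~2/3 of the channel index range (where Cz/Pz
    sit in a front-to-back montage ordering), normalized to peak 1.
    """
    idx = np.arange(n_channels, dtype=float)
    centre = 0.65 * (n_channels - 1)
    width = max(0.18 * n_channels, 1.0)
    w = np.exp(-0.5 * ((idx - centre) / width) ** 2)
    return w / w.max()


@dataclass(frozen=True)
class SessionDesign:
    """Counts and timings of one oddball session."""

    n_symbols_total: int = 36
    n_targets: int = 8
    n_repetitions_per_target: int = 8
    flashes_per_repetition: int = 12
    target_flashes_per_repetition: int = 2
    n_channels: int = 16
    sfreq: float = 128.0
    isi: float = 0.4

    def __post_init__(self) -> None:
        counts = {
            "n_symbols_total": self.n_symbols_total,
            "n_targets": self.n_targets,
            "n_repetitions_per_target": self.n_repetitions_per_target,
            "flashes_per_repetition": self.flashes_per_repetition,
            "target_flashes_per_repetition": self.target_flashes_per_repetition,
            "n_channels": self.n_channels,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {value!r}")
        if self.target_flashes_per_repetition >= self.flashes_per_repetition:
            raise ParameterError(
                "target_flashes_per_repetition must be < flashes_per_repetition"
            )
        if self.sfreq <= 0:
            raise ParameterError(f"sfreq must be > 0, got {self.sfreq}")
        if self.isi <= 0:
            raise ParameterError(f"isi must be > 0, got {self.isi}")

    @property
    def n_flashes(self) -> int:
        return (
            self.n_targets
            * self.n_repetitions_per_target
            * self.flashes_per_repetition
        )

    @property
    def n_target_flashes(self) -> int:
        return (
            self.n_targets
            * self.n_repetitions_per_target
            * self.target_flashes_per_repetition
        )


@dataclass
class P300Params:
    """Shape of the evoked deflection added to TARGET epochs."""

    peak_latency: float = 0.35
    width: float = 0.2
    amplitude: float = 5.0
    spatial_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ParameterError(f"amplitude must be >= 0, got {self.amplitude}")

    def resolve_profile(self, n_channels: int) -> np.ndarray:
        if self.spatial_profile is None:
            return default_spatial_profile(n_channels)
        profile = np.asarray(self.spatial_profile, dtype=float)
        if profile.shape != (n_channels,):
            raise ParameterError(
                f"spatial_profile must have {n_channels} entries, got {profile.shape}"
            )
        return profile


@dataclass
class EpochSet:
    """Labelled windows of multichannel EEG."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    labels: np.ndarray  # (n_trials,) ints in {TARGET, NONTARGET}
    sfreq: float
    window: tuple[float, float]  # (tmin, tmax) seconds relative to onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ParameterError(
                f"epoch data must be (trials, channels, samples), got {self.data.shape}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError(
                f"labels length {len(self.labels)} != number of trials "
                f"{self.data.shape[0]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def p300_template(
    params: P300Params, sfreq: float, duration: float = 0.8
) -> np.ndarray:
    """Single-channel evoked waveform: a Gaussian-windowed positive bump.

    The maximum sits at the sample nearest ``peak_latency``; ``width`` is
    twice the Gaussian standard deviation, so the bump has effectively
    decayed at ``peak_latency +/- width``.
    """
    if params.width <= 0:
        raise ParameterError("width must be > 0")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if duration < params.peak_latency + params.width:
        raise ParameterError(
            "duration must be >= peak_latency + width "
            f"({params.peak_latency + params.width:.3f} s), got {duration}"
        )
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    sigma = params.width / 2.0
    return params.amplitude * np.exp(-0.5 * ((t - params.peak_latency) / sigma) ** 2)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-power Gaussian noise per row, unit standard deviation."""
    n_rows, n_samples = shape
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    # amplitude ~ f^{-1/2} => power ~ 1/f; clamp below the first bin
    f0 = freqs[1] if len(freqs) > 1 else 1.0
    scale = 1.0 / np.sqrt(np.maximum(freqs, f0))
    noise = np.fft.irfft(spectrum * scale, n=n_samples, axis=-1)
    std = noise.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std


def generate_session(
    design: SessionDesign = SessionDesign(),
    p300: P300Params | None = None,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one continuous session.

    Returns
    -------
    record : (n_channels, n_samples) array, microvolts
    onsets : (n_flashes,) int array of flash onset sample indices
    labels : (n_flashes,) int array, TARGET (1) or NONTARGET (0)
    """
    if p300 is None:
        p300 = P300Params()
    if noise_scale < 0:
        raise ParameterError(f"noise_scale must be >= 0, got {noise_scale}")
    rng = np.random.default_rng(seed)

    lead_in = 1.0
    tail = 2.0
    n_flashes = design.n_flashes
    n_samples = int(round((lead_in + n_flashes * design.isi + tail) * design.sfreq))

    onsets = np.array(
        [
            int(round((lead_in + k * design.isi) * design.sfreq))
            for k in range(n_flashes)
        ],
        dtype=int,
    )

    # label pattern: per repetition, target flashes at seeded random positions
    labels = np.zeros(n_flashes, dtype=int)
    n_reps = design.n_targets * design.n_repetitions_per_target
    for r in range(n_reps):
        pos = rng.choice(
            design.flashes_per_repetition,
            size=design.target_flashes_per_repetition,
            replace=False,
        )
        labels[r * design.flashes_per_repetition + pos] = TARGET

    record = noise_scale * _pink_noise(rng, (design.n_channels, n_samples))
    if noise_scale > 0:
        common = 0.2 * noise_scale * _pink_noise(rng, (1, n_samples))
        record += common  # broadcast over channels

    profile = p300.resolve_profile(design.n_channels)
    duration = max(0.8, p300.peak_latency + p300.width)
    template = p300_template(p300, design.sfreq, duration)
    for onset in onsets[labels == TARGET]:
        stop = min(onset + len(template), n_samples)
        record[:, onset:stop] += profile[:, None] * template[: stop - onset]

    return record, onsets, labels


# ---------------------------------------------------------------------------
# serialization: a zip archive of raw little-endian arrays + a JSON manifest
# sidecar (field names, dtypes, shapes, scalar metadata).

_EPOCH_ARRAYS = ("data", "labels")


def _write_archive(path: Path, arrays: dict[str, np.ndarray], meta: dict) -> None:
    manifest = {"arrays": {}, "meta": meta}
    with zipfile.ZipFile(path, "w") as zf:
        for name, arr in arrays.items():
            arr = np.ascontiguousarray(arr)
            manifest["arrays"][name] = {
                "dtype": arr.dtype.str,
                "shape": list(arr.shape),
            }
            zf.writestr(f"{name}.bin", arr.tobytes())
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def _read_archive(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    try:
        manifest = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar is not valid JSON: {exc}") from exc
    for key in ("arrays", "meta"):
        if key not in manifest:
            raise FormatError(f"sidecar missing field '{key}'")
    arrays = {}
    try:
        with zipfile.ZipFile(path) as zf:
            for name, info in manifest["arrays"].items():
                raw = zf.read(f"{name}.bin")
                arr = np.frombuffer(raw, dtype=np.dtype(info["dtype"]))
                expected = int(np.prod(info["shape"])) if info["shape"] else 1
                if arr.size != expected:
                    raise FormatError(
                        f"array '{name}': expected {expected} items, got {arr.size}"
                    )
                arrays[name] = arr.reshape(info["shape"]).copy()
    except (zipfile.BadZipFile, KeyError) as exc:
        raise FormatError(f"corrupt archive {path}: {exc}") from exc
    return arrays, manifest["meta"]


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Serialize an EpochSet; round-trips bit-identically via read_epochs."""
    path = Path(path)
    meta = {
        "kind": "epochs",
        "sfreq": epochs.sfreq,
        "window": list(epochs.window),
    }
    _write_archive(path, {"data": epochs.data, "labels": epochs.labels}, meta)


def read_epochs(path: str | Path) -> EpochSet:
    arrays, meta = _read_archive(Path(path))
    for name in _EPOCH_ARRAYS:
        if name not in arrays:
            raise FormatError(f"archive missing array '{name}'")
    for key in ("sfreq", "window"):
        if key not in meta:
            raise FormatError(f"archive meta missing field '{key}'")
    return EpochSet(
        data=arrays["data"],
        labels=arrays["labels"],
        sfreq=float(meta["sfreq"]),
        window=tuple(meta["window"]),
    )


def write_session(
    path: str | Path,
    record: np.ndarray,
    onsets: np.ndarray,
    labels: np.ndarray,
    sfreq: float,
    design: SessionDesign | None = None,
) -> None:
    meta = {"kind": "session", "sfreq": sfreq}
    if design is not None:
        meta["design"] = dataclasses.asdict(design)
    _write_archive(
        Path(path),
        {"record": np.asarray(record), "onsets": np.asarray(onsets),
         "labels": np.asarray(labels)},
        meta,
    )


def read_session(path: str | Path):
    arrays, meta = _read_archive(Path(path))
    for name in ("record", "onsets", "labels"):
        if name not in arrays:
            raise FormatError(f"archive missing array '{name}'")
    if "sfreq" not in meta:
        raise FormatError("archive meta missing field 'sfreq'")
    return arrays["record"], arrays["onsets"], arrays["labels"], float(meta["sfreq"])
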