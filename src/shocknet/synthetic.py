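"""Synthetic cardiac-arrest rhythm simulator.

Generates labeled single-lead ECG strips whose *measurable* properties match
the amplitude/rate definitions of the rhythm taxonomy in :mod:`.rhythms`:

* coarse VF     -- irregular 3-8 Hz oscillation, peak-to-peak > 200 uV
* fine VF       -- same morphology, peak-to-peak in [100, 200] uV (excluded)
* rapid VT      -- monomorphic wide-complex train at > 150 bpm
* slow VT       -- same at < 150 bpm (excluded)
* NSR           -- P-QRS-T complexes at 50-100 bpm with RR jitter
* ONR           -- one of {AF-like irregular narrow-complex, sinus
                   bradycardia, PVC-interspersed sinus rhythm}
* ASYS          -- low-amplitude colored noise, peak-to-peak < 100 uV
* ARTIFACT      -- large baseline wander + EMG-like noise (excluded)

The waveform shapes are deliberately simple surrogates: the taxonomy defines
classes only by amplitude and rate criteria, so any generator meeting those
measurable criteria is admissible.  Strips are emitted on a 2.5 uV amplitude
lattice (one LSB of the defibrillator front-end quantizer), at 250 Hz, and
may be band-limited to 1-30 Hz to emulate acquisition through defibrillation
pads (``OHCA_LIKE`` source) versus Holter-like recording (``HOLTER_LIKE``).

Every strip is fully determined by an integer seed.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .rhythms import RhythmClass

LSB_UV = 2.5  # amplitude quantizer step, uV per count

#: class-default peak-to-peak amplitudes (uV) and rates (bpm)
_DEFAULT_PP = {
    RhythmClass.VF: 500.0,
    RhythmClass.FINE_VF: 150.0,
    RhythmClass.VT: 1200.0,
    RhythmClass.SLOW_VT: 1200.0,
    RhythmClass.NSR: 1000.0,
    RhythmClass.ONR: 1000.0,
    RhythmClass.ASYS: 60.0,
    RhythmClass.ARTIFACT: 3000.0,
}
_DEFAULT_RATE = {
    RhythmClass.VT: 180.0,
    RhythmClass.SLOW_VT: 120.0,
    RhythmClass.NSR: 75.0,
}


class Source(enum.Enum):
    HOLTER_LIKE = "HOLTER_LIKE"
    OHCA_LIKE = "OHCA_LIKE"


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic strip; ``seed`` fully determines output."""

    rhythm: RhythmClass
    duration: float = 10.0       # s
    fs: float = 250.0            # Hz
    amplitude_pp: float | None = None  # uV peak-to-peak; None -> class default
    rate: float | None = None    # bpm, for beat-based classes; None -> default
    noise_rms: float = 10.0      # uV, additive band-limited Gaussian noise
    seed: int = 0

    def resolved_pp(self) -> float:
        return _DEFAULT_PP[self.rhythm] if self.amplitude_pp is None else float(self.amplitude_pp)

    def resolved_rate(self) -> float | None:
        if self.rate is not None:
            return float(self.rate)
        return _DEFAULT_RATE.get(self.rhythm)

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        pp = self.resolved_pp()
        if pp < 0:
            raise ValueError("amplitude_pp must be >= 0")
        rate = self.resolved_rate()
        cls = self.rhythm
        if cls is RhythmClass.ASYS:
            if pp >= 100.0:
                raise ValueError("ASYS requires peak-to-peak amplitude < 100 uV")
            if self.duration <= 4.0:
                raise ValueError("ASYS requires duration > 4 s")
        elif cls is RhythmClass.VF and pp <= 200.0:
            raise ValueError("coarse VF requires peak-to-peak amplitude > 200 uV")
        elif cls is RhythmClass.FINE_VF and not (100.0 <= pp <= 200.0):
            raise ValueError("fine VF requires peak-to-peak amplitude in [100, 200] uV")
        elif cls is RhythmClass.VT and rate is not None and rate <= 150.0:
            raise ValueError("rapid VT requires rate > 150 bpm")
        elif cls is RhythmClass.SLOW_VT and rate is not None and rate >= 150.0:
            raise ValueError("slow VT requires rate < 150 bpm")
        elif cls is RhythmClass.NSR and rate is not None and not (50.0 <= rate <= 100.0):
            raise ValueError("NSR rate must lie in [50, 100] bpm")


@dataclasses.dataclass
class ECGStrip:
    """One single-lead rhythm strip; samples in uV on the 2.5 uV lattice."""

    samples: np.ndarray
    fs: float
    label: RhythmClass
    source: Source = Source.HOLTER_LIKE
    patient_id: str = ""
    strip_id: str = ""

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def peak_to_peak(self) -> float:
        return float(np.max(self.samples) - np.min(self.samples))


# ---------------------------------------------------------------------------
# waveform primitives (unit-scale; rescaled to the target amplitude later)
# ---------------------------------------------------------------------------

def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _fibrillation(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of 3-5 drifting sinusoids in 3-8 Hz with a random phase walk."""
    n_osc = int(rng.integers(3, 6))
    x = np.zeros_like(t)
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    for _ in range(n_osc):
        f = rng.uniform(3.0, 8.0)
        amp = rng.uniform(0.5, 1.0)
        walk = np.cumsum(rng.normal(0.0, 0.03, size=len(t)))
        x += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi) + walk)
    # slow amplitude drift so successive cycles are not identical
    x *= 1.0 + 0.25 * np.sin(2 * np.pi * rng.uniform(0.1, 0.4) * t + rng.uniform(0, 2 * np.pi))
    del dt
    return x


def _beat_times(duration: float, rate_bpm: float, rng: np.random.Generator,
                rr_jitter: float = 0.0) -> np.ndarray:
    """Beat onset times starting 0.3 periods into the strip."""
    period = 60.0 / rate_bpm
    times = []
    t = 0.3 * period
    while t < duration:
        times.append(t)
        rr = period * (1.0 + rr_jitter * rng.standard_normal()) if rr_jitter else period
        t += max(rr, 0.2)
    return np.asarray(times)


def _wide_complex(t: np.ndarray, center: float) -> np.ndarray:
    """Biphasic wide (~150 ms) ventricular complex."""
    return _gauss(t, center, 0.035) - 0.9 * _gauss(t, center + 0.06, 0.035)


def _pqrst(t: np.ndarray, center: float) -> np.ndarray:
    """Gaussian-bump P-QRS-T template centered on the R wave."""
    return (
        0.15 * _gauss(t, center - 0.17, 0.025)   # P
        - 0.10 * _gauss(t, center - 0.028, 0.008)  # Q
        + 1.00 * _gauss(t, center, 0.012)          # R
        - 0.22 * _gauss(t, center + 0.030, 0.010)  # S
        + 0.30 * _gauss(t, center + 0.30, 0.055)   # T
    )


def _beat_train(t: np.ndarray, times: np.ndarray, template) -> np.ndarray:
    x = np.zeros_like(t)
    for tb in times:
        x += template(t, tb)
    return x


def _colored_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sp_signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _base_waveform(spec: SimSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cls = spec.rhythm
    rate = spec.resolved_rate()
    if cls in (RhythmClass.VF, RhythmClass.FINE_VF):
        return _fibrillation(t, rng)
    if cls in (RhythmClass.VT, RhythmClass.SLOW_VT):
        times = _beat_times(spec.duration, rate, rng, rr_jitter=0.0)
        return _beat_train(t, times, _wide_complex)
    if cls is RhythmClass.NSR:
        times = _beat_times(spec.duration, rate, rng, rr_jitter=0.03)
        return _beat_train(t, times, _pqrst)
    if cls is RhythmClass.ONR:
        variant = rng.choice(["af", "brady", "pvc"])
        if variant == "af":
            base_rate = rate if rate is not None else 110.0
            times = _beat_times(spec.duration, base_rate, rng, rr_jitter=0.20)
            narrow = lambda tt, c: _pqrst(tt, c) - 0.15 * _gauss(tt, c - 0.17, 0.025)
            x = _beat_train(t, times, narrow)
            x += 0.06 * np.sin(2 * np.pi * 6.0 * t + rng.uniform(0, 2 * np.pi))
            return x
        if variant == "brady":
            base_rate = rate if rate is not None else rng.uniform(35.0, 48.0)
            times = _beat_times(spec.duration, base_rate, rng, rr_jitter=0.03)
            return _beat_train(t, times, _pqrst)
        # PVC-interspersed sinus rhythm
        base_rate = rate if rate is not None else 75.0
        times = _beat_times(spec.duration, base_rate, rng, rr_jitter=0.03)
        every = int(rng.integers(3, 6))
        x = np.zeros_like(t)
        for i, tb in enumerate(times):
            if i % every == every - 1:
                x += 1.5 * _wide_complex(t, tb)
            else:
                x += _pqrst(t, tb)
        return x
    if cls is RhythmClass.ASYS:
        return _colored_noise(len(t), spec.fs, 4.0, rng)
    if cls is RhythmClass.ARTIFACT:
        wander = np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t + rng.uniform(0, 2 * np.pi))
        emg = rng.standard_normal(len(t))
        sos = sp_signal.butter(2, 20.0, btype="high", fs=spec.fs, output="sos")
        emg = sp_signal.sosfiltfilt(sos, emg)
        emg_rms = np.sqrt(np.mean(emg**2))
        if emg_rms > 0:
            emg /= emg_rms
        return wander + 0.15 * emg + 0.2 * _beat_train(
            t, _beat_times(spec.duration, 75.0, rng, 0.03), _pqrst)
    raise ValueError(f"unknown rhythm class {cls!r}")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def quantize(strip: ECGStrip, lsb: float = LSB_UV) -> ECGStrip:
    """Round every sample to the nearest multiple of ``lsb`` uV (idempotent)."""
    if lsb <= 0:
        raise ValueError("lsb must be > 0")
    q = np.round(strip.samples / lsb) * lsb
    return dataclasses.replace(strip, samples=q)


def generate_strip(spec: SimSpec) -> ECGStrip:
    """Generate one labeled strip satisfying its class amplitude/rate criteria.

    The composite signal (class waveform + band-limited Gaussian noise) is
    rescaled so that its pre-quantization peak-to-peak amplitude equals
    ``spec.amplitude_pp`` exactly; quantization then perturbs it by at most
    one LSB (2.5 uV), which the class amplitude margins absorb.
    """
    spec.validate()
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)
    x = _base_waveform(spec, t, rng)

    pp = spec.resolved_pp()
    span = float(np.max(x) - np.min(x))
    if span > 0 and pp > 0:
        x = (x - (np.max(x) + np.min(x)) / 2.0) * (pp / span)
    else:
        x = np.zeros(n)

    if spec.noise_rms > 0:
        noise = _colored_noise(n, spec.fs, 30.0, rng) * spec.noise_rms
        x = x + noise
        span = float(np.max(x) - np.min(x))
        if span > 0 and pp > 0:
            x = (x - (np.max(x) + np.min(x)) / 2.0) * (pp / span)

    strip = ECGStrip(samples=x, fs=spec.fs, label=spec.rhythm,
                     source=Source.HOLTER_LIKE)
    return quantize(strip)


def bandlimit_ohca(strip: ECGStrip) -> ECGStrip:
    """Band-limit a strip to 1-30 Hz, emulating defibrillation-pad acquisition.

    Uses a zero-phase 4th-order Butterworth band-pass (applied forward and
    backward), attenuating out-of-band energy by well over 20 dB relative to
    the passband; strip length is preserved and the source is re-tagged
    ``OHCA_LIKE``.
    """
    if strip.fs < 60.0:
        raise ValueError("band-limiting to 1-30 Hz requires fs >= 60 Hz")
    sos = sp_signal.butter(4, [1.0, 30.0], btype="bandpass", fs=strip.fs, output="sos")
    y = sp_signal.sosfiltfilt(sos, strip.samples)
    out = dataclasses.replace(strip, samples=y, source=Source.OHCA_LIKE)
    return quantize(out)


#: per-strip randomization ranges used by generate_dataset (kept inside the
#: validity margins of each class definition)
_DATASET_RANGES = {
    RhythmClass.VF: dict(pp=(250.0, 900.0)),
    RhythmClass.FINE_VF: dict(pp=(110.0, 190.0)),
    RhythmClass.VT: dict(pp=(600.0, 1800.0), rate=(160.0, 240.0)),
    RhythmClass.SLOW_VT: dict(pp=(600.0, 1800.0), rate=(90.0, 140.0)),
    RhythmClass.NSR: dict(pp=(500.0, 1500.0), rate=(55.0, 95.0)),
    RhythmClass.ONR: dict(pp=(500.0, 1500.0)),
    RhythmClass.ASYS: dict(pp=(20.0, 90.0)),
    RhythmClass.ARTIFACT: dict(pp=(1500.0, 4000.0)),
}


def generate_dataset(
    class_counts: Mapping[RhythmClass, int],
    seed: int,
    duration: float = 10.0,
    fs: float = 250.0,
    noise_rms: float = 10.0,
    ohca_fraction: float = 0.3,
    patient_prefix: str = "SYN",
) -> list[ECGStrip]:
    """Generate the requested number of strips per class, deterministically.

    Each strip gets a distinct sub-generator derived from ``seed`` and its
    index, a unique patient id, and with probability ``ohca_fraction`` is
    band-limited to 1-30 Hz and tagged ``OHCA_LIKE`` (roughly the proportion
    of defibrillator-acquired strips in the emulated training corpus).
    """
    for cls, cnt in class_counts.items():
        if cnt < 0:
            raise ValueError(f"negative count for {cls}")
    strips: list[ECGStrip] = []
    idx = 0
    for cls in RhythmClass:  # fixed iteration order for determinism
        cnt = int(class_counts.get(cls, 0))
        ranges = _DATASET_RANGES[cls]
        for _ in range(cnt):
            ss = np.random.SeedSequence([int(seed), idx])
            strip_seed = int(ss.generate_state(1)[0] % (2**31))
            prng = np.random.default_rng(strip_seed + 1)  # parameter draws
            pp = float(prng.uniform(*ranges["pp"]))
            rate = float(prng.uniform(*ranges["rate"])) if "rate" in ranges else None
            spec = SimSpec(rhythm=cls, duration=duration, fs=fs,
                           amplitude_pp=pp, rate=rate, noise_rms=noise_rms,
                           seed=strip_seed)
            strip = generate_strip(spec)
            if prng.uniform() < ohca_fraction:
                strip = bandlimit_ohca(strip)
            strip.patient_id = f"{patient_prefix}{seed}-{idx:05d}"
            strip.strip_id = f"{patient_prefix}{seed}-{idx:05d}-0"
            strips.append(strip)
            idx += 1
    return strips


# ---------------------------------------------------------------------------
# strip archive (CSV header + text sample matrix; bit-exact round trip)
# ---------------------------------------------------------------------------

def save_archive(strips: Sequence[ECGStrip], path: str | Path) -> None:
    """Write strips to a directory archive: ``header.csv`` + ``samples.txt``.

    Samples are stored as integer LSB counts (sample / 2.5 uV), which makes
    the round trip bit-exact for lattice-quantized strips.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = pd.DataFrame(
        {
            "strip_id": [s.strip_id for s in strips],
            "label": [s.label.value for s in strips],
            "fs": [s.fs for s in strips],
            "source": [s.source.value for s in strips],
            "patient_id": [s.patient_id for s in strips],
            "n_samples": [len(s.samples) for s in strips],
        }
    )
    header.to_csv(path / "header.csv", index=False)
    with open(path / "samples.txt", "w") as fh:
        for s in strips:
            counts = np.round(s.samples / LSB_UV).astype(np.int64)
            fh.write(" ".join(map(str, counts.tolist())) + "\n")


def load_archive(path: str | Path) -> list[ECGStrip]:
    """Load a directory archive written by :func:`save_archive`."""
    path = Path(path)
    header = pd.read_csv(path / "header.csv", dtype={"patient_id": str, "strip_id": str})
    strips: list[ECGStrip] = []
    with open(path / "samples.txt") as fh:
        for (_, row), line in zip(header.iterrows(), fh):
            counts = np.array(line.split(), dtype=np.int64)
            if len(counts) != row["n_samples"]:
                raise ValueError(f"sample count mismatch for strip {row['strip_id']}")
            strips.append(
                ECGStrip(
                    samples=counts.astype(np.float64) * LSB_UV,
                    fs=float(row["fs"]),
                    label=RhythmClass(row["label"]),
                    source=Source(row["source"]),
                    patient_id=str(row["patient_id"]),
                    strip_id=str(row["strip_id"]),
                )
            )
    if len(strips) != len(header):
        raise ValueError("archive truncated: fewer sample rows than header rows")
    return strips
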