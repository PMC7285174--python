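"""Turn labeled strips into training/validation tensors.

Pipeline: binary labeling with exclusions -> downsampling 250->125 Hz ->
initial-window extraction (the first ``L1`` seconds, emulating an analysis
started immediately) -> class balancing by replicating shockable cases ->
seeded shuffling and batching.  Amplitudes stay in raw uV on the 2.5 uV/LSB
scale; no normalization is applied, since absolute amplitude is itself
diagnostic (e.g. asystole is defined by peak-to-peak < 100 uV).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import numpy as np

from .rhythms import BinaryLabel, RhythmClass, label_to_class
from .synthetic import ECGStrip, Source

#: network target convention: probability 0 -> shockable, 1 -> nonshockable
Y_SH = 0.0
Y_NSH = 1.0


def downsample_by2(strip: ECGStrip) -> ECGStrip:
    """Decimate a 250 Hz strip to 125 Hz by keeping every second sample.

    No anti-alias filter is applied: strips are band-limited well below the
    62.5 Hz post-decimation Nyquist by construction (1-30 Hz acquisition).
    """
    if strip.fs != 250.0:
        raise ValueError(f"expected fs = 250 Hz, got {strip.fs}")
    return dataclasses.replace(strip, samples=strip.samples[::2], fs=125.0)


def extract_window(strip: ECGStrip, l1_seconds: float) -> np.ndarray:
    """Return the first ``round(L1 * fs)`` samples (no shift)."""
    n = int(round(l1_seconds * strip.fs))
    if n > len(strip.samples):
        raise ValueError(
            f"window of {l1_seconds} s ({n} samples) exceeds strip length {len(strip.samples)}")
    return strip.samples[:n]


@dataclasses.dataclass
class DatasetSplit:
    """Windows and binary targets for one role (train or validation)."""

    X: np.ndarray           # (n_items, window_len), uV at 125 Hz
    y: np.ndarray           # (n_items,), 0.0 = SH, 1.0 = NSH
    sources: np.ndarray     # (n_items,), Source.value strings
    patient_ids: np.ndarray
    role: str               # "TRAIN" or "VALIDATION"
    l1_seconds: float
    fs: float = 125.0

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    @property
    def n_sh(self) -> int:
        return int(np.sum(self.y == Y_SH))

    @property
    def n_nsh(self) -> int:
        return int(np.sum(self.y == Y_NSH))


def build_split(strips: Sequence[ECGStrip], l1_seconds: float, role: str) -> DatasetSplit:
    """Label, exclude, downsample and window a strip collection.

    Excluded rhythm classes (fine VF, slow VT, artifact) are dropped; the
    remainder are decimated to 125 Hz and cut to the initial ``L1`` window.
    """
    xs, ys, srcs, pids = [], [], [], []
    for strip in strips:
        lab = label_to_class(strip.label)
        if lab is BinaryLabel.EXCLUDED:
            continue
        s = downsample_by2(strip) if strip.fs == 250.0 else strip
        if s.fs != 125.0:
            raise ValueError(f"strips must be 250 or 125 Hz, got {strip.fs}")
        xs.append(extract_window(s, l1_seconds))
        ys.append(Y_SH if lab is BinaryLabel.SH else Y_NSH)
        srcs.append(s.source.value)
        pids.append(s.patient_id)
    if not xs:
        raise ValueError("no usable strips after exclusion")
    return DatasetSplit(
        X=np.asarray(xs, dtype=np.float64),
        y=np.asarray(ys, dtype=np.float64),
        sources=np.asarray(srcs),
        patient_ids=np.asarray(pids),
        role=role,
        l1_seconds=l1_seconds,
    )


def balance_by_replication(split: DatasetSplit, factor: int = 4) -> DatasetSplit:
    """Replicate every shockable item ``factor`` times; nonshockable unchanged.

    With the emulated corpus composition (~720 SH vs ~3170 NSH) a factor of 4
    makes the two classes roughly equal, so that plain accuracy on the
    balanced set tracks balanced accuracy.
    """
    if factor < 1:
        raise ValueError("replication factor must be >= 1")
    sh = split.y == Y_SH
    idx = np.concatenate([np.flatnonzero(~sh)] + [np.flatnonzero(sh)] * factor)
    idx.sort()  # keep original ordering with adjacent replicas
    return dataclasses.replace(
        split,
        X=split.X[idx],
        y=split.y[idx],
        sources=split.sources[idx],
        patient_ids=split.patient_ids[idx],
    )


def make_batches(
    split: DatasetSplit, batch_size: int = 256, seed: int = 0
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``(X_batch, y_batch)`` over a seeded permutation of the split.

    All batches have ``batch_size`` items except possibly the last; raw
    amplitudes are passed through untouched.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = len(split.y)
    if n == 0:
        raise ValueError("cannot batch an empty split")
    perm = np.random.default_rng(seed).permutation(n)
    for start in range(0, n, batch_size):
        sel = perm[start:start + batch_size]
        yield split.X[sel], split.y[sel]


def assert_no_patient_leakage(train: DatasetSplit, validation: DatasetSplit) -> None:
    """Raise if any patient id appears in both splits."""
    shared = set(train.patient_ids) & set(validation.patient_ids)
    if shared:
        raise ValueError(f"patient leakage between splits: {sorted(shared)[:5]} ...")
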