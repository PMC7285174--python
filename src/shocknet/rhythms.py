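"""Cardiac-arrest rhythm taxonomy and the shockable/non-shockable label map.

The shock-advisory problem is binary: a defibrillator must decide whether the
current rhythm benefits from a shock.  Following AHA rhythm categories, five
basic classes carry a decision (coarse VF and rapid VT are shockable; NSR,
other organised rhythms and asystole are not), while intermediate rhythms
(fine VF, slow VT) and artifact-laden strips carry no performance goal and
are excluded from training and evaluation.
"""

from __future__ import annotations

import enum


class RhythmClass(enum.Enum):
    """Rhythm annotation of a single 10 s ECG strip."""

    VF = "VF"            # coarse ventricular fibrillation, peak-to-peak > 200 uV
    VT = "VT"            # rapid ventricular tachycardia, rate > 150 bpm
    NSR = "NSR"          # normal sinus rhythm with P-QRS-T waves
    ONR = "ONR"          # other nonshockable rhythm (AF, bradycardia, PVCs, ...)
    ASYS = "ASYS"        # asystole, peak-to-peak < 100 uV for > 4 s
    FINE_VF = "FINE_VF"  # VF with amplitude 100-200 uV (excluded)
    SLOW_VT = "SLOW_VT"  # VT with rate < 150 bpm (excluded)
    ARTIFACT = "ARTIFACT"  # baseline wander / EMG noise (excluded)


class BinaryLabel(enum.Enum):
    """Shock-advisory decision label attached to a rhythm class."""

    SH = "SH"
    NSH = "NSH"
    EXCLUDED = "EXCLUDED"


_LABEL_MAP = {
    RhythmClass.VF: BinaryLabel.SH,
    RhythmClass.VT: BinaryLabel.SH,
    RhythmClass.NSR: BinaryLabel.NSH,
    RhythmClass.ONR: BinaryLabel.NSH,
    RhythmClass.ASYS: BinaryLabel.NSH,
    RhythmClass.FINE_VF: BinaryLabel.EXCLUDED,
    RhythmClass.SLOW_VT: BinaryLabel.EXCLUDED,
    RhythmClass.ARTIFACT: BinaryLabel.EXCLUDED,
}


def label_to_class(rhythm: RhythmClass) -> BinaryLabel:
    """Map a rhythm annotation to its shock-advisory label.

    VF, VT -> SH; NSR, ONR, ASYS -> NSH; fine VF, slow VT and artifact
    strips -> EXCLUDED (they never enter training or evaluation).
    """
    if not isinstance(rhythm, RhythmClass):
        raise ValueError(f"unknown rhythm class: {rhythm!r}")
    return _LABEL_MAP[rhythm]
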