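"""Core domain vocabulary: channels, expression labels, scenes, FACS mapping.

The seven surface-EMG channels of the face mask cover four muscle groups:
frontalis (brow raising), corrugator (brow lowering; a single midline
channel), orbicularis oculi (eye closure) and zygomaticus major (lip-corner
raising), the latter three groups with left/right electrodes.  Channel order
is fixed everywhere in the package: CSV columns, signal matrices, and model
inputs all use :data:`CHANNELS`.
"""

from __future__ import annotations

from enum import Enum

#: Fixed channel order used by every signal matrix and CSV file (7 channels).
CHANNELS: tuple[str, ...] = (
    "corrugator_center",
    "frontalis_left",
    "frontalis_right",
    "orbicularis_left",
    "orbicularis_right",
    "zygomaticus_left",
    "zygomaticus_right",
)

N_CHANNELS = len(CHANNELS)

#: Muscle group of each channel, in CHANNELS order.
CHANNEL_MUSCLE: dict[str, str] = {
    "corrugator_center": "corrugator",
    "frontalis_left": "frontalis",
    "frontalis_right": "frontalis",
    "orbicularis_left": "orbicularis",
    "orbicularis_right": "orbicularis",
    "zygomaticus_left": "zygomaticus",
    "zygomaticus_right": "zygomaticus",
}

MUSCLE_GROUPS: tuple[str, ...] = ("frontalis", "corrugator", "orbicularis", "zygomaticus")


class ExpressionLabel(str, Enum):
    """The four calibrated expression classes; ``neutral`` is the background
    class and comes first in the fixed class order (used for argmax
    tie-breaking and for every probability vector)."""

    NEUTRAL = "neutral"
    SMILE = "smile"
    FROWN = "frown"
    RAISED_EYEBROW = "raised_eyebrow"


#: Fixed class order: index in this tuple == integer class id.
LABELS: tuple[ExpressionLabel, ...] = (
    ExpressionLabel.NEUTRAL,
    ExpressionLabel.SMILE,
    ExpressionLabel.FROWN,
    ExpressionLabel.RAISED_EYEBROW,
)

LABEL_NAMES: tuple[str, ...] = tuple(lbl.value for lbl in LABELS)
LABEL_TO_ID: dict[str, int] = {name: i for i, name in enumerate(LABEL_NAMES)}
N_CLASSES = len(LABELS)

#: Non-neutral classes in fixed order.
NON_NEUTRAL: tuple[str, ...] = ("smile", "frown", "raised_eyebrow")


class SceneLabel(str, Enum):
    """VR scene conditions.  ``baseline`` is the reference for every
    baseline-corrected (delta) quantity."""

    BASELINE = "baseline"
    EMOTIONAL = "emotional"
    COGNITIVE = "cognitive"
    PHYSICAL = "physical"
    DUAL = "dual"
    RECOVERY = "recovery"


SCENES: tuple[str, ...] = tuple(s.value for s in SceneLabel)

#: Scenes present in a standard cohort recording session (recovery excluded).
COHORT_SCENES: tuple[str, ...] = ("baseline", "emotional", "cognitive", "physical", "dual")

STRESSOR_SCENES: tuple[str, ...] = ("emotional", "cognitive", "physical", "dual")

#: FACS-based muscle involvement per expression: smile engages orbicularis and
#: zygomaticus, frown engages frontalis and corrugator, a raised eyebrow
#: engages the frontalis alone, and neutral engages none.
MUSCLE_EXPRESSION_MAP: dict[str, frozenset[str]] = {
    "neutral": frozenset(),
    "smile": frozenset({"orbicularis", "zygomaticus"}),
    "frown": frozenset({"frontalis", "corrugator"}),
    "raised_eyebrow": frozenset({"frontalis"}),
}


def involved_channels(label: str) -> list[int]:
    """Indices (in CHANNELS order) of channels whose muscle group is engaged
    by ``label``."""
    muscles = MUSCLE_EXPRESSION_MAP[str(ExpressionLabel(label).value)]
    return [i for i, ch in enumerate(CHANNELS) if CHANNEL_MUSCLE[ch] in muscles]


def label_id(label: str | ExpressionLabel) -> int:
    """Integer class id of an expression label (fixed class order)."""
    return LABEL_TO_ID[ExpressionLabel(label).value]
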