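"""WHO hand-hygiene step labels, armband placements, and the step grammars.

The WHO guidelines define two procedures: alcohol-based handrub (steps 1-7,
with four of them repeated once per hand) and handwash with soap and water
(steps 2-10; wetting hands and applying soap are excluded because faucet and
dispenser positions vary between lavatories).  Together the two grammars use
14 performable step classes; ``NONE`` marks un-annotated time and is never a
training class.
"""

from __future__ import annotations

import enum
from typing import List


class StepLabel(enum.IntEnum):
    """One hand-hygiene step class.  The integer value is the fixed class
    index used for tie-breaking and as matrix axes."""

    S1_APPLY = 0        # apply hand-hygiene product (handrub only)
    S2_PALM = 1         # rub palm to palm
    S3R_DORSUM = 2      # rub dorsum, right hand leading
    S3L_DORSUM = 3
    S4_INTERLOCK = 4    # interlock fingers
    S5R_KNUCKLES = 5    # twist knuckles
    S5L_KNUCKLES = 6
    S6R_THUMB = 7       # rub thumb
    S6L_THUMB = 8
    S7R_FINGERTIP = 9   # scrub fingertips
    S7L_FINGERTIP = 10
    S8_RINSE = 11       # rinse hands (handwash only)
    S9_DRY = 12         # dry hands with towel (handwash only)
    S10_FAUCET = 13     # turn off faucet with towel (handwash only)
    NONE = 14           # unannotated / no step

    @property
    def is_performable(self) -> bool:
        return self is not StepLabel.NONE


class Mode(str, enum.Enum):
    HANDRUB = "HANDRUB"
    HANDWASH = "HANDWASH"


class Instruction(str, enum.Enum):
    VIDEO = "VIDEO"
    POSTER = "POSTER"


class Side(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Segment(str, enum.Enum):
    ARM = "ARM"          # above the elbow
    FOREARM = "FOREARM"  # below the elbow


class Placement(str, enum.Enum):
    """Armband position: {left,right} x {arm,forearm}, coded LA/RA/LF/RF."""

    LA = "LA"
    RA = "RA"
    LF = "LF"
    RF = "RF"

    @property
    def side(self) -> Side:
        return Side.LEFT if self.value[0] == "L" else Side.RIGHT

    @property
    def segment(self) -> Segment:
        return Segment.ARM if self.value[1] == "A" else Segment.FOREARM


#: Canonical step order of the handrub procedure (11 steps).
HANDRUB_ORDER: List[StepLabel] = [
    StepLabel.S1_APPLY,
    StepLabel.S2_PALM,
    StepLabel.S3R_DORSUM,
    StepLabel.S3L_DORSUM,
    StepLabel.S4_INTERLOCK,
    StepLabel.S5R_KNUCKLES,
    StepLabel.S5L_KNUCKLES,
    StepLabel.S6R_THUMB,
    StepLabel.S6L_THUMB,
    StepLabel.S7R_FINGERTIP,
    StepLabel.S7L_FINGERTIP,
]

#: Canonical step order of the handwash procedure (13 steps).
HANDWASH_ORDER: List[StepLabel] = [
    StepLabel.S2_PALM,
    StepLabel.S3R_DORSUM,
    StepLabel.S3L_DORSUM,
    StepLabel.S4_INTERLOCK,
    StepLabel.S5R_KNUCKLES,
    StepLabel.S5L_KNUCKLES,
    StepLabel.S6R_THUMB,
    StepLabel.S6L_THUMB,
    StepLabel.S7R_FINGERTIP,
    StepLabel.S7L_FINGERTIP,
    StepLabel.S8_RINSE,
    StepLabel.S9_DRY,
    StepLabel.S10_FAUCET,
]

#: Symmetric left/right step pairs participants tend to swap.
SYMMETRIC_PAIRS = [
    (StepLabel.S3R_DORSUM, StepLabel.S3L_DORSUM),
    (StepLabel.S5R_KNUCKLES, StepLabel.S5L_KNUCKLES),
    (StepLabel.S6R_THUMB, StepLabel.S6L_THUMB),
    (StepLabel.S7R_FINGERTIP, StepLabel.S7L_FINGERTIP),
]

#: Placement pairs used in the two-armband ablations.
PLACEMENT_PAIRS = [
    (Placement.LA, Placement.RA),
    (Placement.LF, Placement.RF),
    (Placement.RA, Placement.RF),
    (Placement.LA, Placement.LF),
]


def canonical_order(mode: Mode) -> List[StepLabel]:
    """The expected step sequence for a hygiene mode."""
    return list(HANDRUB_ORDER if mode is Mode.HANDRUB else HANDWASH_ORDER)


def allowed_labels(mode: Mode) -> frozenset:
    """Step labels that may legally appear in a session of ``mode``."""
    return frozenset(canonical_order(mode)) | {StepLabel.NONE}


def parse_label(text: str) -> StepLabel:
    """Parse a label string, rejecting anything outside the fixed set."""
    try:
        return StepLabel[text]
    except KeyError:
        raise ValueError(f"unknown label {text!r}") from None
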