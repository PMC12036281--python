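"""The Lund-Mackay region vocabulary.

Twelve sinus regions are scored: left/right frontal, anterior ethmoid,
posterior ethmoid, maxillary and sphenoid sinuses, plus the left/right
ostiomeatal complex (OMC).  Label volumes use stable integer codes 1-12
for these regions; 0 is reserved for background (bone, soft tissue,
everything that is not an opacifiable sinus space).
"""

from __future__ import annotations

import enum

__all__ = ["Side", "SinusType", "Region", "BACKGROUND", "N_CLASSES"]

BACKGROUND = 0
#: 12 sinus regions + background
N_CLASSES = 13


class Side(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"


class SinusType(str, enum.Enum):
    """The six sinus region classes of the Lund-Mackay system."""

    FRONTAL = "frontal"
    ANTERIOR_ETHMOID = "anterior_ethmoid"
    POSTERIOR_ETHMOID = "posterior_ethmoid"
    MAXILLARY = "maxillary"
    SPHENOID = "sphenoid"
    OMC = "omc"


class Region(enum.IntEnum):
    """Integer-coded sinus regions; code 0 is background and is not a member."""

    RIGHT_FRONTAL = 1
    LEFT_FRONTAL = 2
    RIGHT_ANTERIOR_ETHMOID = 3
    LEFT_ANTERIOR_ETHMOID = 4
    RIGHT_POSTERIOR_ETHMOID = 5
    LEFT_POSTERIOR_ETHMOID = 6
    RIGHT_MAXILLARY = 7
    LEFT_MAXILLARY = 8
    RIGHT_SPHENOID = 9
    LEFT_SPHENOID = 10
    RIGHT_OMC = 11
    LEFT_OMC = 12

    @property
    def side(self) -> Side:
        return Side.RIGHT if self.value % 2 == 1 else Side.LEFT

    @property
    def sinus(self) -> SinusType:
        order = [
            SinusType.FRONTAL,
            SinusType.ANTERIOR_ETHMOID,
            SinusType.POSTERIOR_ETHMOID,
            SinusType.MAXILLARY,
            SinusType.SPHENOID,
            SinusType.OMC,
        ]
        return order[(self.value - 1) // 2]

    @classmethod
    def from_parts(cls, side: Side, sinus: SinusType) -> "Region":
        for r in cls:
            if r.side == side and r.sinus == sinus:
                return r
        raise ValueError(f"no region for {side}, {sinus}")

    @classmethod
    def label_dictionary(cls) -> dict[int, str]:
        """``{code: name}`` mapping including background, for JSON sidecars."""
        d = {BACKGROUND: "background"}
        d.update({int(r): r.name.lower() for r in cls})
        return d
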