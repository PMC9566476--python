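"""The five recognized actions and their fixed state/symbol indexing.

The recognizer distinguishes four static postures — seated in a wheelchair,
standing, sitting, lying — plus a fifth class, Transition, covering any
passage between two postures (the highest-risk moments for an elderly
resident).  States S1..S5 and observation symbols v1..v5 share this order.
"""

from __future__ import annotations

from enum import IntEnum

#: Per-frame marker for "no person detected"; excluded from decoding and scoring.
NO_PERSON = -1

N_STATES = 5
N_SYMBOLS = 5


class ActionLabel(IntEnum):
    """Hidden states of the action model, in fixed index order S1..S5."""

    TRANSITION = 0
    SEATED = 1
    STANDING = 2
    SITTING = 3
    LYING = 4

    @property
    def display_name(self) -> str:
        return _DISPLAY[self]

    @classmethod
    def from_name(cls, name: str) -> "ActionLabel":
        key = name.strip().lower()
        for label, disp in _DISPLAY.items():
            if key in (disp.lower(), label.name.lower()):
                return label
        raise ValueError(f"unknown action label {name!r}")


_DISPLAY = {
    ActionLabel.TRANSITION: "Transition",
    ActionLabel.SEATED: "Seated",
    ActionLabel.STANDING: "Standing",
    ActionLabel.SITTING: "Sitting",
    ActionLabel.LYING: "Lying",
}

ACTION_NAMES = [_DISPLAY[a] for a in ActionLabel]
SYMBOL_NAMES = [f"v{k + 1}" for k in range(N_SYMBOLS)]
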