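"""Shared classification enums for SSA, DPA, and the integrated matrix."""

from __future__ import annotations

import enum


class SignalClass(str, enum.Enum):
    """Per-method signal classification for one drug-disease pair.

    ``INVERSE`` marks a statistically significant inverse association
    (the candidate repositioning direction), ``RISK`` a significant
    positive association, ``NONE`` no signal, and ``UNDEFINED`` a pair
    whose estimates could not be computed (zero margins, no pairs).
    """

    INVERSE = "inverse"
    RISK = "risk"
    NONE = "none"
    UNDEFINED = "undefined"

    @property
    def symbol(self) -> str:
        return _SYMBOLS[self]


class CombinedClass(str, enum.Enum):
    """Integrated SSA + DPA verdict for one drug-disease pair."""

    REPOSITIONING_SIGNAL = "repositioning_signal"
    INVERSE_ONE_METHOD = "inverse_one_method"
    RISK = "risk"
    NONE = "none"


_SYMBOLS = {
    SignalClass.INVERSE: "▼",   # filled down triangle
    SignalClass.RISK: "△",      # open up triangle
    SignalClass.NONE: "-",
    SignalClass.UNDEFINED: "?",
}
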