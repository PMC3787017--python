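"""In vitro transporter potency profiles and selectivity arithmetic.

Potencies are stored as -log10 molar (pIC50 / pKi) throughout; fold
selectivity between the norepinephrine transporter (NET) and the serotonin
transporter (SERT) is the antilog of the pIC50 difference, reported rounded
to one significant figure as is conventional for uptake-selectivity labels.
Unbound (free) drug concentrations are obtained from total concentrations
via measured unbound fractions (fu).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "CompoundProfile",
    "selectivity_fold",
    "unbound_concentration",
    "round_one_sig_fig",
]

_POTENCY_RANGE = (3.0, 12.0)


def round_one_sig_fig(x: float) -> float:
    """Round to one significant figure, half away from zero.

    E.g. 31.6 -> 30, 50.1 -> 50, 19953 -> 20000.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    mantissa = abs(x) / 10.0**exponent
    rounded = math.floor(mantissa + 0.5)  # half away from zero (mantissa > 0)
    if rounded == 10:
        rounded, exponent = 1, exponent + 1
    return math.copysign(rounded * 10.0**exponent, x)


def selectivity_fold(pic50_net: float, pic50_sert: float) -> tuple[float, str]:
    """Fold selectivity between NET and SERT from uptake-inhibition pIC50s.

    Returns ``(fold, preferred)`` where ``fold = 10**|pIC50_NET - pIC50_SERT|``
    rounded to one significant figure and ``preferred`` is the transporter
    with the larger pIC50 ("none" on an exact tie, fold 1).
    """
    for v in (pic50_net, pic50_sert):
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            raise ValueError(f"potency must be finite, got {v!r}")
    delta = pic50_net - pic50_sert
    fold = round_one_sig_fig(10.0 ** abs(delta))
    if delta > 0:
        preferred = "NET"
    elif delta < 0:
        preferred = "SERT"
    else:
        preferred = "none"
    return fold, preferred


def unbound_concentration(total: float, fu: float) -> float:
    """Free concentration from a total concentration and an unbound fraction.

    ``total`` may be in any concentration unit (ng/mL plasma, ng/g brain);
    the result carries the same unit.
    """
    if not (0.0 < fu <= 1.0):
        raise ValueError(f"unbound fraction must be in (0, 1], got {fu!r}")
    if total < 0:
        raise ValueError(f"total concentration must be >= 0, got {total!r}")
    return total * fu


@dataclass(frozen=True)
class CompoundProfile:
    """In vitro potencies and unbound fractions for one compound.

    Potencies in -log10 molar; ``fu_plasma`` / ``fu_brain`` are unitless
    fractions in (0, 1]. pKi values and unbound fractions are optional.
    """

    name: str
    pic50_sert: float
    pic50_net: float
    pki_sert: Optional[float] = None
    pki_net: Optional[float] = None
    fu_plasma: Optional[float] = None
    fu_brain: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = _POTENCY_RANGE
        for label in ("pic50_sert", "pic50_net", "pki_sert", "pki_net"):
            v = getattr(self, label)
            if v is None:
                continue
            if not (isinstance(v, (int, float)) and math.isfinite(v) and lo <= v <= hi):
                raise ValueError(
                    f"{self.name}: {label}={v!r} outside plausible range [{lo}, {hi}]"
                )
        for label in ("fu_plasma", "fu_brain"):
            v = getattr(self, label)
            if v is not None and not (0.0 < v <= 1.0):
                raise ValueError(f"{self.name}: {label}={v!r} not in (0, 1]")

    def selectivity(self) -> tuple[float, str]:
        """Uptake fold-selectivity and preferred transporter (from pIC50s)."""
        return selectivity_fold(self.pic50_net, self.pic50_sert)

    def free_plasma(self, total: float) -> float:
        if self.fu_plasma is None:
            raise ValueError(f"{self.name}: fu_plasma not set")
        return unbound_concentration(total, self.fu_plasma)

    def free_brain(self, total: float) -> float:
        if self.fu_brain is None:
            raise ValueError(f"{self.name}: fu_brain not set")
        return unbound_concentration(total, self.fu_brain)
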