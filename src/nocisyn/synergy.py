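"""Fixed-dose CI-shift test and fixed-ratio (isobolographic) synergy analysis.

Under Loewe additivity, a mixture of drugs A and B at ratio r (parts of A
per part of B) has theoretical additive ED50 (total mixture dose)

    Z_add = F * ED50_A + (1 - F) * ED50_B,   F = r / (r + ED50_A / ED50_B)

where F is the fractional multiplier. The combination is deemed synergistic
when the observed mixture ED50's 95% CI lies wholly below the additive
point's 95% CI (strictly non-overlapping intervals), antagonistic in the
mirrored case, and additive otherwise. The interaction index
Z_obs / Z_add is reported as a continuous effect size alongside the verdict.

The additive point's CI uses a delta-method variance combination,
Var(Z_add) = F^2 Var(A) + (1-F)^2 Var(B), with each component SE recovered
from its 95% CI half-width on the linear dose scale (mean of the two
half-widths when asymmetric); interval Z_add +/- 1.96 SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .dose_response import DoseResponseFit

__all__ = [
    "FixedRatioDesign",
    "IsobologramResult",
    "fractional_multiplier",
    "additive_ed50",
    "additive_ed50_ci",
    "isobologram_verdict",
    "fixed_dose_shift",
    "analyze_fixed_ratio",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def fractional_multiplier(ratio: float, ed50_a: float, ed50_b: float) -> float:
    """Fractional multiplier F = r / (r + ED50_A / ED50_B).

    ``ratio`` is parts of drug A per part of drug B in the mixture; F runs
    from 0 (pure B) to 1 (pure A limit).
    """
    if ed50_a <= 0 or ed50_b <= 0:
        raise ValueError("component ED50s must be > 0")
    if ratio < 0:
        raise ValueError("mixture ratio must be >= 0")
    return ratio / (ratio + ed50_a / ed50_b)


def additive_ed50(f: float, ed50_a: float, ed50_b: float) -> float:
    """Theoretical additive ED50 of the mixture: F*ED50_A + (1-F)*ED50_B."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fractional multiplier must be in [0, 1], got {f!r}")
    if ed50_a <= 0 or ed50_b <= 0:
        raise ValueError("component ED50s must be > 0")
    return f * ed50_a + (1.0 - f) * ed50_b


def _se_from_ci(ed50: float, ci95: tuple[float, float]) -> float:
    # mean of the two half-widths on the linear scale, converted to an SE
    lo, hi = ci95
    return ((ed50 - lo) + (hi - ed50)) / 2.0 / _Z95


def additive_ed50_ci(
    f: float, fit_a: DoseResponseFit, fit_b: DoseResponseFit
) -> Optional[tuple[float, float]]:
    """Delta-method 95% CI for the additive ED50; None if a component CI is absent."""
    if fit_a.ci95 is None or fit_b.ci95 is None:
        return None
    z = additive_ed50(f, fit_a.ed50, fit_b.ed50)
    var = (
        f**2 * _se_from_ci(fit_a.ed50, fit_a.ci95) ** 2
        + (1.0 - f) ** 2 * _se_from_ci(fit_b.ed50, fit_b.ci95) ** 2
    )
    half = _Z95 * math.sqrt(var)
    return (z - half, z + half)


@dataclass(frozen=True)
class FixedRatioDesign:
    """A fixed-ratio mixture design: components, ratio and derived F."""

    drug_a: str
    drug_b: str
    ratio: float  # parts of A per part of B
    ed50_a: DoseResponseFit
    ed50_b: DoseResponseFit

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("mixture ratio must be > 0")

    @property
    def f(self) -> float:
        return fractional_multiplier(self.ratio, self.ed50_a.ed50, self.ed50_b.ed50)


@dataclass(frozen=True)
class IsobologramResult:
    """Verdict of a fixed-ratio isobolographic comparison (total-dose scale)."""

    design: Optional[FixedRatioDesign]
    z_add: float  # mg/kg, theoretical additive mixture ED50
    z_add_ci: Optional[tuple[float, float]]
    z_obs: float  # mg/kg, observed mixture ED50
    z_obs_ci: Optional[tuple[float, float]]
    verdict: str  # synergistic | additive | antagonistic | indeterminate

    @property
    def interaction_index(self) -> float:
        """Observed / additive ED50: < 1 synergy, 1 additivity, > 1 antagonism."""
        return self.z_obs / self.z_add


def _interval_verdict(
    obs_ci: Optional[tuple[float, float]], add_ci: Optional[tuple[float, float]]
) -> str:
    if obs_ci is None or add_ci is None:
        return "indeterminate"
    if obs_ci[1] < add_ci[0]:
        return "synergistic"
    if obs_ci[0] > add_ci[1]:
        return "antagonistic"
    return "additive"  # touching intervals count as overlap


def isobologram_verdict(
    z_obs_fit: DoseResponseFit,
    z_add: float,
    z_add_ci: Optional[tuple[float, float]],
    design: Optional[FixedRatioDesign] = None,
) -> IsobologramResult:
    """Classify a fixed-ratio combination against its Loewe-additive point.

    Synergistic iff the observed CI lies strictly below the additive CI;
    antagonistic in the mirrored case; additive when the intervals overlap
    or touch; indeterminate when either CI is absent.
    """
    obs_ci = z_obs_fit.ci95 if z_obs_fit.converged else None
    return IsobologramResult(
        design=design,
        z_add=z_add,
        z_add_ci=z_add_ci,
        z_obs=z_obs_fit.ed50,
        z_obs_ci=obs_ci,
        verdict=_interval_verdict(obs_ci, z_add_ci),
    )


def fixed_dose_shift(
    fit_alone: DoseResponseFit, fit_with_adjunct: DoseResponseFit
) -> str:
    """Classify a fixed-dose potentiation experiment by 95% CI overlap.

    A leftward shift (potentiation) is significant iff the adjunct curve's
    CI upper bound lies strictly below the alone curve's CI lower bound;
    symmetric rule for rightward; otherwise ``no_shift``. Missing CIs give
    ``indeterminate``.
    """
    if fit_alone.ci95 is None or fit_with_adjunct.ci95 is None:
        return "indeterminate"
    if fit_with_adjunct.ci95[1] < fit_alone.ci95[0]:
        return "significant_leftward"
    if fit_with_adjunct.ci95[0] > fit_alone.ci95[1]:
        return "significant_rightward"
    return "no_shift"


def analyze_fixed_ratio(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    fit_mix: DoseResponseFit,
    ratio: float,
    drug_a: str = "A",
    drug_b: str = "B",
) -> IsobologramResult:
    """Full fixed-ratio analysis from three fits (A alone, B alone, mixture).

    The mixture fit must be on the TOTAL mixture dose axis (A + B parts
    summed); Z_add from the additivity equation is likewise a total-dose
    quantity, bracketed by the component ED50s.
    """
    design = FixedRatioDesign(
        drug_a=drug_a, drug_b=drug_b, ratio=ratio, ed50_a=fit_a, ed50_b=fit_b
    )
    z_add = additive_ed50(design.f, fit_a.ed50, fit_b.ed50)
    z_ci = additive_ed50_ci(design.f, fit_a, fit_b)
    return isobologram_verdict(fit_mix, z_add, z_ci, design=design)
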