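"""Constrained variable-slope sigmoid (Hill) ED50 fitting.

The dose-response model is the two-parameter logistic in log10-dose with the
floor and ceiling hard-fixed at 0% and 100% inhibition:

    E(d) = 100 / (1 + 10**(h * (logED50 - log10 d)))

where ``h`` is the Hill slope (steepness, > 0) and ED50 the dose giving 50%
inhibition of phase-2A flinching. Fitting is unweighted nonlinear least
squares on per-animal percent-inhibition points (not dose means). The 95%
confidence interval is asymptotic-normal on logED50 with a t critical value
(n - 2 df) and is back-transformed, so it is asymmetric on the dose scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .behavior import PHASE2A_WINDOW, FlinchDataset, inhibition_table

__all__ = ["DoseResponseFit", "predict_inhibition", "fit_ed50", "fit_from_dataset"]

#: Hill-slope bounds preventing degenerate step-function fits on sparse data.
HILL_BOUNDS = (0.1, 10.0)


def predict_inhibition(dose, log_ed50: float, hill: float):
    """Percent inhibition at ``dose`` (mg/kg) under the constrained sigmoid.

    Accepts scalar or array dose; returns the same shape. Exactly 50 at
    ``dose == 10**log_ed50``; tends to 0 as dose -> 0+ and 100 as dose -> inf.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be > 0")
    if hill <= 0:
        raise ValueError("Hill slope must be > 0")
    out = 100.0 / (1.0 + 10.0 ** (hill * (log_ed50 - np.log10(d))))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a constrained sigmoid ED50 fit."""

    drug_label: str
    log_ed50: float  # log10 mg/kg
    ed50: float  # mg/kg
    hill: float
    ci95: Optional[tuple[float, float]]  # mg/kg; None if unavailable
    n_points: int
    converged: bool
    residual_sd: Optional[float] = None  # % units

    def __post_init__(self) -> None:
        if self.converged:
            if not math.isclose(self.ed50, 10.0**self.log_ed50, rel_tol=1e-9):
                raise ValueError("ed50 must equal 10**log_ed50")
            if self.hill <= 0:
                raise ValueError("Hill slope must be > 0")
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo < self.ed50 < hi):
                raise ValueError(
                    f"{self.drug_label}: CI ({lo}, {hi}) must bracket ED50 {self.ed50}"
                )

    @classmethod
    def from_interval(
        cls, ed50: float, ci95: tuple[float, float], drug_label: str = ""
    ) -> "DoseResponseFit":
        """Wrap a published ED50 and 95% CI (e.g. values read off a report)
        so it can enter CI-overlap comparisons without refitting."""
        return cls(
            drug_label=drug_label,
            log_ed50=math.log10(ed50),
            ed50=ed50,
            hill=1.0,
            ci95=(float(ci95[0]), float(ci95[1])),
            n_points=0,
            converged=True,
        )


def _initial_guess(doses: np.ndarray, pct: np.ndarray) -> tuple[float, float]:
    # log_ed50 starts at the dose whose mean response is nearest 50%; hill 1.
    uniq = np.unique(doses)
    means = np.array([pct[doses == d].mean() for d in uniq])
    return float(np.log10(uniq[np.argmin(np.abs(means - 50.0))])), 1.0


def fit_ed50(
    doses: Sequence[float],
    pct_inhibition: Sequence[float],
    drug_label: str = "",
) -> DoseResponseFit:
    """Fit the constrained sigmoid to per-animal (dose, % inhibition) points.

    Requires >= 3 distinct positive doses. The two free parameters are
    logED50 and the Hill slope (bounded to (0.1, 10)); floor/ceiling are
    fixed at 0/100. Non-convergence yields ``converged=False`` with CI absent.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(pct_inhibition, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and pct_inhibition must be equal-length 1-D")
    if np.any(d <= 0):
        raise ValueError("all doses must be > 0 (drop vehicle/zero-dose animals)")
    if np.unique(d).size < 3:
        raise ValueError("need >= 3 distinct positive doses to fit an ED50")

    p0 = _initial_guess(d, y)
    logd = np.log10(d)

    def model(logdose, log_ed50, hill):
        return 100.0 / (1.0 + 10.0 ** (hill * (log_ed50 - logdose)))

    try:
        popt, pcov = optimize.curve_fit(
            model,
            logd,
            y,
            p0=p0,
            bounds=([-np.inf, HILL_BOUNDS[0]], [np.inf, HILL_BOUNDS[1]]),
            maxfev=10000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return DoseResponseFit(
            drug_label=drug_label,
            log_ed50=float(p0[0]),
            ed50=10.0 ** float(p0[0]),
            hill=float(p0[1]),
            ci95=None,
            n_points=int(d.size),
            converged=False,
        )

    log_ed50, hill = float(popt[0]), float(popt[1])
    resid = y - model(logd, *popt)
    dof = d.size - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else None

    ci95 = None
    se_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    if converged and dof > 0 and np.isfinite(se_log):
        tcrit = float(stats.t.ppf(0.975, dof))
        ci95 = (10.0 ** (log_ed50 - tcrit * se_log), 10.0 ** (log_ed50 + tcrit * se_log))
        if not (ci95[0] < 10.0**log_ed50 < ci95[1]):
            ci95 = None  # numerically degenerate (near-perfect fit)

    return DoseResponseFit(
        drug_label=drug_label,
        log_ed50=log_ed50,
        ed50=10.0**log_ed50,
        hill=hill,
        ci95=ci95,
        n_points=int(d.size),
        converged=converged,
        residual_sd=residual_sd,
    )


def fit_from_dataset(
    ds: FlinchDataset,
    drug: Optional[str] = None,
    window: tuple[float, float] = PHASE2A_WINDOW,
    vehicle_arm: str = "vehicle",
    dose_axis: str = "drug",
    arms: Optional[Sequence[str]] = None,
    drug_label: Optional[str] = None,
) -> DoseResponseFit:
    """Fit an ED50 directly from a flinch dataset.

    ``dose_axis='drug'`` uses the named drug's per-animal dose (fixed-dose
    designs: the varying component); ``dose_axis='total'`` uses the summed
    mixture dose (fixed-ratio designs). ``arms`` optionally restricts which
    treatment arms enter the fit; the vehicle arm only sets the normalisation
    and never enters the regression.
    """
    tbl = inhibition_table(ds, window=window, vehicle_arm=vehicle_arm)
    tbl = tbl[tbl["arm"] != vehicle_arm]
    if arms is not None:
        tbl = tbl[tbl["arm"].isin(set(arms))]
    if dose_axis == "total":
        dose = tbl["total_dose"].to_numpy()
        keep = dose > 0
    elif dose_axis == "drug":
        if drug is None:
            raise ValueError("dose_axis='drug' requires a drug name")
        dose = tbl["drug_doses"].map(lambda m: m.get(drug, 0.0)).to_numpy(dtype=float)
        keep = dose > 0
    else:
        raise ValueError("dose_axis must be 'drug' or 'total'")
    return fit_ed50(
        dose[keep],
        tbl["pct_inhibition"].to_numpy()[keep],
        drug_label=drug_label or (drug if drug else "mixture"),
    )
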