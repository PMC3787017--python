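"""Synthetic formalin-test and binding data with known ground truth.

No raw per-animal data accompany the study design this package analyses, so
every stage is exercised on simulated animals instead. The generator
emulates the statistical structure of the assay:

* Phase-2A flinch totals are negative-binomially distributed around a group
  mean that follows the constrained variable-slope sigmoid,
  mu(d) = vehicle_mean * (1 - E(d)/100). Counts are overdispersed
  (animal-to-animal variability in this assay is large); the dispersion
  (negative-binomial size) default of 10 yields group SEMs of the magnitude
  seen in formalin dose-response figures.
* Fixed-ratio mixtures respond to TOTAL mixture dose through the same
  sigmoid, with the mixture's true ED50 set to
  interaction_index * Z_add(F, ED50_A, ED50_B): index 1 is exact Loewe
  additivity, < 1 synergy, > 1 antagonism — the minimal model able to
  exercise all three isobologram verdicts.
* Binding time courses are straight lines sampled at 0, 1, 2, 3 min. The
  vehicle slope is fixed at v0; a treated animal's slope is
  v0 * (1 - theta/100) * lognormal noise with coefficient of variation
  ``occupancy_noise_cv`` (mean-one noise, so recovery is unbiased).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .behavior import PHASE2A_WINDOW, FlinchDataset, FlinchRecord
from .dose_response import predict_inhibition
from .occupancy import BindingTimeCourse
from .synergy import additive_ed50, fractional_multiplier

__all__ = ["GeneratorConfig", "gen_single_drug", "gen_fixed_ratio", "gen_binding"]

#: Time points (min) at which synthetic binding courses are sampled.
BINDING_TIMES = (0.0, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth settings for one simulated single-drug experiment.

    ``vehicle_mean_flinches`` is the mean phase-2A flinch total of vehicle
    animals (raw counts are never published for this assay; 150 is a
    realistic default for an automated counter and no downstream result
    depends on it). ``dispersion`` is the negative-binomial size parameter
    (smaller = more overdispersed).
    """

    seed: int
    true_log_ed50: float  # log10 mg/kg
    doses: tuple[float, ...]  # mg/kg, treated arms
    true_hill: float = 1.5
    n_per_group: int = 8
    vehicle_mean_flinches: float = 150.0
    dispersion: float = 10.0
    interaction_index: float = 1.0
    occupancy_noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.vehicle_mean_flinches <= 0:
            raise ValueError("vehicle_mean_flinches must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.true_hill <= 0:
            raise ValueError("true_hill must be > 0")
        if self.interaction_index <= 0:
            raise ValueError("interaction_index must be > 0")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise ValueError("doses must be a non-empty list of positive mg/kg values")
        if self.occupancy_noise_cv < 0:
            raise ValueError("occupancy_noise_cv must be >= 0")

    @property
    def true_ed50(self) -> float:
        return 10.0**self.true_log_ed50


def _nb_counts(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative-binomial counts with given mean and size (dispersion) parameter."""
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _flinch_arm(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    arm: str,
    drug_doses: Mapping[str, float],
    mean_pct: float,
    session: str,
    id_prefix: str,
) -> list[FlinchRecord]:
    mu = cfg.vehicle_mean_flinches * (1.0 - mean_pct / 100.0)
    counts = _nb_counts(rng, mu, cfg.dispersion, cfg.n_per_group)
    return [
        FlinchRecord(
            animal_id=f"{id_prefix}{i:03d}",
            arm=arm,
            drug_doses=dict(drug_doses),
            bin_start=PHASE2A_WINDOW[0],
            bin_end=PHASE2A_WINDOW[1],
            flinches=int(c),
            session=session,
        )
        for i, c in enumerate(counts)
    ]


def gen_single_drug(
    config: GeneratorConfig,
    drug: str = "drug",
    session: str = "sim",
    include_vehicle: bool = True,
) -> FlinchDataset:
    """Simulate one single-drug formalin dose-response experiment.

    One vehicle arm plus one arm per dose, ``n_per_group`` animals each;
    each animal carries a single phase-2A bin [15, 40) whose count is
    negative-binomial around the sigmoid-predicted group mean.
    """
    rng = np.random.default_rng(config.seed)
    records: list[FlinchRecord] = []
    if include_vehicle:
        records += _flinch_arm(
            rng, config, "vehicle", {}, 0.0, session, id_prefix="veh"
        )
    for j, dose in enumerate(config.doses):
        e = predict_inhibition(dose, config.true_log_ed50, config.true_hill)
        records += _flinch_arm(
            rng,
            config,
            f"{drug}_{dose:g}",
            {drug: dose},
            e,
            session,
            id_prefix=f"d{j}a",
        )
    return FlinchDataset(records=records)


def gen_fixed_ratio(
    config_a: GeneratorConfig,
    config_b: GeneratorConfig,
    ratio: float,
    interaction_index: float = 1.0,
    total_doses: Optional[Sequence[float]] = None,
    mix_hill: Optional[float] = None,
    seed: Optional[int] = None,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
    session: str = "sim",
) -> FlinchDataset:
    """Simulate the mixture arms of a fixed-ratio combination experiment.

    The mixture's true total-dose ED50 is
    ``interaction_index * Z_add(F, ED50_A, ED50_B)`` computed from the two
    configs' true ED50s; responses follow the constrained sigmoid on total
    dose with slope ``mix_hill`` (default: mean of the component slopes).
    Default total doses are a 4-point geometric-like series spanning the
    additive prediction (0.2x to 6x), mimicking how mixture dilutions are
    chosen around the expected potency in a real fixed-ratio design. A
    concurrent vehicle arm is included. Component single-drug experiments
    are generated separately with :func:`gen_single_drug`.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if interaction_index <= 0:
        raise ValueError("interaction_index must be > 0")
    ed50_a, ed50_b = config_a.true_ed50, config_b.true_ed50
    f = fractional_multiplier(ratio, ed50_a, ed50_b)
    z_add = additive_ed50(f, ed50_a, ed50_b)
    true_mix_ed50 = interaction_index * z_add
    if total_doses is None:
        total_doses = tuple(z_add * m for m in (0.2, 0.6, 2.0, 6.0))
    hill = mix_hill if mix_hill is not None else (config_a.true_hill + config_b.true_hill) / 2.0
    mix_cfg = replace(
        config_a,
        seed=seed if seed is not None else config_a.seed,
        true_log_ed50=math.log10(true_mix_ed50),
        true_hill=hill,
        doses=tuple(total_doses),
        interaction_index=interaction_index,
    )
    rng = np.random.default_rng(mix_cfg.seed)
    records: list[FlinchRecord] = _flinch_arm(
        rng, mix_cfg, "vehicle", {}, 0.0, session, id_prefix="veh"
    )
    for j, total in enumerate(mix_cfg.doses):
        dose_a = total * ratio / (ratio + 1.0)
        dose_b = total / (ratio + 1.0)
        e = predict_inhibition(total, mix_cfg.true_log_ed50, mix_cfg.true_hill)
        records += _flinch_arm(
            rng,
            mix_cfg,
            f"mix_{ratio:g}to1_{total:g}",
            {drug_a: dose_a, drug_b: dose_b},
            e,
            session,
            id_prefix=f"m{j}a",
        )
    return FlinchDataset(records=records)


def gen_binding(
    config: GeneratorConfig,
    true_occupancy_by_arm: Mapping[str, float],
    transporter: str = "NET",
    n_per_arm: Optional[int] = None,
    v0: float = 10.0,
    baseline: float = 0.0,
    session: str = "sim",
) -> list[BindingTimeCourse]:
    """Simulate radioligand binding time courses with known occupancies.

    A ``vehicle`` arm with slope exactly ``v0`` (the noise-free reference)
    is always generated; each treated arm's animals get slope
    ``v0 * (1 - theta/100)`` perturbed by mean-one lognormal noise with CV
    ``config.occupancy_noise_cv``. Points are sampled noiselessly along the
    line at 0, 1, 2, 3 min above a constant ``baseline`` signal.
    """
    for arm, theta in true_occupancy_by_arm.items():
        if theta > 100:
            raise ValueError(f"occupancy for arm {arm!r} exceeds 100%")
    n = n_per_arm if n_per_arm is not None else config.n_per_group
    rng = np.random.default_rng(config.seed)
    cv = config.occupancy_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv**2))
    courses: list[BindingTimeCourse] = []

    def make_arm(arm: str, slopes: np.ndarray, prefix: str) -> None:
        for i, s in enumerate(slopes):
            pts = tuple((t, baseline + float(s) * t) for t in BINDING_TIMES)
            courses.append(
                BindingTimeCourse(
                    animal_id=f"{prefix}{i:03d}",
                    arm=arm,
                    transporter=transporter,
                    points=pts,
                    session=session,
                )
            )

    make_arm("vehicle", np.full(n, v0), "veh")
    for k, (arm, theta) in enumerate(true_occupancy_by_arm.items()):
        noise = (
            rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
            if cv > 0
            else np.ones(n)
        )
        slopes = np.maximum(v0 * (1.0 - theta / 100.0) * noise, 0.0)
        make_arm(arm, slopes, f"t{k}a")
    return courses
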