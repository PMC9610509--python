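"""High-cycle fatigue life mapping for the denture base.

Two criteria are provided:

* ``basquin-mises`` — the S-N (Basquin) power law
  sigma_eq = sigma_f + sigma_L * N**(-beta) applied to the von Mises field
  of the maximum-effort static solve, with sigma_L calibrated so the curve
  passes through the yield point at N = 10^3 cycles:
  sigma_L = 10**(3*beta) * (sigma_02 - sigma_f).
* ``swt-principal`` — the Smith-Watson-Topper mean-stress-sensitive measure
  sigma_SWT = sqrt(<sigma1_max>_+ * Delta_sigma1 / 2), gated by the Macaulay
  bracket so purely compressive states never fail (opening-mode cracking),
  inverted through its own Basquin-type curve
  sigma_u~ + sigma_V * N**(-beta_VH).

Lives are capped at N_max (default 10^9 cycles, beyond a human lifetime of
mastication) and nodes are classified red (N <= 10^3), intermediate, or
non-hazardous (N >= N_max).

The acrylic fatigue constants are not standardised; the shipped defaults are
a documented placeholder set (yield 60 MPa tied to the ultimate compressive
strength, fatigue limit 40% of it, exponent 0.1) and the SWT curve defaults
to the uniaxial one.  Quantitative service-life statements require
user-supplied constants (``placeholder=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .fem import StressField, principal_stresses, von_mises

__all__ = [
    "FatigueParams",
    "LifeField",
    "calibrate_sigma_L",
    "basquin_stress",
    "basquin_cycles",
    "swt_equivalent",
    "swt_cycles",
    "life_field",
    "cycles_to_years",
    "RED_CYCLES",
]

logger = logging.getLogger(__name__)

RED_CYCLES = 1.0e3
HAZARD_LABELS = {2: "red", 1: "intermediate", 0: "non-hazardous"}


def calibrate_sigma_L(sigma_yield: float, sigma_fatigue: float,
                      beta: float) -> float:
    """Amplitude coefficient anchoring the S-N curve to yield at 10^3 cycles."""
    if sigma_yield <= sigma_fatigue:
        raise ValueError(
            f"invalid material: yield point {sigma_yield} MPa must exceed "
            f"fatigue limit {sigma_fatigue} MPa")
    if beta < 0:
        raise ValueError(f"fatigue exponent must be >= 0, got {beta}")
    return 10.0 ** (3.0 * beta) * (sigma_yield - sigma_fatigue)


@dataclass(frozen=True)
class FatigueParams:
    """Fatigue constants (MPa, cycles).

    ``sigma_yield`` (sigma_0.2), ``sigma_fatigue`` (endurance limit) and
    ``beta`` define the S-N curve; ``sigma_L`` is derived.  ``swt_*`` are
    the Basquin-side constants of the SWT criterion; by default they mirror
    the uniaxial set so the SWT curve coincides with the S-N curve under
    fully reversed uniaxial cycling.
    """

    sigma_yield: float = 60.0
    sigma_fatigue: float = 24.0
    beta: float = 0.1
    swt_sigma_u: float | None = None
    swt_sigma_v: float | None = None
    swt_beta: float | None = None
    n_max: float = 1.0e9
    placeholder: bool = True

    def __post_init__(self):
        calibrate_sigma_L(self.sigma_yield, self.sigma_fatigue, self.beta)
        if self.beta <= 0 or (self.swt_beta is not None and self.swt_beta <= 0):
            raise ValueError("fatigue curve exponents must be > 0")
        if self.n_max <= RED_CYCLES:
            raise ValueError("n_max must exceed the red-zone threshold")
        if self.placeholder:
            logger.info(
                "using placeholder acrylic fatigue constants "
                "(sigma_yield=%.3g, sigma_fatigue=%.3g, beta=%.3g); supply "
                "measured values for non-demo runs", self.sigma_yield,
                self.sigma_fatigue, self.beta)

    @property
    def sigma_L(self) -> float:
        return calibrate_sigma_L(self.sigma_yield, self.sigma_fatigue, self.beta)

    @property
    def swt(self) -> tuple[float, float, float]:
        su = self.swt_sigma_u if self.swt_sigma_u is not None else self.sigma_fatigue
        sv = self.swt_sigma_v if self.swt_sigma_v is not None else self.sigma_L
        b = self.swt_beta if self.swt_beta is not None else self.beta
        return su, sv, b

    def confirmed(self, **overrides) -> "FatigueParams":
        """User-confirmed constants for non-demo runs."""
        return replace(self, placeholder=False, **overrides)


def basquin_stress(cycles, params: FatigueParams):
    """S-N curve: equivalent stress sustained for N cycles (MPa)."""
    n = np.asarray(cycles, dtype=float)
    if np.any(n < 1):
        raise ValueError("cycle count must be >= 1")
    return params.sigma_fatigue + params.sigma_L * n ** (-params.beta)


def _invert_basquin(sigma, sigma_inf, sigma_amp, beta, n_max):
    s = np.asarray(sigma, dtype=float)
    if np.any(s < 0):
        raise ValueError("equivalent stress must be >= 0")
    with np.errstate(divide="ignore", over="ignore"):
        n = ((s - sigma_inf) / sigma_amp) ** (-1.0 / beta)
    n = np.where(s <= sigma_inf, n_max, n)
    return np.clip(n, 1.0, n_max)


def basquin_cycles(sigma_eq, params: FatigueParams):
    """Cycles to failure for a given equivalent stress (total function).

    Stresses at or below the fatigue limit map to the N_max cap; the result
    is the exact inverse of :func:`basquin_stress` on (1, N_max).
    """
    return _invert_basquin(sigma_eq, params.sigma_fatigue, params.sigma_L,
                           params.beta, params.n_max)


def swt_equivalent(sigma1_max, delta_sigma1):
    """SWT stress sqrt(<sigma1_max>_+ * Delta_sigma1 / 2) (MPa).

    The Macaulay bracket keeps only tensile maximum principal stress, so a
    compressive state cannot drive an opening-mode crack.
    """
    s_max = np.asarray(sigma1_max, dtype=float)
    d = np.asarray(delta_sigma1, dtype=float)
    if np.any(d < 0):
        raise ValueError("stress range must be >= 0")
    return np.sqrt(np.maximum(s_max, 0.0) * d / 2.0)


def swt_cycles(sigma_swt, params: FatigueParams):
    """Cycles to failure under the SWT criterion (same capping rules)."""
    su, sv, b = params.swt
    return _invert_basquin(sigma_swt, su, sv, b, params.n_max)


def cycles_to_years(cycles, meals_per_day: float = 3.0,
                    chews_per_meal: float = 1000.0):
    """Convert cycle counts to years of service for a mastication schedule."""
    if meals_per_day <= 0 or chews_per_meal <= 0:
        raise ValueError("mastication schedule must be positive")
    return np.asarray(cycles, dtype=float) / (meals_per_day * chews_per_meal * 365.0)


@dataclass
class LifeField:
    """Per-node cycles-to-failure map with hazard classes.

    ``hazard`` codes: 2 = red (N <= 10^3), 1 = intermediate,
    0 = non-hazardous (N >= N_max).
    """

    cycles: np.ndarray
    years: np.ndarray
    hazard: np.ndarray
    criterion: str
    cycle_model: str
    params: FatigueParams
    meals_per_day: float
    chews_per_meal: float

    @property
    def min_cycles(self) -> float:
        return float(self.cycles.min())

    @property
    def min_years(self) -> float:
        return float(self.years.min())

    def hazard_fraction(self, code: int = 2) -> float:
        return float(np.mean(self.hazard == code))

    def summary(self) -> dict:
        return {
            "criterion": self.criterion,
            "cycle_model": self.cycle_model,
            "min_cycles": self.min_cycles,
            "min_years": self.min_years,
            "red_fraction": self.hazard_fraction(2),
            "intermediate_fraction": self.hazard_fraction(1),
            "schedule": {"meals_per_day": self.meals_per_day,
                         "chews_per_meal": self.chews_per_meal},
            "placeholder_constants": self.params.placeholder,
        }


def life_field(stress: StressField, params: FatigueParams | None = None,
               cycle_model: str = "pulsating",
               criterion: str = "swt-principal",
               meals_per_day: float = 3.0,
               chews_per_meal: float = 1000.0) -> LifeField:
    """Map a maximum-effort static stress field to nodal cycles-to-failure.

    ``cycle_model`` describes the load history each mastication event
    imposes: "pulsating" (load applied and removed, Delta = max) or
    "fully-reversed" (Delta = 2*max; sensitivity studies).  The
    ``basquin-mises`` criterion uses the static von Mises field directly;
    ``swt-principal`` uses the tensile part of the maximum principal stress.
    """
    params = params or FatigueParams()
    if cycle_model not in ("pulsating", "fully-reversed"):
        raise ValueError(f"unknown cycle model {cycle_model!r}")

    if criterion == "basquin-mises":
        n = basquin_cycles(von_mises(stress.nodal), params)
    elif criterion == "swt-principal":
        s1 = principal_stresses(stress.nodal)[..., 0]
        delta = s1 if cycle_model == "pulsating" else 2.0 * np.abs(s1)
        delta = np.maximum(delta, 0.0)
        n = swt_cycles(swt_equivalent(s1, delta), params)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    red_edge = RED_CYCLES * (1.0 + 1e-9)  # tolerate inversion roundoff
    hazard = np.where(n <= red_edge, 2, np.where(n >= params.n_max, 0, 1))
    return LifeField(cycles=n,
                     years=cycles_to_years(n, meals_per_day, chews_per_meal),
                     hazard=hazard, criterion=criterion,
                     cycle_model=cycle_model, params=params,
                     meals_per_day=meals_per_day, chews_per_meal=chews_per_meal)
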