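"""Biodegradable-implant laws and osteogenesis metrics.

The implant fills the defect elements with an equivalent apparent density
derived from its initial modulus through the bone power law.  Two empirical
laws govern its disappearance over the degradation period T:

* mechanical contribution: E1(t) = (1 − t/T)^0.5 · E1_0 — fast early loss of
  stiffness, zero at T;
* mass bookkeeping: r(t) = ρ_implant,0 · (t/T)² — the cumulative degraded
  density, slow at first and accelerating, fully resorbed at T.

The two laws are deliberately independent (they come from different
observations) and are not linked through the density–modulus power law.
Osteogenesis is scored as the mean bone-attributable modulus over the defect
elements, 2315 ρ_j³ − E1(t), clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RemodelConfig
from .mesh import Mesh
from .remodeling import MaterialState

__all__ = [
    "ImplantState",
    "remaining_modulus",
    "implant_initial_density",
    "degraded_density",
    "osteogenesis_score",
    "new_bone_fraction",
    "refilled_area",
]


def implant_initial_density(E1_0: float, config: RemodelConfig | None = None) -> float:
    """Implant-equivalent apparent density (E1_0 / 2315)^(1/3) in g/cm³."""
    config = config or RemodelConfig()
    if E1_0 <= 0:
        raise ValueError(f"initial implant modulus must be positive, got {E1_0}")
    return float((E1_0 / config.density_modulus_coeff) ** (1.0 / config.density_modulus_exp))


@dataclass
class ImplantState:
    """Degradation bookkeeping for the implanted biomaterial.

    E1_0 in MPa, T in days; ``rho_implant_0`` defaults to the modulus-derived
    equivalent density.
    """

    E1_0: float
    T: float
    rho_implant_0: float = field(default=0.0)
    config: RemodelConfig = field(default_factory=RemodelConfig)

    def __post_init__(self) -> None:
        if self.E1_0 <= 0:
            raise ValueError("E1_0 must be positive")
        if self.T <= 0:
            raise ValueError("degradation period T must be positive")
        if self.rho_implant_0 <= 0.0:
            self.rho_implant_0 = implant_initial_density(self.E1_0, self.config)


def remaining_modulus(t: float, implant: ImplantState) -> float:
    """Remaining implant modulus E1(t) = (1 − t/T)^0.5 · E1_0, zero from T on."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if t >= implant.T:
        return 0.0
    return float((1.0 - t / implant.T) ** 0.5 * implant.E1_0)


def degraded_density(t: float, implant: ImplantState) -> float:
    """Cumulative degraded implant density r(t) = ρ_implant,0 (t/T)², capped at full."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if t >= implant.T:
        return float(implant.rho_implant_0)
    return float(implant.rho_implant_0 * (t / implant.T) ** 2)


def _implant_indices(state: MaterialState) -> np.ndarray:
    idx = np.flatnonzero(state.is_implant)
    if len(idx) == 0:
        raise ValueError("material state has no implant (defect) elements")
    return idx


def osteogenesis_score(state: MaterialState, implant: ImplantState, t: float) -> float:
    """Mean bone-attributable modulus over the defect elements (MPa).

    max(0, 2315 ρ_j³ − E1(t)) averaged over the implanted elements: the part
    of the local stiffness supplied by regenerated bone rather than by the
    remaining implant.
    """
    idx = _implant_indices(state)
    E1 = remaining_modulus(t, implant)
    cfg = implant.config
    bone_mod = cfg.density_modulus_coeff * state.density[idx] ** cfg.density_modulus_exp
    return float(np.mean(np.maximum(bone_mod - E1, 0.0)))


def new_bone_fraction(
    state: MaterialState,
    implant: ImplantState,
    baseline: np.ndarray,
    t: float,
    config: RemodelConfig,
) -> float:
    """Percentage of defect elements restored to (θ ×) their pre-defect density.

    The bone-attributable density of a defect element is its total density
    minus the surviving implant density max(ρ_implant,0 − r(t), 0); the
    element counts as new bone once that reaches ``new_bone_theta`` times its
    converged pre-defect baseline.
    """
    idx = _implant_indices(state)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape == state.density.shape:
        base = baseline[idx]
    elif len(baseline) == len(idx):
        base = baseline
    else:
        raise ValueError(
            "baseline must cover the whole mesh or exactly the defect elements"
        )
    surviving = max(implant.rho_implant_0 - degraded_density(t, implant), 0.0)
    bone_density = state.density[idx] - surviving
    restored = bone_density >= config.new_bone_theta * base
    return float(100.0 * np.mean(restored))


def refilled_area(
    state: MaterialState,
    implant: ImplantState,
    mesh: Mesh,
    t: float,
    threshold: float | None = None,
) -> float:
    """Defect cross-section area (mm²) still occupied by dense material.

    Sums the areas of defect elements whose total apparent density exceeds
    the radio-visibility threshold (default: half the initial implant
    density) — the simulated analogue of the micro-CT refilled-defect area.
    """
    idx = _implant_indices(state)
    if threshold is None:
        threshold = implant.config.refill_threshold
    if threshold is None:
        threshold = 0.5 * implant.rho_implant_0
    area_cm2 = mesh.element_area[idx]
    dense = state.density[idx] >= threshold
    return float(np.sum(area_cm2[dense]) * 100.0)  # cm² → mm²
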