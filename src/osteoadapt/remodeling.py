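"""Strain-energy-driven density adaptation under a total-mass constraint.

The adaptation model treats bone as a self-optimizing structure: at each
step the target apparent-density field ρ̂ minimizes the total strain energy

    F(ρ) = Σ_j ½ σ_jᵀ S_j σ_j v_j

subject to the mass constraint Σ_j ρ_j v_j = const and the density bounds
(ρ_min, 1.8] g/cm³.  Stiffness follows the cubic density–modulus power law
E = 2315 ρ³ (MPa), so the problem is the classic compliance minimization
with penalization exponent 3.  ρ̂ is found with the optimality-criteria (OC)
method: a damped multiplicative update with a move limit, the Lagrange
multiplier of the mass constraint resolved by bisection each inner
iteration.  The daily update then moves the actual density a small fraction
c toward the target and subtracts any implant degradation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .config import RemodelConfig
from .mesh import Mesh

log = logging.getLogger("osteoadapt")

__all__ = [
    "MaterialState",
    "density_to_modulus",
    "modulus_to_density",
    "predict_density",
    "apply_update",
    "check_convergence",
    "oc_kkt_residual",
]


def density_to_modulus(rho, config: RemodelConfig | None = None):
    """Elastic modulus (MPa) from apparent density via E = 2315 ρ³."""
    config = config or RemodelConfig()
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("apparent density must be positive")
    out = config.density_modulus_coeff * rho**config.density_modulus_exp
    return float(out) if out.ndim == 0 else out


def modulus_to_density(E, config: RemodelConfig | None = None):
    """Inverse of :func:`density_to_modulus`."""
    config = config or RemodelConfig()
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("modulus must be positive")
    out = (E / config.density_modulus_coeff) ** (1.0 / config.density_modulus_exp)
    return float(out) if out.ndim == 0 else out


@dataclass
class MaterialState:
    """Per-element material state of the adapting bone.

    density in g/cm³, volume in cm³ (area × unit thickness), modulus in MPa
    (kept consistent with density through the power law), ``is_implant``
    flags the defect elements, and ``mass_reference`` is the current total
    mass Σ ρ_j v_j in g — the right-hand side of the mass constraint.
    """

    density: np.ndarray
    volume: np.ndarray
    poisson: float | np.ndarray
    modulus: np.ndarray
    is_implant: np.ndarray
    mass_reference: float

    @classmethod
    def uniform(cls, mesh: Mesh, rho: float, config: RemodelConfig | None = None,
                implant_set: str = "defect") -> "MaterialState":
        """Uniform-density state on a mesh; implant flags from the named element set."""
        config = config or RemodelConfig()
        density = np.full(mesh.n_elements, float(rho))
        return cls.from_density(mesh, density, config, implant_set)

    @classmethod
    def from_density(cls, mesh: Mesh, density: np.ndarray,
                     config: RemodelConfig | None = None,
                     implant_set: str = "defect") -> "MaterialState":
        config = config or RemodelConfig()
        density = np.asarray(density, dtype=float).copy()
        if len(density) != mesh.n_elements:
            raise ValueError("density field length does not match mesh")
        volume = mesh.element_area * config.thickness_cm
        mask = np.zeros(mesh.n_elements, dtype=bool)
        if implant_set in mesh.element_sets:
            mask[mesh.element_sets[implant_set]] = True
        return cls(
            density=density,
            volume=volume,
            poisson=config.poisson,
            modulus=density_to_modulus(density, config),
            is_implant=mask,
            mass_reference=float(np.sum(density * volume)),
        )

    def with_density(self, density: np.ndarray, config: RemodelConfig) -> "MaterialState":
        """New state with the given densities, refreshed moduli and mass reference."""
        density = np.asarray(density, dtype=float).copy()
        return replace(
            self,
            density=density,
            modulus=density_to_modulus(density, config),
            mass_reference=float(np.sum(density * self.volume)),
        )

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.density * self.volume))


def _oc_bisect(rho_cur, sens, v, target_mass, floor, rho_max, eta, zeta,
               n_bisect: int = 200):
    """One OC step: multiplier bisection so the move-limited, bound-clipped
    multiplicative update hits the mass target.  ``sens`` are the per-unit-mass
    strain-energy sensitivities (non-negative)."""

    def candidate(lam):
        with np.errstate(divide="ignore"):
            B = np.where(sens > 0, sens / lam, 0.0)
        cand = rho_cur * B**eta
        cand = np.clip(cand, rho_cur - zeta, rho_cur + zeta)
        return np.clip(cand, floor, rho_max)

    lo, hi = 1e-30, 1e30
    for _ in range(n_bisect):
        lam = np.sqrt(lo * hi)
        mass = float(np.sum(candidate(lam) * v))
        if mass > target_mass:
            lo = lam
        else:
            hi = lam
        if hi / lo < 1.0 + 1e-15:
            break
    return candidate(np.sqrt(lo * hi))


def predict_density(
    mesh: Mesh,
    state: MaterialState,
    energies: np.ndarray,
    config: RemodelConfig,
    resolve: Callable[[np.ndarray], np.ndarray] | None = None,
    warm_start: np.ndarray | None = None,
) -> np.ndarray:
    """Predict the target density field ρ̂ minimizing strain energy at fixed mass.

    ``energies`` are the per-element strain energies of the current solve.
    With ``resolve`` given (a callable mapping a density field to per-element
    energies), the OC iteration re-evaluates the energies at each candidate
    and converges to a KKT point of the true constrained problem; without it,
    the energies are extrapolated under the fixed-stress assumption
    U_j(ρ̂) = U_j (ρ_j/ρ̂_j)³, which is exact for statically determinate
    states.  ``warm_start`` seeds the iteration (e.g. the previous day's ρ̂).
    """
    rho = np.asarray(state.density, dtype=float)
    U0 = np.asarray(energies, dtype=float)
    if len(U0) != mesh.n_elements or len(rho) != mesh.n_elements:
        raise ValueError("field lengths do not match mesh")
    if np.any(U0 < 0):
        raise ValueError("element energies must be non-negative")
    v = state.volume
    M = state.mass_reference
    floor, rmax = config.rho_min_floor, config.rho_max
    p = config.density_modulus_exp
    if M > np.sum(rmax * v) or M < np.sum(floor * v):
        raise ValueError(
            f"mass reference {M:.6g} g is infeasible for bounds "
            f"[{floor}, {rmax}] g/cm³ on total volume {v.sum():.6g} cm³"
        )
    if not np.any(U0 > 0):
        return rho.copy()  # zero load: every feasible field is optimal; keep current

    rho_hat = np.clip(warm_start if warm_start is not None else rho, floor, rmax).astype(float)
    history = []
    prev_step: np.ndarray | None = None
    zeta = config.oc_move_limit
    for it in range(config.oc_max_iter):
        if resolve is not None:
            U_hat = np.asarray(resolve(rho_hat), dtype=float)
        else:
            U_hat = U0 * (rho / rho_hat) ** p
        sens = p * U_hat / (rho_hat * v)
        new = _oc_bisect(rho_hat, sens, v, M, floor, rmax,
                         config.oc_damping, zeta)
        step = new - rho_hat
        if prev_step is not None:
            denom = np.linalg.norm(step) * np.linalg.norm(prev_step)
            if denom > 0 and float(step @ prev_step) < -0.5 * denom:
                # period-2 oscillation: average the iterates (mass-preserving)
                # and tighten the move limit
                new = 0.5 * (new + rho_hat)
                step = new - rho_hat
                zeta = max(0.5 * zeta, 10.0 * config.oc_tol)
        delta = float(np.max(np.abs(step)))
        mass_err = abs(float(np.sum(new * v)) - M) / M
        history.append((delta, mass_err))
        rho_hat = new
        prev_step = step
        log.debug("OC iteration %d: max|Δρ̂|=%.2e mass err=%.1e ζ=%.3f",
                  it + 1, delta, mass_err, zeta)
        if delta < config.oc_tol and mass_err < config.mass_rel_tol:
            return rho_hat
    raise RuntimeError(
        "optimality-criteria iteration did not converge within "
        f"{config.oc_max_iter} iterations; last (Δρ, mass error): {history[-5:]}"
    )


def oc_kkt_residual(rho_hat, energies_at_hat, volume, config: RemodelConfig) -> float:
    """Relative spread of the per-unit-mass energy sensitivity over interior elements.

    At a KKT point of the mass-constrained minimum, s_j = p U_j / (ρ̂_j v_j)
    is a common constant λ for every element strictly inside the bounds,
    s_j ≤ λ at the lower bound and s_j ≥ λ at the upper.  Returns the maximum
    relative violation over all three conditions (0 for a perfect KKT point).
    """
    rho_hat = np.asarray(rho_hat, dtype=float)
    U = np.asarray(energies_at_hat, dtype=float)
    v = np.asarray(volume, dtype=float)
    p = config.density_modulus_exp
    eps = 1e-6
    sens = p * U / (rho_hat * v)
    interior = (rho_hat > config.rho_min_floor + eps) & (rho_hat < config.rho_max - eps)
    at_low = rho_hat <= config.rho_min_floor + eps
    at_high = rho_hat >= config.rho_max - eps
    if interior.sum() == 0:
        return 0.0
    lam = float(np.median(sens[interior]))
    if lam <= 0:
        return float(np.max(np.abs(sens[interior])))
    res = float(np.max(np.abs(sens[interior] - lam))) / lam
    if at_low.any():
        res = max(res, float(np.max(sens[at_low] - lam)) / lam)
    if at_high.any():
        res = max(res, float(np.max(lam - sens[at_high])) / lam)
    return max(res, 0.0)


def apply_update(
    state: MaterialState,
    rho_hat: np.ndarray,
    implant_loss: np.ndarray,
    config: RemodelConfig,
) -> MaterialState:
    """One daily density update toward the target, minus implant degradation.

    Non-implant elements follow Δρ = c (ρ̂ − ρ); implant (defect) elements
    additionally lose the day's degraded implant density.  Results are
    clipped to the admissible density interval and moduli are refreshed.
    """
    rho_hat = np.asarray(rho_hat, dtype=float)
    loss = np.asarray(implant_loss, dtype=float)
    if rho_hat.shape != state.density.shape or loss.shape != state.density.shape:
        raise ValueError("field lengths do not match the material state")
    if np.any(loss[~state.is_implant] != 0.0):
        raise ValueError("implant_loss must be zero on non-implant elements")
    delta = config.c * (rho_hat - state.density) - loss
    new_rho = np.clip(state.density + delta, config.rho_min_floor, config.rho_max)
    return state.with_density(new_rho, config)


def check_convergence(prev: np.ndarray, nxt: np.ndarray, config: RemodelConfig) -> bool:
    """True when the density field no longer changes appreciably,
    max_j |Δρ_j| < convergence_tol."""
    prev = np.asarray(prev, dtype=float)
    nxt = np.asarray(nxt, dtype=float)
    if prev.shape != nxt.shape:
        raise ValueError(f"field length mismatch: {prev.shape} vs {nxt.shape}")
    return bool(np.max(np.abs(nxt - prev)) < config.convergence_tol)
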