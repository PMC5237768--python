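"""Plane-stress linear-elastic finite elements on 4-node quadrilaterals.

Element stiffness uses the bilinear isoparametric formulation with 2×2 Gauss
quadrature.  The constitutive law is plane stress: the per-element compliance

    S = (1/E) [[1, -μ, 0], [-μ, 1, 0], [0, 0, 2(1+μ)]]

relates strain to stress; the stiffness integrand uses D = S⁻¹.  Mesh
coordinates (cm) are converted to mm internally so forces in N and moduli in
MPa give displacements in mm and energies in N·mm.

Per-element strain energy is integrated at the Gauss points,
U_j = ½ u_eᵀ k_e u_e = ∫ ½ σᵀ S σ dV, so that Σ U_j equals ½ uᵀ K u to
round-off; reported stresses are the mean over the quadrature points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import LoadCase, PointLoad, RemodelConfig
from .mesh import Mesh

__all__ = [
    "ElasticField",
    "element_stiffness",
    "compliance_matrix",
    "constitutive_matrix",
    "solve",
    "combined_energy",
]

CM_TO_MM = 10.0

# 2×2 Gauss points in the reference square, weights all 1
_GP = np.array(
    [[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float
) / np.sqrt(3.0)
# reference corner signs of the bilinear shape functions
_XI = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA = np.array([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ElasticField:
    """Result of one elastic solve.

    displacements: (n_nodes, 2) mm; element_stress: (n_elements, 3) MPa as
    (σxx, σyy, τxy); element_energy: U_j in N·mm; total_energy: F = Σ U_j.
    """

    displacements: np.ndarray
    element_stress: np.ndarray
    element_energy: np.ndarray
    total_energy: float


def compliance_matrix(E: float, mu: float) -> np.ndarray:
    """Plane-stress compliance S (strain = S · stress)."""
    if E <= 0:
        raise ValueError(f"elastic modulus must be positive, got {E}")
    return np.array(
        [[1.0 / E, -mu / E, 0.0], [-mu / E, 1.0 / E, 0.0], [0.0, 0.0, 2.0 * (1.0 + mu) / E]]
    )


def constitutive_matrix(E: float, mu: float) -> np.ndarray:
    """Plane-stress stiffness D = S⁻¹ in closed form."""
    if E <= 0:
        raise ValueError(f"elastic modulus must be positive, got {E}")
    if not (0.0 <= mu < 0.5):
        raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {mu}")
    f = E / (1.0 - mu * mu)
    return f * np.array([[1.0, mu, 0.0], [mu, 1.0, 0.0], [0.0, 0.0, (1.0 - mu) / 2.0]])


def _shape_gradients(xi: float, eta: float) -> np.ndarray:
    """(2, 4) derivatives of the bilinear shape functions at (ξ, η)."""
    dxi = 0.25 * _XI * (1.0 + eta * _ETA)
    deta = 0.25 * _ETA * (1.0 + xi * _XI)
    return np.stack([dxi, deta])


def _batch_stiffness(coords_mm: np.ndarray, E: np.ndarray, mu: np.ndarray, t_mm: float):
    """Vectorized 8×8 stiffness for all elements.

    Returns (k, B_gauss, detJ_gauss) with k of shape (m, 8, 8), B of shape
    (4, m, 3, 8) and detJ of shape (4, m), for stress recovery.
    """
    m = len(coords_mm)
    k = np.zeros((m, 8, 8))
    f = E / (1.0 - mu * mu)
    D = np.zeros((m, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = f
    D[:, 0, 1] = D[:, 1, 0] = f * mu
    D[:, 2, 2] = f * (1.0 - mu) / 2.0

    B_all = np.zeros((4, m, 3, 8))
    detJ_all = np.zeros((4, m))
    for g, (xi, eta) in enumerate(_GP):
        dN = _shape_gradients(xi, eta)              # (2, 4)
        J = np.einsum("ga,mad->mgd", dN, coords_mm)  # (m, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            bad = int(np.flatnonzero(detJ <= 0)[0])
            raise ValueError(f"inverted or degenerate element (index {bad}in batch)")
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv /= detJ[:, None, None]
        dNdx = np.einsum("mgd,da->mga", Jinv, dN)    # (m, 2, 4)
        B = np.zeros((m, 3, 8))
        B[:, 0, 0::2] = dNdx[:, 0]
        B[:, 1, 1::2] = dNdx[:, 1]
        B[:, 2, 0::2] = dNdx[:, 1]
        B[:, 2, 1::2] = dNdx[:, 0]
        k += np.einsum("mia,mij,mjb,m->mab", B, D, B, detJ) * t_mm
        B_all[g] = B
        detJ_all[g] = detJ
    return k, B_all, detJ_all


def element_stiffness(coords, E: float, mu: float, thickness_mm: float = 10.0) -> np.ndarray:
    """8×8 plane-stress stiffness of a single quad (coords in mm, E in MPa)."""
    if E <= 0:
        raise ValueError(f"elastic modulus must be positive, got {E}")
    if not (0.0 <= mu < 0.5):
        raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {mu}")
    coords = np.asarray(coords, dtype=float).reshape(1, 4, 2)
    k, _, _ = _batch_stiffness(coords, np.array([E]), np.array([mu]), thickness_mm)
    return k[0]


def _dof_map(elements: np.ndarray) -> np.ndarray:
    """(m, 8) global dof indices per element, (ux0, uy0, ux1, uy1, …)."""
    dofs = np.empty((len(elements), 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * elements
    dofs[:, 1::2] = 2 * elements + 1
    return dofs


def _load_vector(mesh: Mesh, case: LoadCase, n_dof: int) -> np.ndarray:
    f = np.zeros(n_dof)
    for pl in case.loads:
        if pl.node_set not in mesh.node_sets:
            raise KeyError(f"load targets unknown node set {pl.node_set!r}")
        nodes = mesh.node_sets[pl.node_set]
        if len(nodes) == 0:
            raise ValueError(f"load node set {pl.node_set!r} is empty")
        a = np.deg2rad(pl.angle_deg)
        fx = pl.sense[0] * pl.magnitude * np.cos(a) / len(nodes)
        fy = pl.sense[1] * pl.magnitude * np.sin(a) / len(nodes)
        f[2 * nodes] += fx
        f[2 * nodes + 1] += fy
    return f


class _Factorized:
    """Assembled and factorized global system for one material state.

    Supports are taken from the mesh node sets: ``fixed`` clamps both dofs,
    ``fixed_x`` / ``fixed_y`` act as rollers clamping one direction.
    ``prescribed`` optionally imposes nonzero displacements, mapping global
    dof index (2·node for ux, 2·node+1 for uy) to a value in mm.
    """

    def __init__(self, mesh: Mesh, materials, config: RemodelConfig | None,
                 fixed_set: str = "fixed",
                 prescribed: dict[int, float] | None = None):
        config = config or RemodelConfig()
        self.mesh = mesh
        self.config = config
        E = np.maximum(np.asarray(materials.modulus, dtype=float), config.min_modulus)
        if np.any(~np.isfinite(E)) or np.any(E <= 0):
            raise ValueError("non-positive or non-finite element modulus")
        mu = np.broadcast_to(np.asarray(materials.poisson, dtype=float), (mesh.n_elements,))
        coords_mm = mesh.element_coords * CM_TO_MM
        t_mm = config.thickness_cm * CM_TO_MM
        k, self.B, self.detJ = _batch_stiffness(coords_mm, E, mu, t_mm)
        self.k_elem = k
        self.E = E
        self.mu = mu
        self.t_mm = t_mm

        n_dof = 2 * mesh.n_nodes
        dofs = _dof_map(mesh.elements)
        rows = np.repeat(dofs, 8, axis=1).ravel()
        cols = np.tile(dofs, (1, 8)).ravel()
        K = sp.coo_matrix((k.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsc()

        prescribed = dict(prescribed or {})
        con_vals: dict[int, float] = {}
        if fixed_set is not None and fixed_set in mesh.node_sets:
            for nd in mesh.node_sets[fixed_set]:
                con_vals[2 * nd] = 0.0
                con_vals[2 * nd + 1] = 0.0
        for name, offset in (("fixed_x", 0), ("fixed_y", 1)):
            for nd in mesh.node_sets.get(name, ()):
                con_vals[2 * nd + offset] = 0.0
        con_vals.update(prescribed)
        if not con_vals and fixed_set is not None:
            raise KeyError(f"mesh has no node set {fixed_set!r} for supports")
        if len(con_vals) < 3:
            raise ValueError(
                f"only {len(con_vals)} constrained dofs; rigid-body modes "
                "(2 translations + 1 rotation) are unconstrained"
            )
        self.con = np.array(sorted(con_vals), dtype=np.int64)
        self.u_con = np.array([con_vals[d] for d in self.con])
        self.free = np.setdiff1d(np.arange(n_dof), self.con)
        self.n_dof = n_dof
        self.Kfc = K[np.ix_(self.free, self.con)].tocsc()
        Kff = K[np.ix_(self.free, self.free)].tocsc()
        try:
            self.lu = spla.splu(Kff)
        except RuntimeError as err:  # pragma: no cover - singular input
            raise ValueError(f"singular stiffness matrix: {err}") from err
        self.dofs = dofs

    def solve_case(self, case: LoadCase) -> ElasticField:
        f = _load_vector(self.mesh, case, self.n_dof)
        u = np.zeros(self.n_dof)
        u[self.con] = self.u_con
        rhs = f[self.free] - self.Kfc @ self.u_con
        u[self.free] = self.lu.solve(rhs)
        if not np.all(np.isfinite(u)):
            raise ValueError("singular system: solution contains non-finite values")
        ue = u[self.dofs]                                  # (m, 8)
        U = 0.5 * np.einsum("ma,mab,mb->m", ue, self.k_elem, ue)
        U = np.maximum(U, 0.0)                             # clamp round-off negatives
        # mean stress over the Gauss points
        f2 = self.E / (1.0 - self.mu**2)
        strain = np.einsum("gmib,mb->gmi", self.B, ue)     # (4, m, 3)
        stress = np.empty_like(strain)
        stress[..., 0] = f2 * (strain[..., 0] + self.mu * strain[..., 1])
        stress[..., 1] = f2 * (strain[..., 1] + self.mu * strain[..., 0])
        stress[..., 2] = f2 * (1.0 - self.mu) / 2.0 * strain[..., 2]
        return ElasticField(
            displacements=u.reshape(-1, 2),
            element_stress=stress.mean(axis=0),
            element_energy=U,
            total_energy=float(U.sum()),
        )


def solve(mesh: Mesh, materials, load: LoadCase, config: RemodelConfig | None = None,
          fixed_set: str = "fixed",
          prescribed: dict[int, float] | None = None) -> ElasticField:
    """Assemble, apply supports and the load case, and solve.

    Returns nodal displacements (mm), mean element stresses (MPa), per-element
    strain energies U_j (N·mm) and their sum F.  ``prescribed`` imposes
    nonzero boundary displacements (global dof index → mm).
    """
    return _Factorized(mesh, materials, config, fixed_set, prescribed).solve_case(load)


def combined_energy(
    mesh: Mesh,
    materials,
    loads: Sequence[LoadCase],
    config: RemodelConfig | None = None,
    fixed_set: str = "fixed",
) -> tuple[np.ndarray, float, list[ElasticField]]:
    """Weighted-average element strain energy over alternative load cases.

    Each case is solved independently against the same stiffness factorization;
    per-element energies are averaged with the case weights (equal by default).
    Returns (element_energy, total_energy, per-case fields).
    """
    if len(loads) == 0:
        raise ValueError("at least one load case is required")
    fact = _Factorized(mesh, materials, config, fixed_set)
    fields = [fact.solve_case(case) for case in loads]
    w = np.array([case.weight for case in loads], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("load-case weights must be non-negative with positive sum")
    w = w / w.sum()
    energy = np.einsum("c,cm->m", w, np.stack([f.element_energy for f in fields]))
    return energy, float(energy.sum()), fields
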