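"""Configuration objects for the bone-adaptation simulator.

All scalar constants of the remodeling method live in :class:`RemodelConfig`;
parametric domain geometry lives in :class:`FemurGeometry` / :class:`RatGeometry`.
Configs are plain dataclasses and round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class PointLoad:
    """A concentrated force applied to a named boundary node set.

    The force is decomposed as ``(sx * |f| * cos(angle), sy * |f| * sin(angle))``
    with the angle measured from the horizontal and divided equally among the
    nodes of the target set.  The sign pair ``sense`` orients the force: the
    hip joint reaction pushes down into the femoral head ``(+1, -1)`` while the
    abductor tension pulls the greater trochanter up and medially ``(-1, +1)``.
    """

    magnitude: float          # N
    angle_deg: float          # degrees from horizontal, [0, 360)
    node_set: str
    sense: tuple[float, float] = (1.0, -1.0)

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError(f"force magnitude must be >= 0, got {self.magnitude}")
        if not (0.0 <= self.angle_deg < 360.0):
            raise ValueError(f"angle must lie in [0, 360), got {self.angle_deg}")


@dataclass(frozen=True)
class LoadCase:
    """One loading configuration: simultaneous point loads plus an averaging weight."""

    loads: tuple[PointLoad, ...]
    weight: float = 1.0
    name: str = ""


#: Hip joint reaction + abductor (trochanter) tension for three gait instants.
#: Each row is applied as one alternative load case; element strain energies
#: are averaged over the three cases with equal weights.
FEMUR_LOAD_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (1700.0, 25.0, 576.0, 35.0),
    (2271.0, 66.0, 703.0, 62.0),
    (1049.0, 15.0, 248.0, 8.0),
)


def femur_load_cases() -> tuple[LoadCase, ...]:
    """The three standard proximal-femur load cases (joint force + abductor pull)."""
    cases = []
    for i, (fj, aj, ft, at) in enumerate(FEMUR_LOAD_TABLE):
        cases.append(
            LoadCase(
                loads=(
                    PointLoad(fj, aj, "head", sense=(1.0, -1.0)),
                    PointLoad(ft, at, "trochanter", sense=(-1.0, 1.0)),
                ),
                weight=1.0,
                name=f"gait_{i + 1}",
            )
        )
    return tuple(cases)


def rat_load_cases() -> tuple[LoadCase, ...]:
    """Single vertical joint force of 0.65 N on the rat metaphysis top surface."""
    return (
        LoadCase(
            loads=(PointLoad(0.65, 90.0, "joint", sense=(1.0, -1.0)),),
            weight=1.0,
            name="rat_joint",
        ),
    )


@dataclass
class FemurGeometry:
    """Parametric 2D proximal-femur-like outline (all lengths in cm).

    The outline is a union of a shaft rectangle, a spherical head, a neck
    capsule joining them and a greater-trochanter lobe.  It is a stylized
    stand-in for a CT-derived cross-section: topology and loading are
    anatomical, absolute geometry is not.
    """

    element_size: float = 0.5        # edge length; element area 0.25 cm^2
    shaft_x: tuple[float, float] = (4.5, 17.5)
    shaft_top: float = 13.5
    head_center: tuple[float, float] = (4.6, 18.8)
    head_radius: float = 4.6
    neck_width: float = 6.4
    neck_base: tuple[float, float] = (11.5, 10.5)
    trochanter_center: tuple[float, float] = (15.6, 16.0)
    trochanter_radius: float = 3.0
    cortical_thickness: float = 1.0
    # defect: block of defect_nx x defect_ny elements whose lateral (right)
    # edge sits on the lateral shaft cortex, spanning cortical + cancellous bone
    defect_enabled: bool = True
    defect_nx: int = 6
    defect_ny: int = 6
    # default siting: lateral intertrochanteric metaphysis, the usual drilled
    # defect site, spanning the trochanteric cortical shell and cancellous bone
    defect_x0: float | None = 13.0   # left edge; None = flush with the lateral shaft cortex
    defect_y0: float = 15.0          # lower edge of the defect block


@dataclass
class RatGeometry:
    """Parametric rat distal-femur metaphysis cross-section (lengths in cm).

    A rectangular metaphysis with medial/lateral cortical walls, a proximal
    (older, stiffer) and distal (metaphyseal, softer) cortical segment, a
    cancellous core, and a 3 mm x 3 mm defect drilled into the lateral cortex.
    """

    # anatomical scale of a ~200 g rat: metaphysis outer width ≈ 5 mm,
    # cortical walls ≈ 0.5 mm
    element_size: float = 0.025      # 0.25 mm
    width: float = 0.5               # 5 mm
    height: float = 0.8              # 8 mm
    cortical_thickness: float = 0.055    # 0.5 mm walls (2 element columns)
    metaphyseal_fraction: float = 0.45   # top fraction of cortex at the lower modulus
    defect_enabled: bool = True
    defect_size: float = 0.3         # 3 mm square defect
    defect_y0: float = 0.45          # lower edge (cm): in the metaphyseal cortex


#: Initial elastic moduli (MPa) of the rat metaphysis regions.
RAT_REGION_MODULI: dict[str, float] = {
    "cortical_diaphyseal": 7000.0,
    "cortical_metaphyseal": 2000.0,
    "cancellous": 900.0,
    "defect": 800.0,
}


@dataclass
class RemodelConfig:
    """Scalar constants of the density-adaptation method.

    Densities in g/cm^3, moduli in MPa, time in days, coordinates in cm
    (converted to mm internally so N and MPa are consistent).
    """

    # daily update
    c: float = 0.02                  # recycling control rate per day
    step_days: int = 1
    convergence_tol: float = 0.001   # max |Δρ| stopping threshold (g/cm^3)
    max_iterations: int = 2000       # cap on remodeling days

    # density law and bounds
    rho_max: float = 1.8
    rho_min_floor: float = 0.01
    density_modulus_coeff: float = 2315.0   # MPa per (g/cm^3)^exp
    density_modulus_exp: float = 3.0
    poisson: float = 0.3
    min_modulus: float = 0.01        # MPa floor for near-void elements
    thickness_cm: float = 1.0        # out-of-plane thickness for v_j

    # optimality-criteria solver for the density prediction
    oc_damping: float = 0.5          # exponent η of the multiplicative update
    oc_move_limit: float = 0.2       # max |Δρ| per inner iteration (g/cm^3)
    oc_tol: float = 1e-4             # inner fixed-point tolerance
    oc_max_iter: int = 300
    mass_rel_tol: float = 1e-9       # relative mass-constraint tolerance

    # implant / metrics
    implant_modulus: float = 1000.0  # E1_0 (MPa)
    degradation_period: int = 20     # T (days)
    new_bone_theta: float = 0.9      # fraction of baseline density counted as restored
    refill_threshold: float | None = None   # default: 0.5 * initial implant density
    rat_degradation_period: int = 28        # CSC resorbs in ~4 weeks in vivo
    report_days: tuple[int, ...] = (7, 17, 27)

    # domains
    femur: FemurGeometry = field(default_factory=FemurGeometry)
    rat: RatGeometry = field(default_factory=RatGeometry)

    def __post_init__(self) -> None:
        if not (0.0 < self.oc_damping <= 1.0):
            raise ValueError("oc_damping must lie in (0, 1]")
        if not (0.0 < self.oc_move_limit < 1.0):
            raise ValueError("oc_move_limit must lie in (0, 1)")
        for name in ("c", "rho_max", "rho_min_floor", "convergence_tol",
                     "density_modulus_coeff", "density_modulus_exp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rho_min_floor >= self.rho_max:
            raise ValueError("rho_min_floor must be below rho_max")


def default_config() -> RemodelConfig:
    """The packaged default: femur defect with E1_0 = 1000 MPa, T = 20 days."""
    return RemodelConfig()


def _as_plain(obj):
    d = asdict(obj)

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [conv(v) for v in x]
        if isinstance(x, list):
            return [conv(v) for v in x]
        return x

    return conv(d)


def save_config(config: RemodelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain(config), sort_keys=False))


def _tupled(seq) -> tuple:
    return tuple(tuple(x) if isinstance(x, list) else x for x in seq)


def load_config(path: str | Path) -> RemodelConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    femur = raw.pop("femur", None)
    rat = raw.pop("rat", None)
    cfg_kwargs = dict(raw)
    if "report_days" in cfg_kwargs:
        cfg_kwargs["report_days"] = tuple(cfg_kwargs["report_days"])
    cfg = RemodelConfig(**cfg_kwargs)
    if femur is not None:
        for key in ("shaft_x", "head_center", "neck_base", "trochanter_center"):
            if key in femur and isinstance(femur[key], list):
                femur[key] = tuple(femur[key])
        cfg.femur = FemurGeometry(**femur)
    if rat is not None:
        cfg.rat = RatGeometry(**rat)
    return cfg
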