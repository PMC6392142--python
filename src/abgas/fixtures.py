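"""Synthetic Y-shaped coarse-grained antibodies and synthetic IM-MS observables.

Real antibody inputs are prepared atomistic models; everything in this module
is a deliberately simple stand-in that preserves the features the workflow
actually exercises: two globular Fab arms and an Fc stem joined by flexible
upper-hinge linkers, a hinge disulfide pair anchoring the Fc core, and
IM-MS observables (charge-state ladders, travelling-wave calibrant tables)
with known ground truth.  All generators are deterministic for a fixed seed.

Fixture conventions
-------------------
* Domain beads use the pseudo-element ``"X"`` whose collision radius is the
  fixture's ``bead_radius``; :meth:`radii_table` returns a table covering it.
* Flexible linker residues carry a 3-bead N/CA/C peptide backbone (standard
  bond geometry, ~3.6 A rise per residue) so that phi/psi torsions are well
  defined and the hinge kinematics code path is identical for coarse-grained
  and atomistic inputs.  Residue counts therefore remain comparable to real
  upper-hinge residue counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccs import CollisionRadiiTable
from .structure import AntibodyTopology, AtomRecord, DisulfideBond, Structure

__all__ = [
    "PROTON_MASS",
    "SyntheticAntibodyParams",
    "GenerationError",
    "make_synthetic_antibody",
    "make_calibrant_set",
    "make_charge_ladder",
]

PROTON_MASS = 1.00728  # Da

_RISE_PER_RESIDUE = 3.6  # extended-backbone rise, A; keeps counts comparable to Calpha spacing


class GenerationError(ValueError):
    """Raised when fixture parameters produce impossible geometry."""


@dataclass(frozen=True)
class SyntheticAntibodyParams:
    """Geometry of the toy antibody.

    ``arm_length`` / ``stem_length`` are the long axes of the Fab / Fc capsule
    domains; ``inter_arm_angle`` is the opening angle between the two arms of
    the Y in the initial pose.  ``flexible_residues_per_arm`` controls hinge
    length exactly like the upper-hinge residue count of a real subclass
    (IgG2-like 3 ... IgG3-like 12).
    """

    beads_per_domain: int = 48
    bead_radius: float = 1.9
    arm_length: float = 30.0
    stem_length: float = 30.0
    flexible_residues_per_arm: int = 5
    inter_arm_angle: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beads_per_domain < 1:
            raise ValueError("beads_per_domain must be >= 1")
        if min(self.bead_radius, self.arm_length, self.stem_length) <= 0:
            raise ValueError("all lengths must be positive")
        if self.flexible_residues_per_arm < 0:
            raise ValueError("flexible_residues_per_arm must be >= 0")

    def radii_table(self, probe_radius: float = 1.0) -> CollisionRadiiTable:
        """Default radii plus the fixture bead pseudo-element ``X``."""
        return CollisionRadiiTable.default(probe_radius).with_element("X", self.bead_radius)


def _capsule_beads(n: int, length: float, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Deterministic lattice of n beads filling a capsule along +z, centred at 0."""
    for girth in range(1, 64):
        radius = spacing * girth / 2.0
        rings = max(1, int(length / spacing))
        pts = []
        for iz in range(rings):
            z = -length / 2.0 + (iz + 0.5) * length / rings
            shells = max(1, girth)
            for ir in range(shells):
                rr = radius * (ir + 0.5) / shells
                per_ring = max(1, int(2 * np.pi * rr / spacing)) if ir > 0 else 1
                for ia in range(per_ring):
                    ang = 2 * np.pi * ia / per_ring + 0.31 * iz  # twist de-aligns rings
                    pts.append((rr * np.cos(ang), rr * np.sin(ang), z))
        if len(pts) >= n:
            pts = np.array(pts[:n])
            pts += rng.normal(scale=0.05, size=pts.shape)  # tiny seeded jitter
            return pts
    raise GenerationError("could not pack beads into capsule")


def _orient(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the given unit axis."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _backbone_chain(start: np.ndarray, direction: np.ndarray, n_res: int) -> np.ndarray:
    """Zig-zag N/CA/C backbone with standard bond lengths along a direction.

    Returns an array of shape (3*n_res, 3): residues ordered along the chain,
    atoms N, CA, C within each residue.
    """
    direction = direction / np.linalg.norm(direction)
    # lateral unit vector perpendicular to the chain direction
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    lat = np.cross(direction, ref)
    lat /= np.linalg.norm(lat)
    bonds = [1.458, 1.525, 1.329]  # N-CA, CA-C, C-N(next)
    coords = []
    pos = start.astype(float).copy()
    sign = 1.0
    k = 0
    for _ in range(n_res):
        for _ in range(3):
            b = bonds[k % 3]
            ang = np.deg2rad(30.0) * sign  # ~120 deg zig-zag in the chain plane
            step = np.cos(ang) * direction + np.sin(ang) * lat
            pos = pos + b * step
            coords.append(pos.copy())
            sign = -sign
            k += 1
    return np.array(coords)


def make_synthetic_antibody(
    params: SyntheticAntibodyParams,
) -> tuple[Structure, AntibodyTopology]:
    """Build a Y-shaped coarse-grained antibody and its topology.

    Four chains: heavy chains ``A``/``B`` (Fab half -> upper-hinge linker ->
    hinge CYS -> Fc half), light chains ``C``/``D`` (the other Fab half).
    The hinge CYS SG beads of the two heavy chains sit 2.05 A apart so
    disulfide detection finds exactly one inter-heavy bond.

    Raises
    ------
    GenerationError
        If the initial pose would force inter-domain bead overlap below
        0.9 x bead diameter.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    spacing = 2.0 * p.bead_radius * 1.05
    half = np.deg2rad(p.inter_arm_angle / 2.0)
    arm_dirs = [
        np.array([np.sin(half), np.cos(half), 0.0]),
        np.array([-np.sin(half), np.cos(half), 0.0]),
    ]

    # Fc stem capsule pointing down from the hinge junction
    stem_local = _capsule_beads(p.beads_per_domain, p.stem_length, spacing, rng)
    stem_girth = float(np.max(np.linalg.norm(stem_local[:, :2], axis=1))) + p.bead_radius
    stem_top = np.array([0.0, -2.0, 0.0])
    stem_center = stem_top + np.array([0.0, -(p.stem_length / 2 + p.bead_radius), 0.0])
    stem = stem_local @ _orient(np.array([0.0, -1.0, 0.0])).T + stem_center

    # hinge CYS pair just above the stem top, each on its own arm's side
    cys_sg = [np.array([1.025, 0.0, 0.0]), np.array([-1.025, 0.0, 0.0])]

    hinge_len = 3 * p.flexible_residues_per_arm * 1.2  # rough backbone extent
    arm_offset = 2.0 + hinge_len + p.arm_length / 2 + 2 * p.bead_radius

    chains: list[AtomRecord] = []
    serial = 1
    rigid: dict[str, list[tuple[str, int]]] = {"Fab1": [], "Fab2": [], "Fc_core": []}
    flexible: dict[str, list[tuple[str, int]]] = {"arm1": [], "arm2": []}

    def add(chain: str, res: int, name: str, element: str, pos, res_name: str = "BEA") -> None:
        nonlocal serial
        chains.append(
            AtomRecord(serial, name, element, res_name, res, chain, tuple(float(v) for v in pos))
        )
        serial += 1

    n_fab_heavy = (p.beads_per_domain + 1) // 2
    fab_centers = []
    for arm_i, (heavy, light, u) in enumerate(zip("AB", "CD", arm_dirs), start=1):
        # flexible linker from near the hinge CYS out along the arm direction;
        # arms offset in +-z so their hinge-proximal residues cannot touch
        linker_start = cys_sg[arm_i - 1] + np.array([0.0, 1.0, 1.2 if arm_i == 1 else -1.2])
        bb = (
            _backbone_chain(linker_start, u, p.flexible_residues_per_arm)
            if p.flexible_residues_per_arm
            else np.zeros((0, 3))
        )
        fab_anchor = bb[-1] if len(bb) else linker_start
        fab_center = fab_anchor + u * (p.arm_length / 2 + 2 * p.bead_radius)
        fab_centers.append(fab_center)
        fab_local = _capsule_beads(p.beads_per_domain, p.arm_length, spacing, rng)
        fab = fab_local @ _orient(u).T + fab_center

        # heavy chain: Fab half (res 1..nH), linker, hinge CYS, Fc half
        res = 0
        for i in range(n_fab_heavy):
            res += 1
            add(heavy, res, "X", "X", fab[i])
            rigid[f"Fab{arm_i}"].append((heavy, res))
        hinge_first = res + 1
        # linker residues run N->C from the Fab toward the hinge CYS, so
        # reverse the geometric build order (which went hinge -> Fab)
        for r in range(p.flexible_residues_per_arm):
            res += 1
            tri = bb[3 * (p.flexible_residues_per_arm - 1 - r) : 3 * (p.flexible_residues_per_arm - r)]
            add(heavy, res, "N", "N", tri[2])
            add(heavy, res, "CA", "C", tri[1])
            add(heavy, res, "C", "C", tri[0])
            flexible[f"arm{arm_i}"].append((heavy, res))
        res += 1
        cys_res = res
        add(heavy, res, "CA", "C", cys_sg[arm_i - 1] + np.array([0.0, 0.5, 0.8]), "CYS")
        add(heavy, res, "SG", "S", cys_sg[arm_i - 1], "CYS")
        rigid["Fc_core"].append((heavy, res))
        half_stem = stem[arm_i - 1 :: 2]
        for i in range(len(half_stem)):
            res += 1
            add(heavy, res, "X", "X", half_stem[i])
            rigid["Fc_core"].append((heavy, res))
        # light chain: other Fab half
        for i, bead in enumerate(fab[n_fab_heavy:], start=1):
            add(light, i, "X", "X", bead)
            rigid[f"Fab{arm_i}"].append((light, i))

    structure = Structure.from_records(
        chains,
        metadata={
            "title": "synthetic Y-shaped antibody fixture",
            "fixture_params": {
                "beads_per_domain": p.beads_per_domain,
                "bead_radius": p.bead_radius,
                "arm_length": p.arm_length,
                "stem_length": p.stem_length,
                "flexible_residues_per_arm": p.flexible_residues_per_arm,
                "inter_arm_angle": p.inter_arm_angle,
                "seed": p.seed,
            },
            "hinge_span": {
                "A": (hinge_first, cys_res),
                "B": (hinge_first, cys_res),
            },
            "chain_annotation": {"A": "heavy", "B": "heavy", "C": "light", "D": "light"},
        },
    )

    disulfide = DisulfideBond(("A", cys_res), ("B", cys_res), 2.05)
    topology = AntibodyTopology(
        rigid_bodies=rigid, flexible_residues=flexible, disulfides=[disulfide]
    )

    # initial-pose sanity: no inter-domain bead overlap below 0.9 x diameter
    body_id = np.full(len(structure), -1)
    for b, name in enumerate(["Fab1", "Fab2", "Fc_core"]):
        body_id[structure.residue_mask(rigid[name])] = b
    coords = structure.coord
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(0.9 * 2 * p.bead_radius):
        if body_id[i] != body_id[j] and body_id[i] >= 0 and body_id[j] >= 0:
            raise GenerationError(
                "initial pose forces inter-domain overlap; increase inter_arm_angle "
                "or flexible_residues_per_arm"
            )
    return structure, topology


def make_calibrant_set(
    power_A: float,
    power_B: float,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    gas_mass: float = 28.006,
) -> pd.DataFrame:
    """Synthetic travelling-wave calibrant table with known power law.

    Reference CCS values follow a protein-like mass scaling; drift times are
    constructed so that corrected CCS' = ``power_A * t'**power_B`` holds
    exactly at ``noise_sd`` = 0, with multiplicative Gaussian drift-time noise
    otherwise.  Columns: ``ccs`` (A^2), ``drift_time``, ``mass`` (Da),
    ``charge``.
    """
    if n < 2:
        raise ValueError("calibration needs at least 2 calibrants")
    if power_A <= 0:
        raise ValueError("power_A must be positive")
    rng = np.random.default_rng(seed)
    mass = np.geomspace(1.2e4, 8e5, n)
    charge = np.clip(np.round(0.078 * np.sqrt(mass)), 1, None).astype(int)
    ccs = 2.435 * mass ** (2.0 / 3.0)
    mu = mass * gas_mass / (mass + gas_mass)
    ccs_corr = ccs * np.sqrt(mu) / charge
    t_prime = (ccs_corr / power_A) ** (1.0 / power_B)
    drift = t_prime * (1.0 + noise_sd * rng.standard_normal(n))
    return pd.DataFrame({"ccs": ccs, "drift_time": drift, "mass": mass, "charge": charge})


def make_charge_ladder(mass: float, charges: list[int]) -> np.ndarray:
    """m/z peak positions of a protonated charge-state ladder (ascending)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if len(charges) == 0:
        raise ValueError("charge list is empty")
    z = np.asarray(charges, dtype=float)
    if np.any(z <= 0) or len(set(charges)) != len(charges):
        raise ValueError("charges must be positive and distinct")
    return np.sort((mass + z * PROTON_MASS) / z)
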