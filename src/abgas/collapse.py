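"""Gas-phase collapse of a charged conformer by coarse-grained vacuum dynamics.

One bead per residue (the CA atom, or the native bead of coarse fixtures)
evolves under Langevin dynamics with no solvent: harmonic bonds along each
chain, an elastic network holding every rigid body's internal shape, a soft
generalised Lennard-Jones (6-3) cohesion between beads of different bodies,
and unscreened Coulomb repulsion between the protonated sites (vacuum
dielectric of 1).  The 6-3 well is the mean-force attraction between
residue-scale beads — each bead aggregates the dispersion, hydrogen-bonding
and dipolar attraction of a whole residue, which makes the effective well
deeper and longer-ranged than an atomic 12-6; rigid-body interiors are
governed by the elastic network alone.  The CCS is recorded along the
trajectory and the final window quantifies how narrow a CCS range the
collapsed ion occupies.

This is a desk-scale model of in-vacuo dynamics: it answers at the CCS level
(does the ion compact, how tightly, how does charge oppose collapse), not at
the level of atomic detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from ._md_kernels import run_langevin
from .ccs import CCSResult, CollisionRadiiTable, final_window_stats, pa_from_arrays
from .structure import AntibodyTopology, Structure

__all__ = [
    "KB",
    "COULOMB_CONSTANT",
    "ChargeAssignment",
    "ForceFieldParams",
    "CollapseTrajectory",
    "SimulationError",
    "assign_charges",
    "simulate_collapse",
    "replicate_collapse",
]

KB = 8.31446261815324e-3  # kJ/mol/K
COULOMB_CONSTANT = 1389.35  # kJ A / mol / e^2
_BEAD_MASS = 110.0  # Da, average residue

_BASIC_TIPS = {"ARG": ("NH1", "NH2", "CZ"), "LYS": ("NZ",), "HIS": ("NE2", "ND1")}


class SimulationError(RuntimeError):
    """Raised on numerical blow-up during integration."""


@dataclass(frozen=True)
class ChargeAssignment:
    """Unit charges on atom indices of the source structure."""

    site_charges: dict[int, int]
    net_charge: int

    def __post_init__(self) -> None:
        if sum(self.site_charges.values()) != self.net_charge:
            raise ValueError("site charges do not sum to net_charge")


@dataclass(frozen=True)
class ForceFieldParams:
    """Coarse-grained vacuum force field and integrator settings.

    Units: energy kJ/mol, length A, time ps, temperature K, mass Da.
    ``dt`` = 0.01 ps (10 fs); the default 200 000 steps integrate 2 ns of
    coarse-grained dynamics, enough for the standard fixture to reach its
    collapsed plateau at the experimental charge state.  ``lj_epsilon`` /
    ``lj_sigma`` parameterise the residue-scale 6-3 cohesion well (depth at
    r = sigma) acting between different bodies.
    """

    bond_k: float = 500.0
    bond_r0: float = 3.8
    elastic_network_cutoff: float = 8.0
    elastic_k: float = 50.0
    lj_epsilon: float = 25.0
    lj_sigma: float = 6.0
    lj_cutoff: float = 30.0
    coulomb_constant: float = COULOMB_CONSTANT
    dielectric: float = 1.0
    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 0.01
    n_steps: int = 200000
    seed: int = 0
    force_cap: float = 2000.0

    def __post_init__(self) -> None:
        for name in (
            "bond_k", "bond_r0", "elastic_network_cutoff", "elastic_k",
            "lj_epsilon", "lj_sigma", "lj_cutoff", "coulomb_constant",
            "dielectric", "temperature", "friction", "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass
class CollapseTrajectory:
    """Strided frames with per-frame CCS and final-window statistics."""

    frames: list[Structure]
    ccs_series: list[CCSResult]
    final_ccs: float
    final_window_range: float
    net_charge: int
    seed: int

    def __post_init__(self) -> None:
        if self.final_ccs != self.ccs_series[-1].ccs:
            raise ValueError("final_ccs must equal the last CCS in the series")
        if self.final_window_range < 0:
            raise ValueError("final_window_range must be >= 0")


# ---------------------------------------------------------------------------
# Charging
# ---------------------------------------------------------------------------

def assign_charges(
    structure: Structure,
    topology: AntibodyTopology,
    net_charge: int,
    rule: str = "surface_spread",
    neighbour_cutoff: float = 10.0,
    exposure_quantile: float = 0.5,
) -> ChargeAssignment:
    """Place ``net_charge`` unit protons on exposed sites, spread apart.

    ``surface_spread`` takes solvent exposure as a neighbour-count proxy
    (atoms with at most the ``exposure_quantile`` neighbour count within
    ``neighbour_cutoff`` are eligible) and places charges by greedy
    farthest-point selection: the first site is the eligible atom farthest
    from the centroid, each next site maximises its minimum distance to the
    sites already chosen (ties: lowest atom index).  ``basic_residues``
    restricts eligibility to Arg/Lys/His side-chain tips first.  Deterministic
    for a given structure.
    """
    if net_charge < 0:
        raise ValueError("net_charge must be >= 0")
    if net_charge == 0:
        return ChargeAssignment({}, 0)
    coords = structure.coord
    if rule == "surface_spread":
        tree = cKDTree(coords)
        counts = np.array([len(tree.query_ball_point(c, neighbour_cutoff)) - 1 for c in coords])
        eligible = np.flatnonzero(counts <= np.quantile(counts, exposure_quantile))
    elif rule == "basic_residues":
        mask = np.zeros(len(structure), dtype=bool)
        for res, names in _BASIC_TIPS.items():
            mask |= (structure.res_name == res) & np.isin(structure.name, names)
        if not mask.any():  # coarse structures: fall back to all beads of basic residues
            mask = np.isin(structure.res_name, list(_BASIC_TIPS))
        eligible = np.flatnonzero(mask)
    else:
        raise ValueError(f"unknown charging rule {rule!r}")
    if net_charge > len(eligible):
        raise ValueError(
            f"net_charge {net_charge} exceeds {len(eligible)} eligible sites under rule {rule!r}"
        )
    centroid = coords.mean(axis=0)
    chosen = [int(eligible[np.argmax(np.linalg.norm(coords[eligible] - centroid, axis=1))])]
    while len(chosen) < net_charge:
        remaining = np.array([i for i in eligible if i not in chosen])
        dmin = np.min(
            np.linalg.norm(coords[remaining][:, None, :] - coords[chosen][None, :, :], axis=-1),
            axis=1,
        )
        chosen.append(int(remaining[np.argmax(dmin)]))
    return ChargeAssignment({i: 1 for i in chosen}, net_charge)


# ---------------------------------------------------------------------------
# Coarse-graining helpers
# ---------------------------------------------------------------------------

def _bead_model(structure: Structure, topology: AntibodyTopology):
    """One bead per residue: the CA atom when present, else the first atom."""
    keys = structure.residue_keys()
    bead_atom = []
    for chain, res, ins in keys:
        mask = (
            (structure.chain_id == chain)
            & (structure.res_id == res)
            & (structure.ins_code == ins)
        )
        idx = np.flatnonzero(mask & (structure.name == "CA"))
        if len(idx) == 0:
            idx = np.flatnonzero(mask)
        bead_atom.append(int(idx[0]))
    bead_atom = np.array(bead_atom)
    beads = structure.select(bead_atom)
    atom_to_bead = {}
    key_to_bead = {k: b for b, k in enumerate(keys)}
    for a in range(len(structure)):
        k = (str(structure.chain_id[a]), int(structure.res_id[a]), str(structure.ins_code[a]))
        atom_to_bead[a] = key_to_bead[k]
    return beads, bead_atom, atom_to_bead, keys


def _body_ids(beads: Structure, topology: AntibodyTopology) -> np.ndarray:
    body = np.full(len(beads), -1)
    for b, name in enumerate(["Fab1", "Fab2", "Fc_core"]):
        body[beads.residue_mask(topology.rigid_bodies.get(name, []))] = b
    return body


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_collapse(
    structure: Structure,
    topology: AntibodyTopology,
    charges: ChargeAssignment,
    ff: ForceFieldParams | None = None,
    radii: CollisionRadiiTable | None = None,
    report_stride: int = 1000,
    ccs_orientations: int = 60,
    ccs_points: int = 2500,
) -> CollapseTrajectory:
    """Langevin vacuum collapse of one charged conformer.

    CCS is evaluated every ``report_stride`` steps with a shared orientation
    set so the series reflects structural change; ``final_window_range`` is
    the CCS max - min over the final 10 % of reported frames.  Deterministic
    for a fixed ``ff.seed``.

    Raises
    ------
    SimulationError
        If any coordinate becomes non-finite (suggests a smaller ``dt``).
    """
    ff = ff or ForceFieldParams()
    radii = radii or CollisionRadiiTable.default()
    beads, bead_atom, atom_to_bead, keys = _bead_model(structure, topology)
    n = len(beads)
    body = _body_ids(beads, topology)

    # chain bonds between consecutive residues of one chain
    bond_i, bond_j, bond_r0 = [], [], []
    for a, b in zip(range(n - 1), range(1, n)):
        if beads.chain_id[a] != beads.chain_id[b]:
            continue
        d = float(np.linalg.norm(beads.coord[a] - beads.coord[b]))
        if d > 2.5 * ff.bond_r0:  # chain break, not a physical bond
            continue
        bond_i.append(a)
        bond_j.append(b)
        bond_r0.append(d)  # rest length from the input geometry

    # elastic network inside each rigid body
    en_i, en_j, en_r0 = [], [], []
    for bid in range(3):
        members = np.flatnonzero(body == bid)
        if len(members) < 2:
            continue
        tree = cKDTree(beads.coord[members])
        for a, b in tree.query_pairs(ff.elastic_network_cutoff):
            i, j = int(members[a]), int(members[b])
            en_i.append(i)
            en_j.append(j)
            en_r0.append(float(np.linalg.norm(beads.coord[i] - beads.coord[j])))

    # cohesion acts between bodies only: rigid-body interiors are governed by
    # the elastic network, bonded neighbours by the chain bonds
    excl = np.zeros((n, n), dtype=np.bool_)
    for i, j in zip(bond_i, bond_j):
        excl[i, j] = excl[j, i] = True
    for i, j in zip(en_i, en_j):
        excl[i, j] = excl[j, i] = True
    for bid in range(3):
        members = np.flatnonzero(body == bid)
        excl[np.ix_(members, members)] = True

    # charges mapped from atom sites onto their residue beads
    q: dict[int, int] = {}
    for atom, charge in charges.site_charges.items():
        bead = atom_to_bead[atom]
        q[bead] = q.get(bead, 0) + charge
    q_idx = np.array(sorted(q), dtype=np.int64)
    q_val = np.array([float(q[i]) for i in sorted(q)])

    masses = np.full(n, _BEAD_MASS)
    kT = KB * ff.temperature
    frames_arr, status = run_langevin(
        np.ascontiguousarray(beads.coord),
        masses,
        np.array(bond_i, dtype=np.int64),
        np.array(bond_j, dtype=np.int64),
        np.array(bond_r0),
        ff.bond_k,
        np.array(en_i, dtype=np.int64),
        np.array(en_j, dtype=np.int64),
        np.array(en_r0),
        ff.elastic_k,
        excl,
        ff.lj_epsilon,
        ff.lj_sigma,
        ff.lj_cutoff,
        q_idx,
        q_val,
        ff.coulomb_constant / ff.dielectric,
        kT,
        ff.friction,
        ff.dt,
        ff.n_steps,
        report_stride,
        ff.seed % 2**31,
        ff.force_cap,
    )
    if status >= 0:
        raise SimulationError(
            f"non-finite coordinates at step {status}; reduce dt (currently {ff.dt} ps)"
        )

    disk = radii.disk_radii(beads.element)
    frames = [beads.with_coord(f) for f in frames_arr]
    ccs_series = [
        pa_from_arrays(f, disk, n_orientations=ccs_orientations, seed=ff.seed, n_points=ccs_points)
        for f in frames_arr
    ]
    final_ccs, window_range = final_window_stats(ccs_series)
    return CollapseTrajectory(
        frames=frames,
        ccs_series=ccs_series,
        final_ccs=final_ccs,
        final_window_range=window_range,
        net_charge=charges.net_charge,
        seed=ff.seed,
    )


def replicate_collapse(
    conformers: list,
    topology: AntibodyTopology,
    charges: ChargeAssignment | int,
    ff: ForceFieldParams | None = None,
    radii: CollisionRadiiTable | None = None,
    seeds: list[int] | None = None,
    report_stride: int = 1000,
    charge_rule: str = "surface_spread",
) -> tuple[list[CollapseTrajectory], float]:
    """Collapse each selected conformer with its own seed; report the spread.

    ``charges`` may be a ready :class:`ChargeAssignment` (reused for every
    variant) or an integer net charge (re-placed per conformer, since exposed
    surfaces differ between conformers).  The spread is the maximum pairwise
    relative difference of final CCS, |a - b| / mean(a, b).
    """
    from .sampling import Conformer  # local import to avoid cycle

    if len(conformers) == 0:
        raise ValueError("no conformers given")
    ff = ff or ForceFieldParams()
    if seeds is None:
        seeds = [ff.seed + k for k in range(len(conformers))]
    if len(seeds) != len(conformers):
        raise ValueError("need one seed per conformer")
    trajectories = []
    for conf, seed in zip(conformers, seeds):
        struct = conf.structure if isinstance(conf, Conformer) else conf
        assignment = (
            charges
            if isinstance(charges, ChargeAssignment)
            else assign_charges(struct, topology, int(charges), rule=charge_rule)
        )
        trajectories.append(
            simulate_collapse(
                struct,
                topology,
                assignment,
                replace(ff, seed=seed),
                radii,
                report_stride,
            )
        )
    finals = [t.final_ccs for t in trajectories]
    spread = 0.0
    for a, b in combinations(finals, 2):
        m = 0.5 * (a + b)
        if m > 0:
            spread = max(spread, abs(a - b) / m)
    return trajectories, spread
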