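"""Upper-hinge conformational sampling with a rapidly-exploring random tree.

The flexible degrees of freedom are the backbone phi/psi torsions of the
upper-hinge residues (between the Fab domains and the most N-terminal hinge
disulfide).  Rotating about a hinge torsion moves everything on the Fab side
of the bond as one rigid unit — Fab internal geometry and the Fc core are
exactly preserved.  The RRT grows a tree through this torsion space from the
input conformation, which spreads conformers over the reachable space without
any energetic weighting; each accepted (clash-free) node becomes a conformer
scored by projection-approximation CCS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ccs import CCSResult, CollisionRadiiTable, pa_from_arrays
from .structure import AntibodyTopology, Structure

__all__ = [
    "RRTParams",
    "Conformer",
    "Ensemble",
    "EnsembleSummary",
    "HingeKinematics",
    "apply_dihedrals",
    "clash_check",
    "sample_ensemble",
    "select_compact",
    "summarise_ensemble",
]


def wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap angles (degrees) into (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(a, dtype=float), 360.0)


@dataclass(frozen=True)
class RRTParams:
    """Tree-sampler settings.

    ``step_size`` is the per-torsion RMS extension step in degrees: the
    Euclidean step in the full torsion space is ``step_size * sqrt(dim)``, so
    exploration per torsion is comparable across hinges of different lengths.
    ``max_extension_attempts`` multiplies ``n_samples`` into the total
    extension-attempt budget; CCS during sampling uses the reduced
    ``ccs_orientations``/``ccs_points`` settings for speed (selected
    conformers are re-scored at full settings downstream).
    """

    n_samples: int = 10000
    step_size: float = 15.0
    clash_factor: float = 0.7
    max_extension_attempts: int = 50
    seed: int = 0
    ccs_orientations: int = 100
    ccs_points: int = 3000

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 < self.clash_factor <= 1:
            raise ValueError("clash_factor must be in (0, 1]")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


@dataclass
class Conformer:
    """One sampled conformation: torsion offsets, structure, CCS, Fab centroids."""

    dihedrals: np.ndarray
    structure: Structure
    ccs: CCSResult
    fab_centroids: np.ndarray  # (2, 3), Fab1 and Fab2


class Ensemble(list):
    """List of conformers; ``complete`` is False when the attempt budget ran out."""

    complete: bool = True


@dataclass
class EnsembleSummary:
    n: int
    ccs_min: float
    ccs_max: float
    delta_ccs: float
    fab_centroid_cloud: dict[str, np.ndarray]
    overlap_fraction: float


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

# residue-local atom names that ride with the Fab-side fragment of each torsion
_PHI_MOVERS = {"H", "HN", "1H", "2H", "3H"}
_PSI_MOVERS = _PHI_MOVERS | {"N"}


class HingeKinematics:
    """Precomputed torsion axes and moving-atom sets for both arms.

    Torsions are ordered arm1 then arm2; within an arm, residues run from the
    Fab side toward the hinge disulfide, with (phi, psi) per residue — so the
    dihedral vector length is 2 x total flexible residues.  Each torsion k
    stores its axis atom indices (p on the Fab side of the bond, q on the Fc
    side) and the indices of all atoms rigidly moved by it.
    """

    def __init__(self, structure: Structure, topology: AntibodyTopology):
        self.topology = topology
        self.axes: list[tuple[int, int]] = []
        self.moving: list[np.ndarray] = []
        n = len(structure)

        def atom_index(chain: str, res: int, name: str) -> int:
            hit = np.flatnonzero(
                (structure.chain_id == chain) & (structure.res_id == res) & (structure.name == name)
            )
            if len(hit) != 1:
                raise ValueError(
                    f"flexible residue ({chain},{res}) needs exactly one backbone atom "
                    f"{name!r}, found {len(hit)}"
                )
            return int(hit[0])

        for arm in topology.arm_names:
            residues = topology.flexible_residues[arm]  # Fab side first
            fab_mask = structure.residue_mask(topology.rigid_bodies[topology.body_of_arm(arm)])
            res_masks = [structure.residue_mask([key]) for key in residues]
            for i, (chain, res) in enumerate(residues):
                i_n = atom_index(chain, res, "N")
                i_ca = atom_index(chain, res, "CA")
                i_c = atom_index(chain, res, "C")
                fabward = fab_mask.copy()
                for m in res_masks[:i]:
                    fabward |= m
                res_names = structure.name
                this_res = res_masks[i]
                phi_moving = fabward | (this_res & np.isin(res_names, list(_PHI_MOVERS)))
                psi_moving = fabward | (this_res & np.isin(res_names, list(_PSI_MOVERS)))
                # phi: axis through CA-N, Fab-ward fragment rotates
                self.axes.append((i_n, i_ca))
                self.moving.append(np.flatnonzero(phi_moving))
                # psi: axis through C-CA
                self.axes.append((i_ca, i_c))
                self.moving.append(np.flatnonzero(psi_moving))
        self.n_torsions = len(self.axes)
        self.n_atoms = n

    def apply(self, coord: np.ndarray, deltas: np.ndarray) -> np.ndarray:
        """Rotate each torsion's Fab-ward fragment by its delta (degrees).

        Torsions are applied hinge-most first so that every rotation uses the
        current axis positions; the result is the conformation whose internal
        torsions each changed by exactly the requested delta.
        """
        deltas = np.asarray(deltas, dtype=float)
        if deltas.shape != (self.n_torsions,):
            raise ValueError(f"expected {self.n_torsions} dihedral deltas, got {deltas.shape}")
        out = np.array(coord, dtype=float)
        for k in range(self.n_torsions - 1, -1, -1):
            d = deltas[k]
            if d == 0.0:
                continue
            p, q = self.axes[k]
            axis = out[p] - out[q]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            axis /= norm
            theta = np.deg2rad(d)
            c, s = np.cos(theta), np.sin(theta)
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + s * K + (1 - c) * (K @ K)
            idx = self.moving[k]
            out[idx] = (out[idx] - out[q]) @ R.T + out[q]
        return out


def apply_dihedrals(
    structure: Structure, topology: AntibodyTopology, dihedrals: np.ndarray
) -> Structure:
    """Rotate the upper-hinge torsions by the given increments (degrees).

    ``dihedrals`` is a change vector — all zeros returns an identical
    structure, and applying a vector followed by its negation restores the
    original coordinates.
    """
    kin = HingeKinematics(structure, topology)
    return structure.with_coord(kin.apply(structure.coord, dihedrals))


# ---------------------------------------------------------------------------
# Clash detection
# ---------------------------------------------------------------------------

def _clash_groups(structure: Structure, topology: AntibodyTopology) -> np.ndarray:
    group = np.full(len(structure), 0)
    for g, name in enumerate(["Fab1", "Fab2", "Fc_core"], start=1):
        group[structure.residue_mask(topology.rigid_bodies.get(name, []))] = g
    for g, arm in enumerate(topology.arm_names, start=4):
        group[structure.residue_mask(topology.flexible_residues[arm])] = g
    return group


def _exempt(structure: Structure, topology: AntibodyTopology, group: np.ndarray, i: int, j: int) -> bool:
    if group[i] == group[j]:
        return True
    # bonded neighbours across a group boundary: sequence-adjacent residues
    if structure.chain_id[i] == structure.chain_id[j] and abs(
        int(structure.res_id[i]) - int(structure.res_id[j])
    ) <= 1:
        return True
    # disulfide-bonded residue pairs
    ri = (str(structure.chain_id[i]), int(structure.res_id[i]))
    rj = (str(structure.chain_id[j]), int(structure.res_id[j]))
    for b in topology.disulfides:
        if {ri, rj} == {b.cys_a, b.cys_b}:
            return True
    return False


def clash_check(
    structure: Structure,
    radii: CollisionRadiiTable,
    clash_factor: float = 0.7,
    rigid_partition: AntibodyTopology | None = None,
) -> bool:
    """True iff any inter-body atom pair is closer than clash_factor x (r_i + r_j).

    Pairs within the same rigid body or flexible segment, sequence-adjacent
    residues on one chain, and disulfide-bonded residue pairs are exempt.
    Candidate pairs come from a k-d tree at the maximal clash distance.
    """
    if rigid_partition is None:
        raise ValueError("rigid_partition topology is required")
    r = radii.element_radii(structure.element)
    group = _clash_groups(structure, rigid_partition)
    max_d = clash_factor * 2.0 * float(r.max())
    tree = cKDTree(structure.coord)
    for i, j in tree.query_pairs(max_d):
        d = np.linalg.norm(structure.coord[i] - structure.coord[j])
        if d < clash_factor * (r[i] + r[j]) and not _exempt(
            structure, rigid_partition, group, i, j
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# RRT sampling
# ---------------------------------------------------------------------------

def _fab_centroids(structure: Structure, topology: AntibodyTopology) -> np.ndarray:
    return np.array(
        [
            structure.coord[structure.residue_mask(topology.rigid_bodies[b])].mean(axis=0)
            for b in ("Fab1", "Fab2")
        ]
    )


def sample_ensemble(
    structure: Structure,
    topology: AntibodyTopology,
    params: RRTParams,
    radii: CollisionRadiiTable | None = None,
) -> Ensemble:
    """Grow an RRT through hinge-torsion space and return accepted conformers.

    Tree nodes are absolute torsion-offset vectors from the input
    conformation (the root, offset zero, is the first conformer).  Each
    iteration draws a uniform random target vector, finds the nearest node
    under the wrapped-Euclidean metric (ties: lowest node index), steps toward
    the target by at most ``step_size`` degrees, and accepts the new node iff
    the realised structure is clash-free.  Deterministic for a fixed seed.

    Returns an :class:`Ensemble` of ``n_samples`` conformers (including the
    root); if the extension-attempt budget runs out first, the partial
    ensemble is returned with ``complete = False`` and a warning.
    """
    radii = radii or CollisionRadiiTable.default()
    kin = HingeKinematics(structure, topology)
    dim = kin.n_torsions
    clash_r = radii.element_radii(structure.element)
    group = _clash_groups(structure, topology)
    max_d = params.clash_factor * 2.0 * float(clash_r.max())

    def is_clashing(coord: np.ndarray) -> bool:
        tree = cKDTree(coord)
        for i, j in tree.query_pairs(max_d):
            d = float(np.linalg.norm(coord[i] - coord[j]))
            if d < params.clash_factor * (clash_r[i] + clash_r[j]) and not _exempt(
                structure, topology, group, i, j
            ):
                return True
        return False

    def score(coord: np.ndarray) -> CCSResult:
        return pa_from_arrays(
            coord,
            radii.disk_radii(structure.element),
            n_orientations=params.ccs_orientations,
            seed=params.seed,
            n_points=params.ccs_points,
        )

    root_struct = structure.copy()
    ensemble = Ensemble()
    ensemble.append(
        Conformer(
            dihedrals=np.zeros(dim),
            structure=root_struct,
            ccs=score(structure.coord),
            fab_centroids=_fab_centroids(structure, topology),
        )
    )
    if dim == 0 or params.n_samples == 1:
        return ensemble

    rng = np.random.default_rng(params.seed)
    nodes = np.zeros((1, dim))
    budget = params.max_extension_attempts * params.n_samples
    step_norm = params.step_size * np.sqrt(dim)
    attempts = 0
    while len(ensemble) < params.n_samples and attempts < budget:
        attempts += 1
        target = rng.uniform(-180.0, 180.0, size=dim)
        diff = wrap_angles(target[None, :] - nodes)
        dist = np.linalg.norm(diff, axis=1)
        nearest = int(np.argmin(dist))  # argmin takes the lowest index on ties
        d = dist[nearest]
        if d < 1e-12:
            continue
        step = diff[nearest] * min(1.0, step_norm / d)
        candidate = wrap_angles(nodes[nearest] + step)
        coord = kin.apply(structure.coord, candidate)
        if is_clashing(coord):
            continue
        nodes = np.vstack([nodes, candidate])
        conf_struct = structure.with_coord(coord)
        ensemble.append(
            Conformer(
                dihedrals=candidate.copy(),
                structure=conf_struct,
                ccs=score(coord),
                fab_centroids=_fab_centroids(conf_struct, topology),
            )
        )
    if len(ensemble) < params.n_samples:
        ensemble.complete = False
        warnings.warn(
            f"RRT attempt budget exhausted: {len(ensemble)}/{params.n_samples} conformers",
            stacklevel=2,
        )
    return ensemble


# ---------------------------------------------------------------------------
# Selection and summary
# ---------------------------------------------------------------------------

def _backbone_coord(structure: Structure) -> np.ndarray:
    mask = structure.name == "CA"
    return structure.coord[mask] if mask.any() else structure.coord


def select_compact(
    ensemble: list[Conformer], k: int, diversity_rmsd: float = 5.0
) -> list[Conformer]:
    """Pick the lowest-CCS conformer plus further low-CCS, mutually distinct ones.

    After the global CCS minimum, each subsequent pick is the next-lowest-CCS
    conformer whose backbone RMSD (no superposition — conformers share the
    fixed Fc frame) to every already-selected conformer exceeds
    ``diversity_rmsd``; if no candidate is left the constraint is relaxed with
    a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    if k > len(ensemble):
        raise ValueError(f"k={k} exceeds ensemble size {len(ensemble)}")
    order = sorted(range(len(ensemble)), key=lambda i: ensemble[i].ccs.ccs)
    coords = [_backbone_coord(ensemble[i].structure) for i in range(len(ensemble))]
    selected = [order[0]]
    relaxed = False
    while len(selected) < k:
        pick = None
        for i in order:
            if i in selected:
                continue
            rmsds = [
                float(np.sqrt(np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1))))
                for j in selected
            ]
            if min(rmsds) > diversity_rmsd:
                pick = i
                break
        if pick is None:
            relaxed = True
            pick = next(i for i in order if i not in selected)
        selected.append(pick)
    if relaxed:
        warnings.warn("diversity constraint relaxed: too few distinct low-CCS conformers", stacklevel=2)
    return [ensemble[i] for i in selected]


def summarise_ensemble(ensemble: list[Conformer], voxel_size: float | None = None) -> EnsembleSummary:
    """Ensemble CCS range and per-arm Fab-centroid clouds with overlap fraction.

    The overlap fraction voxelises both centroid clouds on a common grid and
    reports |occupied by both| / |occupied by either| (Jaccard).  By default
    the voxel edge adapts to the sampling density
    (``2.5 x cloud RMS extent / n**(1/3)``, floor 2 A) so the fraction
    measures shared region, not point coincidence; for single-conformer
    clouds it degenerates to 1 if the two centroids share a voxel, else 0.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    ccs = np.array([c.ccs.ccs for c in ensemble])
    clouds = {
        "arm1": np.array([c.fab_centroids[0] for c in ensemble]),
        "arm2": np.array([c.fab_centroids[1] for c in ensemble]),
    }
    if voxel_size is None:
        extent = float(np.linalg.norm(np.vstack(list(clouds.values())).std(axis=0)))
        voxel_size = max(2.0, 2.5 * extent / len(ensemble) ** (1.0 / 3.0))
    vox = {
        arm: {tuple(v) for v in np.floor(cloud / voxel_size).astype(int)}
        for arm, cloud in clouds.items()
    }
    union = vox["arm1"] | vox["arm2"]
    inter = vox["arm1"] & vox["arm2"]
    return EnsembleSummary(
        n=len(ensemble),
        ccs_min=float(ccs.min()),
        ccs_max=float(ccs.max()),
        delta_ccs=float(ccs.max() - ccs.min()),
        fab_centroid_cloud=clouds,
        overlap_fraction=len(inter) / len(union) if union else 0.0,
    )
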