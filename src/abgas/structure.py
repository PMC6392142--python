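"""Structure container, PDB I/O, disulfide detection and antibody partitioning.

The :class:`Structure` class is the currency passed between every stage of the
workflow: a flat, ordered collection of atoms (or coarse-grained beads) with
element, coordinates in Angstrom, and residue/chain identity.  PDB parsing and
writing are delegated to :mod:`biotite`; this module adds the dialect rules the
workflow relies on (altloc filtering, HETATM flagging, serial bookkeeping) and
the antibody-specific topology operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "AtomRecord",
    "Structure",
    "DisulfideBond",
    "AntibodyTopology",
    "FormatError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "detect_disulfides",
    "partition_antibody",
]


class FormatError(ValueError):
    """Raised for malformed or empty structure files."""


class TopologyError(ValueError):
    """Raised when an antibody partition cannot be derived."""


class AtomRecord(NamedTuple):
    """A single atom: plain view used for iteration and construction."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: tuple[float, float, float]
    ins_code: str = ""
    hetero: bool = False


@dataclass
class Structure:
    """Ordered atom collection backed by parallel numpy arrays.

    Parameters
    ----------
    serial, name, element, res_name, res_id, chain_id, coord
        Parallel arrays, one entry per atom. ``coord`` has shape ``(n, 3)``
        in Angstrom.
    ins_code, hetero
        Optional per-atom insertion codes and HETATM flags.
    metadata
        Free-form provenance (title, source id, fixture parameters).
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    ins_code: np.ndarray | None = None
    hetero: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.serial)
        if n == 0:
            raise FormatError("a Structure must contain at least one atom")
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (n, 3):
            raise ValueError(f"coord shape {self.coord.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        if len(np.unique(self.serial)) != n:
            raise ValueError("atom serials are not unique")
        if self.ins_code is None:
            self.ins_code = np.full(n, "", dtype="U1")
        if self.hetero is None:
            self.hetero = np.zeros(n, dtype=bool)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[AtomRecord], metadata: dict | None = None) -> "Structure":
        recs = list(records)
        return cls(
            serial=np.array([r.serial for r in recs], dtype=int),
            name=np.array([r.name for r in recs], dtype="U6"),
            element=np.array([r.element for r in recs], dtype="U4"),
            res_name=np.array([r.residue_name for r in recs], dtype="U5"),
            res_id=np.array([r.residue_seq for r in recs], dtype=int),
            chain_id=np.array([r.chain_id for r in recs], dtype="U4"),
            coord=np.array([r.position for r in recs], dtype=float),
            ins_code=np.array([r.ins_code for r in recs], dtype="U1"),
            hetero=np.array([r.hetero for r in recs], dtype=bool),
            metadata=dict(metadata or {}),
        )

    # -- basic protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    def __iter__(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield self.atom(i)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            residue_name=str(self.res_name[i]),
            residue_seq=int(self.res_id[i]),
            chain_id=str(self.chain_id[i]),
            position=tuple(float(x) for x in self.coord[i]),
            ins_code=str(self.ins_code[i]),
            hetero=bool(self.hetero[i]),
        )

    def copy(self) -> "Structure":
        return Structure(
            serial=self.serial.copy(),
            name=self.name.copy(),
            element=self.element.copy(),
            res_name=self.res_name.copy(),
            res_id=self.res_id.copy(),
            chain_id=self.chain_id.copy(),
            coord=self.coord.copy(),
            ins_code=self.ins_code.copy(),
            hetero=self.hetero.copy(),
            metadata=dict(self.metadata),
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        s = self.copy()
        s.coord = np.asarray(coord, dtype=float).reshape(len(self), 3)
        return s

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            serial=self.serial[mask],
            name=self.name[mask],
            element=self.element[mask],
            res_name=self.res_name[mask],
            res_id=self.res_id[mask],
            chain_id=self.chain_id[mask],
            coord=self.coord[mask],
            ins_code=self.ins_code[mask],
            hetero=self.hetero[mask],
            metadata=dict(self.metadata),
        )

    # -- residue helpers -------------------------------------------------
    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_id, ins_code) keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def residue_mask(self, keys: Sequence[tuple[str, int] | tuple[str, int, str]]) -> np.ndarray:
        wanted = {(k[0], k[1], k[2] if len(k) > 2 else "") for k in keys}
        return np.array(
            [
                (str(c), int(r), str(i)) in wanted
                for c, r, i in zip(self.chain_id, self.res_id, self.ins_code)
            ],
            dtype=bool,
        )

    # -- biotite bridge --------------------------------------------------
    def to_atom_array(self) -> bst.AtomArray:
        arr = bst.AtomArray(len(self))
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_id.astype(int)
        arr.ins_code = self.ins_code.astype("U1")
        arr.res_name = self.res_name.astype("U5")
        arr.atom_name = self.name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = self.hetero.astype(bool)
        arr.set_annotation("atom_id", self.serial.astype(int))
        return arr

    @classmethod
    def from_atom_array(cls, arr: bst.AtomArray, metadata: dict | None = None) -> "Structure":
        n = arr.array_length()
        serial = (
            np.asarray(arr.atom_id, dtype=int)
            if "atom_id" in arr.get_annotation_categories()
            else np.arange(1, n + 1)
        )
        return cls(
            serial=serial,
            name=np.asarray(arr.atom_name, dtype="U6"),
            element=np.asarray(arr.element, dtype="U4"),
            res_name=np.asarray(arr.res_name, dtype="U5"),
            res_id=np.asarray(arr.res_id, dtype=int),
            chain_id=np.asarray(arr.chain_id, dtype="U4"),
            coord=np.asarray(arr.coord, dtype=float),
            ins_code=np.asarray(arr.ins_code, dtype="U1")
            if "ins_code" in arr.get_annotation_categories()
            else None,
            hetero=np.asarray(arr.hetero, dtype=bool),
            metadata=dict(metadata or {}),
        )


@dataclass(frozen=True)
class DisulfideBond:
    """One S-S bond between two cysteines, identified by (chain, residue)."""

    cys_a: tuple[str, int]
    cys_b: tuple[str, int]
    sg_distance: float

    def __post_init__(self) -> None:
        if self.cys_a == self.cys_b:
            raise ValueError("disulfide endpoints must differ")


@dataclass
class AntibodyTopology:
    """Partition of an antibody into rigid bodies and flexible hinge residues.

    ``rigid_bodies`` maps the three rigid units (``Fab1``, ``Fab2``,
    ``Fc_core``) to residue-key lists; ``flexible_residues`` holds the
    per-arm ordered upper-hinge residues, N-terminal (Fab side) first.
    """

    rigid_bodies: dict[str, list[tuple[str, int]]]
    flexible_residues: dict[str, list[tuple[str, int]]]
    disulfides: list[DisulfideBond] = field(default_factory=list)
    unassigned: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = {k: set(map(tuple, v)) for k, v in self.rigid_bodies.items()}
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if sets[a] & sets[b]:
                    raise TopologyError(f"rigid bodies {a} and {b} overlap")
        rigid_all = set().union(*sets.values()) if sets else set()
        for arm, residues in self.flexible_residues.items():
            overlap = rigid_all & set(map(tuple, residues))
            if overlap:
                raise TopologyError(f"flexible residues of {arm} inside a rigid body: {sorted(overlap)}")

    @property
    def arm_names(self) -> list[str]:
        return sorted(self.flexible_residues)

    def n_flexible(self) -> int:
        return sum(len(v) for v in self.flexible_residues.values())

    def body_of_arm(self, arm: str) -> str:
        """Rigid Fab body moved by a given arm's hinge (``arm1`` -> ``Fab1``)."""
        return {"arm1": "Fab1", "arm2": "Fab2"}[arm]

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "rigid_bodies": {k: [list(t) for t in v] for k, v in self.rigid_bodies.items()},
                "flexible_residues": {k: [list(t) for t in v] for k, v in self.flexible_residues.items()},
                "disulfides": [
                    {"cys_a": list(b.cys_a), "cys_b": list(b.cys_b), "sg_distance": b.sg_distance}
                    for b in self.disulfides
                ],
                "unassigned": [list(t) for t in self.unassigned],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "AntibodyTopology":
        d = json.loads(text)
        return cls(
            rigid_bodies={k: [(c, int(r)) for c, r in v] for k, v in d["rigid_bodies"].items()},
            flexible_residues={k: [(c, int(r)) for c, r in v] for k, v in d["flexible_residues"].items()},
            disulfides=[
                DisulfideBond((b["cys_a"][0], int(b["cys_a"][1])), (b["cys_b"][0], int(b["cys_b"][1])), float(b["sg_distance"]))
                for b in d.get("disulfides", [])
            ],
            unassigned=[(c, int(r)) for c, r in d.get("unassigned", [])],
        )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Dialect: for atoms with alternate locations only the blank or ``'A'``
    altloc is retained; HETATM records are kept and flagged both per atom and
    in ``metadata['has_hetatm']``.

    Raises
    ------
    FormatError
        If the file contains no ATOM/HETATM records.
    OSError
        If the file cannot be read.
    """
    pdb_file = bpdb.PDBFile.read(path)
    try:
        arr = pdb_file.get_structure(model=1, altloc="all", extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises on files without coordinates
        raise FormatError(f"no ATOM/HETATM records parsed from {path!s}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"no ATOM/HETATM records in {path!s}")
    if "altloc_id" in arr.get_annotation_categories():
        keep = np.isin(arr.altloc_id, [".", "", " ", "A"])
        arr = arr[keep]
    if arr.array_length() == 0:
        raise FormatError(f"all atoms filtered out by altloc rule in {path!s}")
    structure = Structure.from_atom_array(arr, metadata={"source": str(path)})
    structure.metadata["has_hetatm"] = bool(structure.hetero.any())
    return structure


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` as PDB (fixed width, 3-decimal coordinates).

    Chain ids longer than one character cannot be represented in the PDB
    column layout and raise a ``ValueError`` naming the offending chain.
    Structures above 99 999 atoms are written with hybrid-36 serials.
    """
    bad = sorted({str(c) for c in structure.chain_id if len(str(c)) > 1})
    if bad:
        raise ValueError(f"chain id(s) {bad} exceed one character; PDB cannot represent them")
    arr = structure.to_atom_array()
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(arr, hybrid36=len(structure) > 99999)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Disulfides
# ---------------------------------------------------------------------------

def detect_disulfides(structure: Structure, cutoff: float = 2.5) -> list[DisulfideBond]:
    """Pair cysteine SG atoms closer than ``cutoff`` (Angstrom).

    Greedy nearest pairing: the globally closest SG-SG pair is bonded first,
    both partners removed, and the scan repeats, so each SG joins at most one
    bond.  The result is independent of atom ordering.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    is_sg = (structure.res_name == "CYS") & (structure.name == "SG")
    idx = np.flatnonzero(is_sg)
    if len(idx) < 2:
        return []
    coords = structure.coord[idx]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    pairs = []
    used = np.zeros(len(idx), dtype=bool)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if i >= j or used[i] or used[j] or d[i, j] > cutoff:
            continue
        used[i] = used[j] = True
        a = (str(structure.chain_id[idx[i]]), int(structure.res_id[idx[i]]))
        b = (str(structure.chain_id[idx[j]]), int(structure.res_id[idx[j]]))
        pairs.append(DisulfideBond(*sorted((a, b)), sg_distance=float(d[i, j])))
    return sorted(pairs, key=lambda b: (b.cys_a, b.cys_b))


# ---------------------------------------------------------------------------
# Antibody partitioning
# ---------------------------------------------------------------------------

def partition_antibody(
    structure: Structure,
    chain_annotation: Mapping[str, str],
    hinge_span: Mapping[str, tuple[int, int]],
    disulfides: Sequence[DisulfideBond] | None = None,
    disulfide_cutoff: float = 2.5,
) -> AntibodyTopology:
    """Partition a 2-heavy / 2-light chain antibody into rigid bodies.

    Parameters
    ----------
    chain_annotation
        Maps chain id to ``"heavy"`` or ``"light"``. Exactly two of each.
    hinge_span
        Per heavy chain, the inclusive ``(first, last)`` residue interval of
        the hinge. The flexible upper hinge is the part of this span strictly
        N-terminal of the most N-terminal hinge disulfide cysteine; everything
        from that cysteine on (C-terminal) joins the Fc core.
    disulfides
        Explicit disulfide list; detected from SG distances when omitted.

    Returns
    -------
    AntibodyTopology
        Rigid bodies ``Fab1``/``Fab2`` (heavy Fab portion plus its nearest
        light chain), ``Fc_core``, and the per-arm flexible residues.
    """
    heavies = sorted(c for c, role in chain_annotation.items() if role == "heavy")
    lights = sorted(c for c, role in chain_annotation.items() if role == "light")
    if len(heavies) != 2 or len(lights) != 2:
        raise TopologyError(
            f"need exactly 2 heavy + 2 light chains, got {len(heavies)} heavy / {len(lights)} light"
        )
    if disulfides is None:
        disulfides = detect_disulfides(structure, cutoff=disulfide_cutoff)

    # Hinge disulfides: bonds with at least one cysteine inside a hinge span.
    def in_span(chain: str, res: int) -> bool:
        span = hinge_span.get(chain)
        return span is not None and span[0] <= res <= span[1]

    anchor: dict[str, int] = {}
    for bond in disulfides:
        for chain, res in (bond.cys_a, bond.cys_b):
            if chain in heavies and in_span(chain, res):
                anchor[chain] = min(anchor.get(chain, res), res)
    missing = [c for c in heavies if c not in anchor]
    if missing:
        raise TopologyError(
            f"no hinge disulfide found on heavy chain(s) {missing}; "
            "pass explicit `disulfides` or widen the hinge span"
        )

    # Pair each light chain with the nearest heavy-chain Fab portion.
    def chain_centroid(chain: str, res_lo: int | None = None, res_hi: int | None = None) -> np.ndarray:
        mask = structure.chain_id == chain
        if res_lo is not None:
            mask &= structure.res_id >= res_lo
        if res_hi is not None:
            mask &= structure.res_id <= res_hi
        return structure.coord[mask].mean(axis=0)

    fab_centroids = {h: chain_centroid(h, res_hi=hinge_span[h][0] - 1) for h in heavies}
    pairing: dict[str, str] = {}
    remaining = list(lights)
    for h in heavies:
        dists = [np.linalg.norm(chain_centroid(l) - fab_centroids[h]) for l in remaining]
        best = remaining.pop(int(np.argmin(dists)))
        pairing[h] = best

    rigid_bodies: dict[str, list[tuple[str, int]]] = {"Fab1": [], "Fab2": [], "Fc_core": []}
    flexible: dict[str, list[tuple[str, int]]] = {"arm1": [], "arm2": []}
    assigned: set[tuple[str, int]] = set()
    keys = [(c, r) for c, r, _ in structure.residue_keys()]

    for arm_i, h in enumerate(heavies, start=1):
        span_start = hinge_span[h][0]
        cys = anchor[h]
        fab, arm = f"Fab{arm_i}", f"arm{arm_i}"
        for c, r in keys:
            if (c, r) in assigned:
                continue
            if c == h:
                if r < span_start:
                    rigid_bodies[fab].append((c, r))
                elif r < cys:
                    flexible[arm].append((c, r))
                else:
                    rigid_bodies["Fc_core"].append((c, r))
                assigned.add((c, r))
            elif c == pairing[h]:
                rigid_bodies[fab].append((c, r))
                assigned.add((c, r))
        flexible[arm].sort(key=lambda t: t[1])

    unassigned = [k for k in keys if k not in assigned]
    return AntibodyTopology(
        rigid_bodies=rigid_bodies,
        flexible_residues=flexible,
        disulfides=list(disulfides),
        unassigned=unassigned,
    )
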