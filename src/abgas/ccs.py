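"""Projection-approximation collision cross sections.

The model CCS convention used throughout the package is

    CCS = 1.14 x PA

where PA is the orientation-averaged area of the union of atom-centred disks
(disk radius = element collision radius + probe radius).  The 1.14 scale maps
the bare projection approximation onto experimental nitrogen-gas CCS values
for protein-sized ions and is applied exactly, never refitted.

Two per-orientation area estimators are provided: a Monte-Carlo point sampler
(default) and a grid rasteriser used as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._pa_kernels import pa_areas_grid, pa_areas_mc
from .structure import Structure

__all__ = [
    "CCS_SCALE",
    "DEFAULT_RADII",
    "CollisionRadiiTable",
    "CCSResult",
    "projection_area",
    "pa_to_ccs",
    "ccs_trajectory",
    "final_window_stats",
]

CCS_SCALE = 1.14

#: van der Waals collision radii (Angstrom) for the common protein elements.
DEFAULT_RADII: dict[str, float] = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


@dataclass(frozen=True)
class CollisionRadiiTable:
    """Element -> collision radius mapping plus a probe radius, in Angstrom."""

    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    probe_radius: float = 1.0

    def __post_init__(self) -> None:
        bad = {e: r for e, r in self.radii.items() if not r > 0}
        if bad:
            raise ValueError(f"non-positive radii: {bad}")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")

    @classmethod
    def default(cls, probe_radius: float = 1.0) -> "CollisionRadiiTable":
        return cls(dict(DEFAULT_RADII), probe_radius)

    def with_element(self, element: str, radius: float) -> "CollisionRadiiTable":
        radii = dict(self.radii)
        radii[element] = radius
        return replace(self, radii=radii)

    def element_radii(self, elements: Sequence[str]) -> np.ndarray:
        """Bare element radii (no probe) for an element array."""
        unknown = sorted({e for e in elements if e not in self.radii})
        if unknown:
            raise KeyError(f"no collision radius for element(s): {unknown}")
        return np.array([self.radii[e] for e in elements], dtype=float)

    def disk_radii(self, elements: Sequence[str]) -> np.ndarray:
        """Projection-disk radii: element radius + probe radius."""
        return self.element_radii(elements) + self.probe_radius


@dataclass(frozen=True)
class CCSResult:
    """Projection area and scaled CCS with Monte-Carlo uncertainty (Angstrom^2)."""

    pa_area: float
    ccs: float
    mc_standard_error: float
    n_orientations: int
    seed: int

    def __post_init__(self) -> None:
        if self.ccs != CCS_SCALE * self.pa_area:
            raise ValueError("CCS/PA scale violated")
        if self.mc_standard_error < 0:
            raise ValueError("negative MC standard error")


def _rotation_matrices(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations via normalised 4-normal quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], axis=-1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], axis=-1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=1,
    )


def pa_from_arrays(
    coords: np.ndarray,
    disk_radii: np.ndarray,
    n_orientations: int = 300,
    sampler: str = "monte_carlo",
    seed: int = 0,
    n_points: int = 40000,
    grid_cell: float = 0.5,
) -> CCSResult:
    """Array-level PA/CCS used by every stage (sampling, collapse, trajectories)."""
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    if sampler not in ("monte_carlo", "grid"):
        raise ValueError(f"unknown sampler {sampler!r}")
    coords = np.ascontiguousarray(coords, dtype=float)
    disk_radii = np.ascontiguousarray(disk_radii, dtype=float)
    if coords.shape[0] == 1:
        # one disk: the projection is orientation-independent and analytic
        pa = float(np.pi * disk_radii[0] ** 2)
        return CCSResult(pa, CCS_SCALE * pa, 0.0, n_orientations, seed)
    rng = np.random.default_rng(seed)
    rotmats = np.ascontiguousarray(_rotation_matrices(n_orientations, rng))
    if sampler == "monte_carlo":
        seeds = rng.integers(1, 2**63 - 1, size=n_orientations, dtype=np.uint64)
        areas = pa_areas_mc(coords, disk_radii, rotmats, n_points, seeds)
    else:
        areas = pa_areas_grid(coords, disk_radii, rotmats, grid_cell)
    pa = float(np.mean(areas))
    se = float(np.std(areas, ddof=1) / np.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return CCSResult(pa, CCS_SCALE * pa, se, n_orientations, seed)


def projection_area(
    structure: Structure,
    radii: CollisionRadiiTable | None = None,
    n_orientations: int = 300,
    sampler: str = "monte_carlo",
    seed: int = 0,
    n_points: int = 40000,
    grid_cell: float = 0.5,
) -> CCSResult:
    """Orientation-averaged projected area and CCS of a structure.

    Parameters
    ----------
    structure
        Any :class:`~abgas.structure.Structure`; every element must be present
        in the radii table.
    radii
        Collision radii + probe; defaults to the standard vdW set, probe 1 A.
    n_orientations
        Number of uniformly random viewing orientations averaged over.
    sampler
        ``"monte_carlo"`` (point sampling, default) or ``"grid"``
        (rasterisation oracle, cell size ``grid_cell``).
    """
    radii = radii or CollisionRadiiTable.default()
    disk = radii.disk_radii(structure.element)
    return pa_from_arrays(
        structure.coord, disk, n_orientations, sampler, seed, n_points, grid_cell
    )


def pa_to_ccs(pa_area: float) -> float:
    """Scale a projection area to the model CCS convention (x 1.14)."""
    if pa_area < 0:
        raise ValueError("projection area must be non-negative")
    return CCS_SCALE * pa_area


def ccs_trajectory(
    frames: Sequence[Structure],
    radii: CollisionRadiiTable | None = None,
    stride: int = 1,
    n_orientations: int = 300,
    seed: int = 0,
    sampler: str = "monte_carlo",
    n_points: int = 40000,
    shared_seed: bool = True,
) -> list[CCSResult]:
    """CCS per strided frame of a trajectory.

    With ``shared_seed`` (default) every frame reuses the same orientation set
    and sampling stream, so CCS differences along the trajectory reflect
    structural change rather than independent MC noise — identical frames give
    bitwise-identical CCS.
    """
    if len(frames) == 0:
        raise ValueError("empty frame list")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    radii = radii or CollisionRadiiTable.default()
    out = []
    for k, frame in enumerate(frames[::stride]):
        frame_seed = seed if shared_seed else seed + k
        out.append(
            projection_area(
                frame, radii, n_orientations, sampler, frame_seed, n_points
            )
        )
    return out


def final_window_stats(ccs_series: Sequence[CCSResult], window_fraction: float = 0.1) -> tuple[float, float]:
    """Final CCS and the (max - min) CCS range over the final window.

    The window is the final ``window_fraction`` of frames (at least one); it
    generalises a fixed final-time window to trajectories of any length.
    """
    if len(ccs_series) == 0:
        raise ValueError("empty CCS series")
    n_win = max(1, int(round(window_fraction * len(ccs_series))))
    tail = [r.ccs for r in ccs_series[-n_win:]]
    return ccs_series[-1].ccs, max(tail) - min(tail)
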