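"""Experimental-side IM-MS computations.

Mass inference from native charge-state ladders, travelling-wave ion
mobility (TWIMS) CCS calibration via the standard power law
``CCS' = A * t'**B`` on reduced-mass/charge-corrected quantities,
multi-wave-velocity averaging, and model-vs-experiment CCS verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS",
    "NITROGEN_MASS",
    "PeakList",
    "CalibrationFit",
    "CCSMeasurement",
    "ComparisonVerdict",
    "infer_mass",
    "twims_calibrate",
    "apply_calibration",
    "average_over_waves",
    "compare_to_experiment",
]

PROTON_MASS = 1.00728  # Da
NITROGEN_MASS = 28.006  # Da, default drift gas


@dataclass
class PeakList:
    """(m/z, intensity) pairs sorted ascending, with instrument metadata."""

    mz: np.ndarray
    intensity: np.ndarray | None = None
    wave_velocity: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)[order]


@dataclass(frozen=True)
class CalibrationFit:
    """Power-law TWIMS calibration CCS' = A * t'**B."""

    A: float
    B: float
    residual_rms: float
    n_calibrants: int
    gas_mass: float = NITROGEN_MASS
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.n_calibrants < 2:
            raise ValueError("calibration needs >= 2 calibrants")


@dataclass
class CCSMeasurement:
    """Mean CCS over wave velocities with standard deviation (sample, n-1)."""

    mean_ccs: float
    sd: float
    per_wave: dict = field(default_factory=dict)
    charge: int | None = None
    sd_convention: str = "sample"
    single_value: bool = False


@dataclass(frozen=True)
class ComparisonVerdict:
    """Relative model-vs-experiment CCS difference and within-band flag."""

    model_ccs: float
    experimental_ccs: float
    relative_difference: float
    within_band: bool
    band: float
    denominator: str


def infer_mass(
    peaks: PeakList | np.ndarray,
    assumed_consecutive: bool = True,
    max_spread: float = 1e-3,
) -> tuple[float, list[int]]:
    """Protein mass and charge states from a native charge-state ladder.

    Adjacent peaks ``m1 > m2`` are assumed to carry consecutive charges
    ``z`` and ``z+1``; each adjacent pair gives
    ``z = round((m2 - mp) / (m1 - m2))`` with the proton mass ``mp``, and the
    mass is the mean of ``z * (m/z - mp)`` over all peaks.

    Raises
    ------
    ValueError
        For fewer than two peaks, or when per-peak masses disagree by more
        than ``max_spread`` (relative) — an inconsistent ladder.
    """
    if not isinstance(peaks, PeakList):
        peaks = PeakList(np.asarray(peaks))
    mz = peaks.mz[::-1]  # descending: charge increases along the array
    if len(mz) < 2:
        raise ValueError("need at least two peaks to infer mass")
    if not assumed_consecutive:
        raise NotImplementedError("only consecutive charge ladders are supported")
    z0 = (mz[1] - PROTON_MASS) / (mz[0] - mz[1])
    z_top = int(round(z0))
    if z_top < 1:
        raise ValueError(f"implausible charge {z0:.2f} from adjacent peak spacing")
    charges = np.arange(z_top, z_top + len(mz))
    masses = charges * (mz - PROTON_MASS)
    spread = float(masses.max() - masses.min()) / float(np.mean(masses))
    if spread > max_spread:
        per_peak = ", ".join(f"z={z}: {m:.1f}" for z, m in zip(charges, masses))
        raise ValueError(
            f"inconsistent charge ladder (relative mass spread {spread:.2e}): {per_peak}"
        )
    return float(np.mean(masses)), [int(z) for z in charges]


def _corrected(ccs: np.ndarray, mass: np.ndarray, charge: np.ndarray, gas_mass: float) -> np.ndarray:
    mu = mass * gas_mass / (mass + gas_mass)
    return ccs * np.sqrt(mu) / charge


def twims_calibrate(
    calibrants: pd.DataFrame,
    gas_mass: float = NITROGEN_MASS,
    dead_time: float = 0.0,
) -> CalibrationFit:
    """Fit the TWIMS power law to a calibrant table.

    ``calibrants`` needs columns ``ccs`` (reference, Angstrom^2),
    ``drift_time``, ``mass`` (Da) and ``charge``.  Reference CCS values are
    reduced-mass/charge corrected, drift times dead-time corrected, and
    ``ln CCS'`` is fit against ``ln t'`` by least squares.
    ``residual_rms`` is the RMS relative residual in corrected-CCS space.
    """
    if len(calibrants) < 2:
        raise ValueError("calibration needs at least 2 calibrants")
    t = np.asarray(calibrants["drift_time"], dtype=float) - dead_time
    if np.any(t <= 0):
        raise ValueError("non-positive corrected drift times")
    ccs_c = _corrected(
        np.asarray(calibrants["ccs"], dtype=float),
        np.asarray(calibrants["mass"], dtype=float),
        np.asarray(calibrants["charge"], dtype=float),
        gas_mass,
    )
    B, lnA = np.polyfit(np.log(t), np.log(ccs_c), 1)
    A = float(np.exp(lnA))
    pred = A * t**B
    residual_rms = float(np.sqrt(np.mean((pred / ccs_c - 1.0) ** 2)))
    return CalibrationFit(A, float(B), residual_rms, len(calibrants), gas_mass, dead_time)


def apply_calibration(
    fit: CalibrationFit,
    drift_times: np.ndarray | float,
    mass: float,
    charge: int,
) -> np.ndarray | float:
    """CCS values for analyte drift times under a calibration fit.

    Inverse of the corrected-CCS transform: ``A * t'**B`` un-corrected by
    ``charge / sqrt(reduced mass)``.  Vector input maps an arrival-time
    distribution onto a CCS distribution (order-preserving for B > 0).
    """
    t = np.asarray(drift_times, dtype=float) - fit.dead_time
    if np.any(t <= 0):
        raise ValueError("drift time at or below dead time")
    mu = mass * fit.gas_mass / (mass + fit.gas_mass)
    ccs = fit.A * t**fit.B * charge / np.sqrt(mu)
    return float(ccs) if np.isscalar(drift_times) else ccs


def average_over_waves(
    per_wave: dict[float, float] | list[float],
    charge: int | None = None,
) -> CCSMeasurement:
    """Arithmetic mean and sample (n-1) standard deviation across wave velocities."""
    values = np.array(list(per_wave.values()) if isinstance(per_wave, dict) else per_wave, dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one wave-velocity value")
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return CCSMeasurement(
        mean_ccs=float(np.mean(values)),
        sd=sd,
        per_wave=dict(per_wave) if isinstance(per_wave, dict) else {i: v for i, v in enumerate(values)},
        charge=charge,
        single_value=len(values) == 1,
    )


def compare_to_experiment(
    model_ccs: float,
    experiment: CCSMeasurement | float,
    band: float = 0.06,
    denominator: str = "experiment",
) -> ComparisonVerdict:
    """Relative CCS difference (model - experiment) and a within-band flag.

    ``denominator`` selects the convention: ``"experiment"`` divides by the
    experimental mean (used for within-band agreement statements),
    ``"model"`` divides by the model CCS (used when quoting how far an
    uncollapsed model overestimates the measured ion).
    """
    if band <= 0:
        raise ValueError("band must be positive")
    exp_ccs = experiment.mean_ccs if isinstance(experiment, CCSMeasurement) else float(experiment)
    if denominator == "experiment":
        rel = (model_ccs - exp_ccs) / exp_ccs
    elif denominator == "model":
        rel = (model_ccs - exp_ccs) / model_ccs
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return ComparisonVerdict(
        model_ccs=float(model_ccs),
        experimental_ccs=exp_ccs,
        relative_difference=float(rel),
        within_band=bool(abs(rel) <= band),
        band=band,
        denominator=denominator,
    )
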