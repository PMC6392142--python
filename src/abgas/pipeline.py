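"""Four-stage workflow orchestration and reporting.

initial model -> Fab-arm RRT sampling -> compact-conformer selection ->
charged vacuum collapse -> comparison with experimental CCS.  The
:func:`run_workflow` entry point drives the library modules from a single
config mapping and produces a :class:`StageReport`; :func:`make_report`
renders the stage table and percentage reductions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ccs as ccs_mod
from .ccs import CollisionRadiiTable, projection_area
from .collapse import ForceFieldParams, assign_charges, replicate_collapse
from .fixtures import SyntheticAntibodyParams, make_synthetic_antibody
from .imms import CCSMeasurement, ComparisonVerdict, compare_to_experiment
from .sampling import RRTParams, sample_ensemble, select_compact, summarise_ensemble
from .structure import AntibodyTopology, read_pdb, write_pdb

__all__ = ["StageReport", "run_workflow", "make_report"]


@dataclass
class StageReport:
    """Per-stage CCS summary with reductions, verdicts and provenance."""

    initial_ccs: float
    initial_se: float
    sampled_min_ccs: float
    sampling_delta_ccs: float
    n_conformers: int
    overlap_fraction: float
    collapsed_final_ccs: float
    collapsed_window_range: float
    replicate_spread: float
    replicate_finals: list[float]
    reduction_sampling_pct: float
    reduction_collapse_pct: float
    net_charge: int
    verdict: ComparisonVerdict | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, default=float)


def _load_inputs(config: dict):
    if "fixture" in config:
        params = SyntheticAntibodyParams(**config["fixture"])
        structure, topology = make_synthetic_antibody(params)
        radii = params.radii_table(config.get("probe_radius", 1.0))
    else:
        structure = read_pdb(config["structure"])
        topology = AntibodyTopology.from_json(Path(config["topology"]).read_text())
        radii = CollisionRadiiTable.default(config.get("probe_radius", 1.0))
        for element, r in config.get("extra_radii", {}).items():
            radii = radii.with_element(element, r)
    return structure, topology, radii


def run_workflow(config: dict | str | Path, outdir: str | Path | None = None) -> StageReport:
    """Execute the full workflow from a config mapping or YAML path.

    Config sections (all optional except an input): ``fixture`` (synthetic
    antibody parameters) or ``structure``/``topology`` (PDB + topology JSON
    paths); ``ccs`` (orientations/points for final scoring); ``sampler``
    (RRT parameters); ``selection`` (k, diversity_rmsd); ``collapse``
    (force-field overrides, net_charge, replicates); ``experiment``
    (mean CCS, sd, band).  Every stage derives its seed from the top-level
    ``seed`` so the whole report is reproducible bit for bit.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    structure, topology, radii = _load_inputs(config)

    ccs_cfg = config.get("ccs", {})
    n_orient = int(ccs_cfg.get("n_orientations", 300))
    n_points = int(ccs_cfg.get("n_points", 40000))

    initial = projection_area(
        structure, radii, n_orientations=n_orient, seed=seed, n_points=n_points
    )

    sampler_cfg = dict(config.get("sampler", {}))
    sampler_cfg.setdefault("seed", seed + 1)
    params = RRTParams(**sampler_cfg)
    ensemble = sample_ensemble(structure, topology, params, radii)
    summary = summarise_ensemble(ensemble)

    sel_cfg = config.get("selection", {})
    k = int(sel_cfg.get("k", 3))
    k = min(k, len(ensemble))
    selected = select_compact(ensemble, k, float(sel_cfg.get("diversity_rmsd", 5.0)))
    # re-score the selected conformers at full CCS settings
    rescored = [
        projection_area(c.structure, radii, n_orientations=n_orient, seed=seed, n_points=n_points)
        for c in selected
    ]

    col_cfg = dict(config.get("collapse", {}))
    net_charge = int(col_cfg.pop("net_charge", 21))
    n_rep = int(col_cfg.pop("replicates", len(selected)))
    charge_rule = col_cfg.pop("charge_rule", "surface_spread")
    report_stride = int(col_cfg.pop("report_stride", 1000))
    col_cfg.setdefault("seed", seed + 2)
    ff = ForceFieldParams(**col_cfg)
    variants = (selected * n_rep)[:n_rep] if n_rep > len(selected) else selected[:n_rep]
    trajectories, spread = replicate_collapse(
        variants,
        topology,
        net_charge,
        ff,
        radii,
        seeds=[ff.seed + i for i in range(len(variants))],
        report_stride=report_stride,
        charge_rule=charge_rule,
    )
    # stage-level collapsed CCS: the replicate whose final CCS is lowest
    best = min(trajectories, key=lambda t: t.final_ccs)

    sampled_min = min(summary.ccs_min, initial.ccs)
    red1 = 100.0 * (initial.ccs - sampled_min) / initial.ccs
    red2 = 100.0 * (sampled_min - best.final_ccs) / sampled_min

    verdict = None
    if "experiment" in config:
        exp_cfg = config["experiment"]
        measurement = CCSMeasurement(
            mean_ccs=float(exp_cfg["mean_ccs"]), sd=float(exp_cfg.get("sd", 0.0))
        )
        verdict = compare_to_experiment(
            best.final_ccs, measurement, band=float(exp_cfg.get("band", 0.06))
        )

    config_json = json.dumps(config, sort_keys=True, default=str)
    report = StageReport(
        initial_ccs=initial.ccs,
        initial_se=ccs_mod.CCS_SCALE * initial.mc_standard_error,
        sampled_min_ccs=sampled_min,
        sampling_delta_ccs=summary.delta_ccs,
        n_conformers=summary.n,
        overlap_fraction=summary.overlap_fraction,
        collapsed_final_ccs=best.final_ccs,
        collapsed_window_range=best.final_window_range,
        replicate_spread=spread,
        replicate_finals=[t.final_ccs for t in trajectories],
        reduction_sampling_pct=red1,
        reduction_collapse_pct=red2,
        net_charge=net_charge,
        verdict=verdict,
        provenance={
            "seed": seed,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "stage_seeds": {"ccs": seed, "sampler": params.seed, "collapse": ff.seed},
            "n_selected": len(selected),
            "ensemble_complete": bool(getattr(ensemble, "complete", True)),
            "selected_rescored_ccs": [r.ccs for r in rescored],
        },
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(make_report(report)[0])
        manifest = [
            {"conformer": i, "ccs": c.ccs.ccs, "dihedrals": c.dihedrals.tolist()}
            for i, c in enumerate(ensemble)
        ]
        (outdir / "ensemble.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "topology.json").write_text(topology.to_json())
        for i, c in enumerate(selected):
            write_pdb(c.structure, outdir / f"selected_{i}.pdb")
        for i, t in enumerate(trajectories):
            np.savetxt(
                outdir / f"collapse_{i}_ccs.csv",
                np.array([[j, r.ccs] for j, r in enumerate(t.ccs_series)]),
                delimiter=",",
                header="frame,ccs",
                comments="",
            )
            write_pdb(t.frames[-1], outdir / f"collapsed_{i}.pdb")
    return report


def make_report(
    stage: StageReport | None = None,
    *,
    initial_ccs: float | None = None,
    sampled_min_ccs: float | None = None,
    collapsed_final_ccs: float | None = None,
    experimental_ccs: float | None = None,
    band: float = 0.06,
) -> tuple[str, dict]:
    """Render a stage summary as text plus a JSON-ready dict.

    Either pass a :class:`StageReport` or raw stage CCS values.  Reductions
    between consecutive stages are percentages of the earlier stage; the
    final-model verdict is relative to the experimental mean.  Missing stages
    are reported as explicit gaps rather than errors.
    """
    if stage is not None:
        initial_ccs = stage.initial_ccs
        sampled_min_ccs = stage.sampled_min_ccs
        collapsed_final_ccs = stage.collapsed_final_ccs
        if stage.verdict is not None:
            experimental_ccs = stage.verdict.experimental_ccs
            band = stage.verdict.band

    data: dict = {"stages": {}, "reductions_pct": {}, "comparison": None}
    lines = ["Gas-phase modelling stage summary", "=" * 34]

    def stage_line(name: str, value: float | None) -> None:
        data["stages"][name] = value
        lines.append(f"{name:<22s} {'missing' if value is None else f'{value:9.1f} A^2'}")

    stage_line("initial model", initial_ccs)
    stage_line("sampling minimum", sampled_min_ccs)
    stage_line("collapsed final", collapsed_final_ccs)

    if initial_ccs is not None and sampled_min_ccs is not None:
        red1 = 100.0 * (initial_ccs - sampled_min_ccs) / initial_ccs
        data["reductions_pct"]["sampling"] = red1
        lines.append(f"reduction by sampling: {red1:.1f} %")
    if sampled_min_ccs is not None and collapsed_final_ccs is not None:
        red2 = 100.0 * (sampled_min_ccs - collapsed_final_ccs) / sampled_min_ccs
        data["reductions_pct"]["collapse"] = red2
        lines.append(f"reduction by collapse: {red2:.1f} %")
    if experimental_ccs is not None and collapsed_final_ccs is not None:
        verdict = compare_to_experiment(collapsed_final_ccs, experimental_ccs, band=band)
        data["comparison"] = {
            "experimental_ccs": experimental_ccs,
            "relative_difference_pct": 100.0 * verdict.relative_difference,
            "within_band": verdict.within_band,
            "band_pct": 100.0 * band,
        }
        sign = "+" if verdict.relative_difference >= 0 else ""
        lines.append(
            f"final vs experiment:   {sign}{100.0 * verdict.relative_difference:.1f} % "
            f"({'within' if verdict.within_band else 'outside'} +-{100.0 * band:.0f} % band)"
        )
    elif collapsed_final_ccs is not None:
        lines.append("final vs experiment:   no experimental CCS provided")
        data["comparison"] = None
    if stage is not None:
        lines.append(
            f"replicates: finals {[round(v, 1) for v in stage.replicate_finals]}, "
            f"max pairwise spread {100.0 * stage.replicate_spread:.1f} %"
        )
        data["replicates"] = {
            "finals": stage.replicate_finals,
            "spread": stage.replicate_spread,
        }
    return "\n".join(lines) + "\n", data
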