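"""End-to-end screening pipeline: simulate -> segment -> link -> score ->
readouts -> fit -> report.

A :class:`RunConfig` fully defaults to a demo screen (one compound, six
doses x three replicates plus vehicle controls, simulated spheroids of
1,000 cells) and the same config + seed always reproduces byte-identical
output tables. All per-well randomness is derived from the single run
seed, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytometry import (ChannelRoles, ScoreThresholds, ScoringConfigError,
                        estimate_threshold, score_cells, spheroid_readouts)
from .dosestats import classify_outcome, fit_4pl
from .seg2d import SegParams, segment_stack_cytoplasm, segment_stack_nuclei
from .stackio import ImageStack, PlateLayout, write_readouts, write_stack
from .synthgen import (EffectParams, SyntheticConfig, generate_spheroid_truth,
                       render_stack)
from .vol3d import (DEFAULT_CYTO_DISPLACEMENT_UM, DEFAULT_NUCLEI_DISPLACEMENT_UM,
                    connect_by_best_match, find_spherical_object)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and well id."""


@dataclass
class RunConfig:
    """Everything needed to run a (simulated) screen; every field has a
    default and the fully-defaulted config runs end-to-end."""

    outdir: str | Path = "spherotox_run"
    seed: int = 0
    compound_name: str = "demo-compound"
    true_ic50_uM: float = 1.0
    hill: float = 1.0
    doses_uM: tuple = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
    n_replicates: int = 3
    n_controls: int = 3
    n_cells: int = 1000
    synth: dict = field(default_factory=dict)      # SyntheticConfig overrides
    effect: dict = field(default_factory=dict)     # EffectParams overrides
    channel_roles: ChannelRoles = field(default_factory=ChannelRoles)
    nuclei_params: SegParams = field(default_factory=SegParams)
    cyto_params: SegParams = field(
        default_factory=lambda: SegParams(min_diameter_um=4.0, max_diameter_um=60.0)
    )
    nuclei_displacement_um: float = DEFAULT_NUCLEI_DISPLACEMENT_UM
    cyto_displacement_um: float = DEFAULT_CYTO_DISPLACEMENT_UM
    max_gap_planes: int = 0
    # axial size caps for linking, the z analogue of the 2D size window
    nuclei_max_axial_um: float = 15.0
    cyto_max_axial_um: float = 25.0
    dead_threshold: float | None = None  # None -> per-plate estimate
    effect_criterion: float = 0.30
    write_images: bool = False
    find_spheroid: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(data)
        if "channel_roles" in kwargs:
            kwargs["channel_roles"] = ChannelRoles(**kwargs["channel_roles"])
        for key in ("nuclei_params", "cyto_params"):
            if key in kwargs:
                kwargs[key] = SegParams(**kwargs[key])
        if "doses_uM" in kwargs:
            kwargs["doses_uM"] = tuple(kwargs["doses_uM"])
        return cls(**kwargs)

    def base_synth_config(self, seed: int) -> SyntheticConfig:
        return SyntheticConfig(n_cells=self.n_cells, seed=seed, **self.synth)

    def effect_params(self) -> EffectParams:
        kwargs = {"ic50_true_uM": self.true_ic50_uM, "hill": self.hill}
        kwargs.update(self.effect)
        return EffectParams(**kwargs)

    def validate(self) -> None:
        probe = self.base_synth_config(seed=0)
        channels = set(probe.channel_intensity_means)
        roles = self.channel_roles
        needed = {roles.nuclear, roles.live, roles.dead}
        needed |= {c for c in (roles.caspase, roles.mito) if c is not None}
        missing = needed - channels
        if missing:
            raise ScoringConfigError(
                f"channel mapping names {sorted(missing)} not present in "
                f"configured channels {sorted(channels)}"
            )


def build_platemap(config: RunConfig) -> PlateLayout:
    """Dilution-series layout: one treated well per dose x replicate plus
    vehicle-control wells at dose 0."""
    rows = []
    for r in range(config.n_controls):
        rows.append({
            "well_id": f"C{r + 1:02d}", "compound_name": "vehicle",
            "dose_uM": 0.0, "replicate_id": f"r{r + 1}",
            "role": "vehicle_control",
        })
    for di, dose in enumerate(config.doses_uM, start=1):
        for r in range(config.n_replicates):
            rows.append({
                "well_id": f"D{di:02d}R{r + 1}", "compound_name": config.compound_name,
                "dose_uM": float(dose), "replicate_id": f"r{r + 1}",
                "role": "treated",
            })
    return PlateLayout(pd.DataFrame(rows))


def _well_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class WellResult:
    well_id: str
    compound_name: str
    dose_uM: float
    replicate_id: str
    role: str
    nuclei3d: list
    cyto3d: list
    region: object | None
    stack: ImageStack | None = None


def analyze_stack(stack: ImageStack, config: RunConfig) -> tuple[list, list, object]:
    """Segment one stack plane-wise, link nuclei and cytoplasm into 3D
    objects, and detect the spheroid region."""
    roles = config.channel_roles
    nuc_planes = segment_stack_nuclei(stack, roles.nuclear, config.nuclei_params)
    nuclei3d = connect_by_best_match(
        nuc_planes, stack.z_step_um, config.nuclei_displacement_um,
        config.max_gap_planes,
        max_span_planes=math.ceil(config.nuclei_max_axial_um / stack.z_step_um),
    )
    # seed each plane with the linked nuclei whose cell body can reach
    # it, so cytoplasm splits per cell even in planes where the nucleus
    # itself has no section
    reach = config.cyto_max_axial_um / 2.0
    seeds_per_plane = []
    for k in range(stack.n_planes):
        zk = k * stack.z_step_um
        seeds_per_plane.append([
            (n.centroid_um[0], n.centroid_um[1]) for n in nuclei3d
            if abs(n.centroid_um[2] - zk) <= reach
        ])
    cyto_planes = segment_stack_cytoplasm(
        stack, roles.live,
        nuclei_planes=seeds_per_plane,
        params=config.cyto_params,
    )
    cyto3d = connect_by_best_match(
        cyto_planes, stack.z_step_um, config.cyto_displacement_um,
        config.max_gap_planes,
        max_span_planes=math.ceil(config.cyto_max_axial_um / stack.z_step_um),
    )
    region = find_spherical_object(stack, roles.nuclear) if config.find_spheroid else None
    if region is not None:
        # keep summary values only; the voxel mask is bulky
        region.mask = np.zeros((0, 0, 0), dtype=bool)
    return nuclei3d, cyto3d, region


def _dead_threshold(config: RunConfig, pooled_means: Sequence[float]) -> float:
    if config.dead_threshold is not None:
        return config.dead_threshold
    bg = config.base_synth_config(seed=0).background_level
    fallback = bg + 4.0 * math.sqrt(bg + 1.0)
    return estimate_threshold(pooled_means, fallback)


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the full screen; returns paths and summary values.

    Writes ``readouts.csv`` (one row per well), ``fits.csv`` (one row
    per compound), ``platemap.csv``, ``report.json`` and ``run.log``
    under ``config.outdir``; identical config + seed give byte-identical
    CSVs.
    """
    if config is None:
        config = RunConfig()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    layout = build_platemap(config)
    layout.table.to_csv(outdir / "platemap.csv", index=False)
    effect = config.effect_params()
    seeds = _well_seeds(config.seed, len(layout))

    results: list[WellResult] = []
    for (row, wseed) in zip(layout.table.itertuples(index=False), seeds):
        well = row.well_id
        try:
            synth = config.base_synth_config(seed=wseed)
            truth = generate_spheroid_truth(synth, effect, row.dose_uM)
            stack = render_stack(truth, synth, well_id=well)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate' failed for well {well}: {exc}") from exc
        if config.write_images:
            write_stack(stack, outdir / f"{well}.tif")
            truth.write_sidecar(outdir / f"{well}_truth.csv")
            truth.write_metadata(outdir / f"{well}_meta.json")
        try:
            nuclei3d, cyto3d, region = analyze_stack(stack, config)
        except Exception as exc:
            raise PipelineError(f"stage 'segment' failed for well {well}: {exc}") from exc
        results.append(WellResult(
            well_id=well, compound_name=row.compound_name, dose_uM=row.dose_uM,
            replicate_id=row.replicate_id, role=row.role,
            nuclei3d=nuclei3d, cyto3d=cyto3d, region=region,
        ))

    dead_ch = config.channel_roles.dead
    pooled = [n.mean_intensity.get(dead_ch, 0.0)
              for r in results for n in r.nuclei3d]
    thr = _dead_threshold(config, pooled)
    thresholds = ScoreThresholds(dead_mean=thr)

    readouts = []
    for r in results:
        try:
            cells = score_cells(r.nuclei3d, r.cyto3d, thresholds,
                                config.channel_roles,
                                config.cyto_displacement_um)
            readouts.append(spheroid_readouts(
                r.region, cells, well_id=r.well_id, dose_uM=r.dose_uM,
                roles=config.channel_roles, compound_name=r.compound_name,
                replicate_id=r.replicate_id, role=r.role,
            ))
        except Exception as exc:
            raise PipelineError(f"stage 'score' failed for well {r.well_id}: {exc}") from exc

    readout_path = write_readouts(readouts, outdir / "readouts.csv")
    fits_df = fit_compounds(readouts, config)
    fits_path = outdir / "fits.csv"
    fits_df.to_csv(fits_path, index=False, float_format="%.12g")

    report = {
        "version": __version__,
        "seed": config.seed,
        "dead_threshold": thr,
        "n_wells": len(results),
        "compounds": fits_df.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "run.log").write_text(
        f"spherotox {__version__}\nseed={config.seed}\n"
        f"wells={len(results)}\ndead_threshold={thr:.6g}\n"
    )
    return {
        "readouts_csv": readout_path,
        "fits_csv": fits_path,
        "report_json": outdir / "report.json",
        "readouts": readouts,
        "fits": fits_df,
        "dead_threshold": thr,
    }


def fit_compounds(readouts: Sequence, config: RunConfig) -> pd.DataFrame:
    """4PL fit of live-cell counts per compound, with outcome
    classification against the vehicle controls."""
    df = pd.DataFrame([r.as_dict() for r in readouts])
    controls = df[df["role"] == "vehicle_control"]
    rows = []
    for compound, sub in df[df["role"] == "treated"].groupby("compound_name"):
        doses = np.concatenate([controls["dose_uM"], sub["dose_uM"]])
        resp = np.concatenate([controls["n_live"], sub["n_live"]]).astype(float)
        try:
            fit = fit_4pl(doses, resp)
        except Exception as exc:
            raise PipelineError(f"stage 'fit' failed for compound {compound}: {exc}") from exc
        by_dose = {float(d): resp[doses == d].tolist() for d in np.unique(doses)}
        outcome = classify_outcome(fit, by_dose, max_tested_uM=float(doses.max()),
                                   effect_criterion=config.effect_criterion)
        rows.append({
            "compound_name": compound,
            "n_points": fit.n_points,
            "bottom": fit.bottom, "top": fit.top,
            "ic50_uM": fit.ic50_uM, "se_ic50_uM": fit.se_ic50_uM,
            "hill": fit.hill, "se_hill": fit.se_hill,
            "converged": fit.converged, "at_bounds": fit.at_bounds,
            "residual_sd": fit.residual_sd,
            "outcome_kind": outcome.kind,
            "outcome_value_uM": outcome.value_uM,
            "outcome_max_uM": outcome.max_uM,
        })
    return pd.DataFrame(rows)
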