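"""Synthetic liver-spheroid Z-stacks with full ground truth.

The generator emulates the assay geometry of a non-proliferating
hepatocyte spheroid resting on the bottom of a round-bottom
ultra-low-attachment well: ~60-8,000 cells packed in a sphere whose
diameter follows a cube-root law of the cell number (1,000 cells ->
220 μm), imaged from below as a stack of planes (default 11 planes at
10 μm spacing) with an effective imaging-depth limit (default 110 μm)
beyond which dye signal is not recovered.

A compound-effect model (Hill dead-fraction, optional swelling,
detachment, and nuclear condensation) converts a dose into per-cell
live/dead states and dye intensities:

* Hoechst (DAPI channel): every nucleus; brighter for condensed dead nuclei.
* calcein AM (FITC channel): cytoplasm of metabolically active live cells.
* EthD-1 (TexasRed channel): nuclei of membrane-compromised dead cells.
* optional caspase-3/7 and MitoTracker channels via the same machinery.

Every stochastic choice flows from a single seeded generator so a
(config, effect, dose, seed) tuple renders bit-identically.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .stackio import ImageStack

# channel -> which compartment carries the dye
CHANNEL_COMPARTMENTS = {
    "DAPI": "nucleus",
    "TexasRed": "nucleus",
    "Caspase": "nucleus",
    "FITC": "cytoplasm",
    "Mito": "cytoplasm",
}

NOISE_MODELS = ("none", "poisson", "poisson+gaussian")


class GenerationError(RuntimeError):
    """Raised when a valid spheroid cannot be generated from the config."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Geometry, optics, and noise parameters of the simulated assay.

    ``cell_diameter_um`` is the *effective* cell diameter including
    intercellular spacing: at ``packing_fraction`` 1.0 it equals the mean
    center-to-center spacing, and the ground-truth spheroid diameter is
    ``cell_diameter_um * (n_cells / packing_fraction)**(1/3)`` — calibrated
    so that 1,000 cells give a 220 μm spheroid.
    """

    n_cells: int
    nucleus_diameter_um: float = 10.0
    cell_diameter_um: float = 22.0
    packing_fraction: float = 1.0
    channel_intensity_means: Mapping[str, float] = field(
        default_factory=lambda: {"DAPI": 120.0, "FITC": 160.0, "TexasRed": 140.0}
    )
    z_step_um: float = 10.0
    n_planes: int = 11
    pixel_size_um: float = 1.0
    min_center_spacing_um: float | None = None  # None -> 0.6 * cell_diameter
    attenuation_length_um: float = math.inf
    imaging_depth_cutoff_um: float = 110.0
    psf_sigma_um: float = 1.5
    plane_thickness_um: float | None = None  # None -> z_step (optical section)
    noise_model: str = "poisson"
    background_level: float = 5.0
    intensity_cv: float = 0.1  # cell-to-cell lognormal brightness spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise GenerationError("n_cells must be >= 1")
        for name in ("nucleus_diameter_um", "cell_diameter_um", "z_step_um",
                     "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.packing_fraction <= 1.0):
            raise ValueError("packing_fraction must be in (0, 1]")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")

    @property
    def spheroid_radius_um(self) -> float:
        """Calibrated resting radius before any compound effect."""
        return 0.5 * self.cell_diameter_um * (
            self.n_cells / self.packing_fraction
        ) ** (1.0 / 3.0)

    @property
    def cytoplasm_radius_um(self) -> float:
        # cytoplasm sphere kept inside the effective cell territory
        return 0.4 * self.cell_diameter_um

    @property
    def center_spacing_um(self) -> float:
        """Minimum nucleus center-to-center spacing when packing.

        Cells in a confluent aggregate deform but do not interpenetrate,
        so centers keep a floor of ~60% of the effective cell diameter
        (never less than one nucleus diameter, which would overlap
        nuclei outright).
        """
        spacing = (self.min_center_spacing_um
                   if self.min_center_spacing_um is not None
                   else 0.6 * self.cell_diameter_um)
        return max(spacing, self.nucleus_diameter_um)


@dataclass(frozen=True)
class EffectParams:
    """Hill-type compound effect acting on a spheroid.

    ``dead_fraction(dose) = dose^h / (dose^h + ic50^h)``; the remaining
    parameters translate death into the morphological phenotypes seen in
    treated spheroids (radial swelling/loosening, detachment of dead
    cells from the spheroid body, Hoechst condensation of dead nuclei).
    Defaults model a pure viability effect; swelling and detachment are
    compound-specific and switched on explicitly.
    """

    ic50_true_uM: float = 1.0
    hill: float = 1.0
    swelling_per_dead_fraction: float = 0.0
    detach_fraction: float = 0.05
    hoechst_condensation_factor: float = 1.3
    caspase_rate_dead: float = 0.8
    caspase_rate_live: float = 0.05
    mito_intact_rate_live: float = 0.95
    mito_intact_rate_dead: float = 0.1

    def __post_init__(self) -> None:
        if self.ic50_true_uM <= 0:
            raise ValueError("ic50_true_uM must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.swelling_per_dead_fraction < 0:
            raise ValueError("swelling_per_dead_fraction must be >= 0")
        if not (0.0 <= self.detach_fraction <= 1.0):
            raise ValueError("detach_fraction must be in [0, 1]")
        if self.hoechst_condensation_factor < 1.0:
            raise ValueError("hoechst_condensation_factor must be >= 1")

    def dead_fraction(self, dose_uM: float) -> float:
        if dose_uM < 0:
            raise ValueError("dose must be >= 0")
        if dose_uM == 0.0:
            return 0.0
        dh = dose_uM ** self.hill
        return dh / (dh + self.ic50_true_uM ** self.hill)


@dataclass
class GroundTruth:
    """Per-cell ground truth for one simulated spheroid.

    ``cells`` columns: cell_id, x_um/y_um/z_um (stack frame: origin at
    the bottom-left of plane 0, z up from the well bottom),
    nucleus_radius_um, cell_radius_um, state (live/dead), detached,
    caspase_positive, mito_intact, and one ``I_<channel>`` true-intensity
    column per configured channel.
    """

    cells: pd.DataFrame
    spheroid_center_um: tuple[float, float, float]
    spheroid_radius_um: float
    fov_xy_um: float
    dose_uM: float
    dead_fraction_expected: float
    seed: int
    config: SyntheticConfig
    effect: EffectParams

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_dead(self) -> int:
        return int((self.cells["state"] == "dead").sum())

    def write_sidecar(self, path: str | Path) -> Path:
        path = Path(path)
        self.cells.to_csv(path, index=False, float_format="%.6g")
        return path

    def metadata(self) -> dict:
        cfg = {k: (None if isinstance(v, float) and math.isinf(v) else v)
               for k, v in vars(self.config).items()
               if not isinstance(v, Mapping)}
        cfg["channel_intensity_means"] = dict(self.config.channel_intensity_means)
        return {
            "seed": self.seed,
            "dose_uM": self.dose_uM,
            "n_cells": self.n_cells,
            "n_dead": self.n_dead,
            "spheroid_radius_um": self.spheroid_radius_um,
            "spheroid_center_um": list(self.spheroid_center_um),
            "config": cfg,
            "effect": vars(self.effect).copy(),
        }

    def write_metadata(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.metadata(), indent=2))
        return path


# --------------------------------------------------------------------------
# packing


def _pack_sphere(n: int, radius: float, min_sep: float,
                 rng: np.random.Generator, edge_margin: float = 0.0,
                 max_attempts: int = 400) -> np.ndarray:
    """Random sequential placement of n points in a sphere of ``radius``
    (centered at the origin) with pairwise distance >= ``min_sep`` and
    centers at least ``edge_margin`` inside the boundary."""
    if radius <= 0:
        raise GenerationError("spheroid radius must be positive")
    # quick feasibility check: random sequential packing saturates well
    # below the hard-sphere volume fraction
    frac = n * (min_sep / 2.0) ** 3 / radius**3
    if frac > 0.3:
        raise GenerationError(
            f"cannot pack {n} nuclei of exclusion diameter {min_sep:g} um "
            f"into a {2 * radius:g} um spheroid (volume fraction {frac:.2f}); "
            "lower packing_fraction or n_cells"
        )
    cell = min_sep if min_sep > 0 else radius
    grid: dict[tuple[int, int, int], list[int]] = {}
    pts = np.empty((n, 3))
    min_sep2 = min_sep**2
    for i in range(n):
        for _ in range(max_attempts):
            # uniform in the sphere, nucleus kept fully inside
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = (radius - edge_margin) * rng.random() ** (1.0 / 3.0)
            p = v * r
            key = tuple((p // cell).astype(int))
            ok = True
            for dk in np.ndindex(3, 3, 3):
                nb = (key[0] + dk[0] - 1, key[1] + dk[1] - 1, key[2] + dk[2] - 1)
                for j in grid.get(nb, ()):
                    d = pts[j] - p
                    if d @ d < min_sep2:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                pts[i] = p
                grid.setdefault(key, []).append(i)
                break
        else:
            raise GenerationError(
                f"packing failed after {max_attempts} attempts at cell {i}/{n}"
            )
    return pts


def generate_spheroid_truth(
    config: SyntheticConfig,
    effect: EffectParams | None = None,
    dose_uM: float = 0.0,
) -> GroundTruth:
    """Generate per-cell ground truth for one spheroid at one dose.

    Cells are packed without nucleus overlap inside the calibrated
    sphere; a seeded Bernoulli draw at the Hill dead fraction assigns
    states; swelling dilates all centroids radially about the spheroid
    center; a fraction of dead cells detaches just outside the spheroid
    boundary. The random stream is consumed identically at every dose,
    so dose 0 reproduces the untreated draw bit-for-bit.
    """
    if effect is None:
        effect = EffectParams()
    if dose_uM < 0:
        raise ValueError("dose must be >= 0")
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    r_nuc = config.nucleus_diameter_um / 2.0
    radius = config.spheroid_radius_um

    pos = _pack_sphere(n, radius, config.center_spacing_um, rng,
                       edge_margin=r_nuc)

    dead_frac = effect.dead_fraction(dose_uM)
    dead = rng.random(n) < dead_frac
    u_detach = rng.random(n)
    extra_r = rng.uniform(5.0, 25.0, n)
    channels = list(config.channel_intensity_means)
    bright = rng.lognormal(
        mean=-0.5 * config.intensity_cv**2, sigma=config.intensity_cv,
        size=(n, len(channels)),
    )
    u_casp = rng.random(n)
    u_mito = rng.random(n)

    swell = 1.0 + effect.swelling_per_dead_fraction * dead_frac
    pos = pos * swell
    radius_now = radius * swell

    detached = dead & (u_detach < effect.detach_fraction)
    if detached.any():
        norms = np.linalg.norm(pos[detached], axis=1)
        norms[norms == 0] = 1.0
        unit = pos[detached] / norms[:, None]
        pos[detached] = unit * (radius_now + extra_r[detached])[:, None]

    # stack frame: spheroid rests on the well bottom, XY centered in FOV
    margin = 40.0
    fov = 2.0 * (radius_now + margin)
    pos[:, 0] += fov / 2.0
    pos[:, 1] += fov / 2.0
    pos[:, 2] += radius_now
    pos[:, 2] = np.maximum(pos[:, 2], r_nuc)

    caspase_pos = np.where(dead, u_casp < effect.caspase_rate_dead,
                           u_casp < effect.caspase_rate_live)
    mito_intact = np.where(dead, u_mito < effect.mito_intact_rate_dead,
                           u_mito < effect.mito_intact_rate_live)

    df = pd.DataFrame({
        "cell_id": np.arange(n),
        "x_um": pos[:, 0],
        "y_um": pos[:, 1],
        "z_um": pos[:, 2],
        "nucleus_radius_um": np.full(n, r_nuc),
        "cell_radius_um": np.full(n, config.cytoplasm_radius_um),
        "state": np.where(dead, "dead", "live"),
        "detached": detached,
        "caspase_positive": caspase_pos,
        "mito_intact": mito_intact,
    })
    means = config.channel_intensity_means
    for k, ch in enumerate(channels):
        base = means[ch] * bright[:, k]
        if ch == "DAPI":
            inten = base * np.where(dead, effect.hoechst_condensation_factor, 1.0)
        elif ch == "FITC":
            inten = np.where(dead, 0.0, base)
        elif ch == "TexasRed":
            inten = np.where(dead, base, 0.0)
        elif ch == "Caspase":
            inten = np.where(caspase_pos, base, 0.0)
        elif ch == "Mito":
            inten = np.where(mito_intact, base, 0.0)
        else:
            inten = base
        df[f"I_{ch}"] = inten

    return GroundTruth(
        cells=df,
        spheroid_center_um=(fov / 2.0, fov / 2.0, radius_now),
        spheroid_radius_um=radius_now,
        fov_xy_um=fov,
        dose_uM=dose_uM,
        dead_fraction_expected=dead_frac,
        seed=config.seed,
        config=config,
        effect=effect,
    )


# --------------------------------------------------------------------------
# rendering


def _sphere_slab_weight(rho2: np.ndarray, zc: float, r: float,
                        za: float, zb: float) -> np.ndarray:
    """Fraction of the slab [za, zb] filled by the sphere chord at squared
    lateral distance rho2 from the sphere axis."""
    h = np.sqrt(np.maximum(r * r - rho2, 0.0))
    lo = np.maximum(za, zc - h)
    hi = np.minimum(zb, zc + h)
    return np.maximum(hi - lo, 0.0) / (zb - za)


def _sphere_section(rho2: np.ndarray, zc: float, r: float,
                    z_plane: float) -> np.ndarray:
    """Indicator of the infinitesimally thin geometric cross-section."""
    dz = z_plane - zc
    rad2 = r * r - dz * dz
    if rad2 <= 0:
        return np.zeros_like(rho2)
    return (rho2 < rad2).astype(float)


def apply_noise(image: np.ndarray, noise_model: str,
                rng: np.random.Generator, gaussian_sd: float = 2.0) -> np.ndarray:
    """Apply the configured shot/read-noise model to a noiseless image."""
    if noise_model == "none":
        return image
    if noise_model == "poisson":
        return rng.poisson(image).astype(float)
    if noise_model == "poisson+gaussian":
        return rng.poisson(image).astype(float) + rng.normal(
            0.0, gaussian_sd, size=image.shape
        )
    raise ValueError(f"unknown noise model {noise_model!r}")


def render_stack(truth: GroundTruth, config: SyntheticConfig | None = None,
                 well_id: str = "", site_id: str = "s1") -> ImageStack:
    """Render a ground-truth spheroid into a multi-channel Z-stack.

    Each plane integrates fluorophore density over an optical section of
    thickness ``plane_thickness_um`` (default: the z step, matching the
    thick optical sections of a low-NA 10x confocal; set 0 for ideal
    infinitesimal geometric cross-sections). Signal is attenuated by
    ``exp(-z / attenuation_length_um)`` with depth z from the well
    bottom, and cells whose centroid lies deeper than
    ``imaging_depth_cutoff_um`` contribute nothing anywhere. The image
    is then blurred by a lateral Gaussian PSF, offset by a constant
    background, degraded by the noise model, and quantized to 16 bits.
    """
    if config is None:
        config = truth.config
    px = config.pixel_size_um
    npx = int(round(truth.fov_xy_um / px))
    nz = config.n_planes
    channels = list(config.channel_intensity_means)
    img = np.zeros((len(channels), nz, npx, npx), dtype=float)

    thickness = config.plane_thickness_um
    if thickness is None:
        thickness = config.z_step_um
    cut = config.imaging_depth_cutoff_um
    att = config.attenuation_length_um

    cells = truth.cells
    xs = cells["x_um"].to_numpy()
    ys = cells["y_um"].to_numpy()
    zs = cells["z_um"].to_numpy()
    r_nucs = cells["nucleus_radius_um"].to_numpy()
    r_cells = cells["cell_radius_um"].to_numpy()

    any_signal = False
    for ci, ch in enumerate(channels):
        inten = cells[f"I_{ch}"].to_numpy()
        compartment = CHANNEL_COMPARTMENTS.get(ch, "nucleus")
        for i in np.flatnonzero(inten > 0):
            if zs[i] > cut:
                continue
            r_out = r_nucs[i] if compartment == "nucleus" else r_cells[i]
            # pixel patch around the cell
            x0 = max(int((xs[i] - r_out) / px) - 1, 0)
            x1 = min(int((xs[i] + r_out) / px) + 2, npx)
            y0 = max(int((ys[i] - r_out) / px) - 1, 0)
            y1 = min(int((ys[i] + r_out) / px) + 2, npx)
            if x0 >= x1 or y0 >= y1:
                continue
            gx = (np.arange(x0, x1) + 0.5) * px - xs[i]
            gy = (np.arange(y0, y1) + 0.5) * px - ys[i]
            rho2 = gy[:, None] ** 2 + gx[None, :] ** 2
            for k in range(nz):
                z_plane = k * config.z_step_um
                if thickness > 0:
                    za, zb = z_plane - thickness / 2.0, z_plane + thickness / 2.0
                    if zs[i] + r_out <= za or zs[i] - r_out >= zb:
                        continue
                    w = _sphere_slab_weight(rho2, zs[i], r_out, za, zb)
                    if compartment == "cytoplasm":
                        w = w - _sphere_slab_weight(rho2, zs[i], r_nucs[i], za, zb)
                else:
                    if abs(z_plane - zs[i]) >= r_out:
                        continue
                    w = _sphere_section(rho2, zs[i], r_out, z_plane)
                    if compartment == "cytoplasm":
                        w = w - _sphere_section(rho2, zs[i], r_nucs[i], z_plane)
                factor = 1.0
                if math.isfinite(att):
                    factor = math.exp(-z_plane / att)
                if w.any():
                    any_signal = True
                img[ci, k, y0:y1, x0:x1] += inten[i] * factor * w

    if not any_signal:
        warnings.warn(
            "rendered stack contains no signal: plane range does not cover "
            "any visible part of the spheroid", stacklevel=2,
        )

    if config.psf_sigma_um > 0:
        sig = config.psf_sigma_um / px
        for ci in range(len(channels)):
            for k in range(nz):
                img[ci, k] = ndimage.gaussian_filter(img[ci, k], sig)

    img += config.background_level
    rng = np.random.default_rng([config.seed, 977])
    img = apply_noise(img, config.noise_model, rng)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return ImageStack(
        data=img,
        pixel_size_um=px,
        z_step_um=config.z_step_um,
        channel_names=channels,
        well_id=well_id,
        site_id=site_id,
        metadata=truth.metadata(),
    )


def simulate_stack(config: SyntheticConfig, effect: EffectParams | None = None,
                   dose_uM: float = 0.0, well_id: str = "") -> tuple[GroundTruth, ImageStack]:
    """Convenience: generate ground truth and render it in one call."""
    truth = generate_spheroid_truth(config, effect, dose_uM)
    return truth, render_stack(truth, config, well_id=well_id)


# --------------------------------------------------------------------------
# benchmark-compound fixtures

OUTCOME_KINDS = ("ic50", "gt_max", "approx", "no_tox", "nd")


@dataclass(frozen=True)
class Outcome:
    """Censored per-assay screening outcome.

    ``ic50``: a fitted IC50 (standard error may be undefined);
    ``gt_max``: toxicity seen at the top dose but IC50 not determined
    (">100"); ``approx``: an approximate IC50 ("~500"); ``no_tox``: no
    effect up to the top dose tested; ``nd``: not determined.
    """

    kind: str
    value_uM: float | None = None
    se_uM: float | None = None
    max_uM: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in OUTCOME_KINDS:
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.kind in ("ic50", "approx") and not (self.value_uM or 0) > 0:
            raise ValueError(f"{self.kind} outcome requires value_uM > 0")
        if self.kind in ("gt_max", "no_tox") and not (self.max_uM or 0) > 0:
            raise ValueError(f"{self.kind} outcome requires max_uM > 0")

    @property
    def detected(self) -> bool:
        """Whether a toxic effect was observed (nd is not evaluable)."""
        return self.kind in ("ic50", "gt_max", "approx")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound x assay row of a benchmark table."""

    name: str
    compound_class: str
    description: str
    assay: str
    outcome: Outcome

    @property
    def is_negative_control(self) -> bool:
        return self.compound_class == "Negative controls"


def _fixture_path(table_id: str):
    table_id = table_id.upper()
    if table_id not in ("T1", "T2"):
        raise KeyError(f"unknown table id {table_id!r}; expected 'T1' or 'T2'")
    fname = "table1.csv" if table_id == "T1" else "table2.csv"
    return resources.files("spherotox.data") / fname


def load_table_fixtures(table_id: str) -> list[CompoundRecord]:
    """Load the packaged benchmark-compound table (``T1``: 48 compounds,
    iPSC 3D vs 2D; ``T2``: 23 compounds, HepG2 vs iPSC 3D spheroids)."""
    with resources.as_file(_fixture_path(table_id)) as p:
        df = pd.read_csv(p).rename(columns={"class": "compound_class"})
    records = []
    for row in df.itertuples(index=False):
        out = Outcome(
            kind=row.outcome_kind,
            value_uM=None if pd.isna(row.value_uM) else float(row.value_uM),
            se_uM=None if pd.isna(row.se_uM) else float(row.se_uM),
            max_uM=None if pd.isna(row.max_uM) else float(row.max_uM),
        )
        records.append(CompoundRecord(
            name=row.compound,
            compound_class=row.compound_class,
            description="" if pd.isna(row.description) else row.description,
            assay=row.assay,
            outcome=out,
        ))
    return records


def get_record(records: list[CompoundRecord], compound: str,
               assay: str) -> CompoundRecord:
    """Exact-name lookup of one compound x assay record."""
    for rec in records:
        if rec.name == compound and rec.assay == assay:
            return rec
    known = sorted({r.name for r in records})
    raise KeyError(
        f"no record for ({compound!r}, {assay!r}); known compounds: {known}"
    )
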