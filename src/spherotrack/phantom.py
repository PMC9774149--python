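"""Synthetic spheroid phantoms with analytic ground truth.

Generates growth trajectories, brightfield-like rasters, and absorbance
readouts for a drug-dose plate design, so every downstream measurement
stage can be tested against known truth.

Model summary
-------------
* Radius follows a discrete daily logistic update damped by a Hill
  inhibition term ``I = Emax * C^h / (C^h + EC50^h)``.
* The boundary is a polar cosine series ``r(theta) = R * (1 + a * sum_k
  w_k cos(k theta + phi_k))`` with seeded random phases; the protrusion
  amplitude ``a`` is the single invasiveness knob.
* Hypoxia rescales growth rate, invasion rate, and Emax multiplicatively.
* Viability signal is linear in viable volume; a necrotic core (radius
  beyond a fixed viable rim) contributes no signal and is rendered as a
  darker central disk only - it never alters boundary geometry.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidArgumentError, RenderOverflowError

__all__ = [
    "PhantomConfig",
    "GrowthTrajectory",
    "PlateDataset",
    "DEFAULT_DOSES_UM",
    "simulate_growth",
    "boundary_polygon",
    "render_spheroid_image",
    "simulate_viability_readout",
    "generate_plate",
    "well_seed",
]

#: Dose ladder used by the study design: eight positive doses plus vehicle.
DEFAULT_DOSES_UM: tuple[float, ...] = (
    0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0,
)

CONDITIONS = ("normoxia", "hypoxia")

# Harmonic weights of the boundary cosine series, normalized to sum 1 so
# that the peak radial deviation is bounded by the protrusion amplitude.
_HARMONIC_WEIGHTS = (6.0 / 11.0, 3.0 / 11.0, 2.0 / 11.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth simulation parameters for one phantom plate."""

    base_radius_um: float = 80.0
    growth_rate_per_day: float = 0.25
    r_max_um: float = 320.0
    invasion_rate_per_day: float = 0.02
    n_protrusions: int = 7
    drug_emax: float = 0.9
    drug_ec50_uM: float = 0.02
    hill_coef: float = 1.0
    hypoxia_growth_factor: float = 1.0
    hypoxia_invasion_factor: float = 1.0
    hypoxia_drug_factor: float = 1.0
    viability_per_volume: float = 1e-7
    noise_sd: float = 0.0
    pixel_size_um: float = 2.0
    image_size_px: int = 384
    viable_rim_um: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.drug_emax <= 1.0):
            raise InvalidArgumentError(
                f"drug_emax must be in [0, 1], got {self.drug_emax}")
        nonneg = {
            "base_radius_um": self.base_radius_um,
            "growth_rate_per_day": self.growth_rate_per_day,
            "r_max_um": self.r_max_um,
            "invasion_rate_per_day": self.invasion_rate_per_day,
            "drug_ec50_uM": self.drug_ec50_uM,
            "viability_per_volume": self.viability_per_volume,
            "noise_sd": self.noise_sd,
            "viable_rim_um": self.viable_rim_um,
        }
        for name, value in nonneg.items():
            if not math.isfinite(value) or value < 0:
                raise InvalidArgumentError(
                    f"{name} must be finite and >= 0, got {value}")
        for name, value in (
            ("hill_coef", self.hill_coef),
            ("hypoxia_growth_factor", self.hypoxia_growth_factor),
            ("hypoxia_invasion_factor", self.hypoxia_invasion_factor),
            ("hypoxia_drug_factor", self.hypoxia_drug_factor),
            ("pixel_size_um", self.pixel_size_um),
        ):
            if not math.isfinite(value) or value <= 0:
                raise InvalidArgumentError(
                    f"{name} must be finite and > 0, got {value}")
        if self.r_max_um < self.base_radius_um:
            raise InvalidArgumentError("r_max_um must be >= base_radius_um")
        if self.n_protrusions < 0:
            raise InvalidArgumentError("n_protrusions must be >= 0")
        if self.image_size_px < 16:
            raise InvalidArgumentError("image_size_px must be >= 16")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        return cls(**d)


@dataclass(frozen=True)
class GrowthTrajectory:
    """Per-day ground truth for one well."""

    days: tuple[int, ...]
    radius_um: tuple[float, ...]
    protrusion_amp: tuple[float, ...]
    viable_volume_um3: tuple[float, ...]
    condition: str
    dose_uM: float

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.radius_um) == len(self.protrusion_amp)
                == len(self.viable_volume_um3) == n):
            raise InvalidArgumentError("trajectory field lengths differ")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise InvalidArgumentError("days must be strictly increasing")
        if any(r < 0 for r in self.radius_um):
            raise InvalidArgumentError("radii must be >= 0")
        if any(a < 0 for a in self.protrusion_amp):
            raise InvalidArgumentError("protrusion_amp must be >= 0")


def _hill_inhibition(dose_uM: float, emax: float, ec50: float, h: float) -> float:
    if dose_uM == 0.0:
        return 0.0
    if math.isinf(dose_uM):
        return emax
    ch = dose_uM ** h
    return emax * ch / (ch + ec50 ** h)


def _necrosis_fraction(radius_um: float, viable_rim_um: float) -> float:
    core = max(0.0, radius_um - viable_rim_um)
    if radius_um <= 0:
        return 0.0
    return (core / radius_um) ** 3


def simulate_growth(
    config: PhantomConfig,
    condition: str,
    dose_uM: float,
    n_days: int = 7,
    first_day: int = 1,
) -> GrowthTrajectory:
    """Deterministic daily trajectory under one (condition, dose).

    Radius follows ``r <- r + g*r*(1 - r/r_max)*(1 - I)`` and protrusion
    amplitude ``a <- a + invasion_rate*(1 - I)`` (floored at 0), where the
    inhibition ``I`` is the Hill term of the dose. Under hypoxia the growth
    rate, invasion rate, and Emax are each multiplied by their condition
    factor; a factor pushing effective Emax above 1 makes ``1 - I``
    negative, i.e. treated spheroids shrink.
    """
    if condition not in CONDITIONS:
        raise InvalidArgumentError(
            f"condition must be one of {CONDITIONS}, got {condition!r}")
    if math.isnan(dose_uM) or dose_uM < 0:
        raise InvalidArgumentError(f"dose_uM must be >= 0, got {dose_uM}")
    if n_days < 1:
        raise InvalidArgumentError("n_days must be >= 1")

    g = config.growth_rate_per_day
    inv = config.invasion_rate_per_day
    emax = config.drug_emax
    if condition == "hypoxia":
        g *= config.hypoxia_growth_factor
        inv *= config.hypoxia_invasion_factor
        emax *= config.hypoxia_drug_factor

    inhibition = _hill_inhibition(dose_uM, emax, config.drug_ec50_uM,
                                  config.hill_coef)
    effect = 1.0 - inhibition

    days = tuple(range(first_day, first_day + n_days))
    radii = [config.base_radius_um]
    amps = [0.0]
    for _ in days[1:]:
        r = radii[-1]
        r_next = r + g * r * (1.0 - r / config.r_max_um) * effect
        radii.append(max(0.0, r_next))
        amps.append(max(0.0, amps[-1] + inv * effect))
    volumes = tuple(
        (4.0 / 3.0) * math.pi * r ** 3
        * (1.0 - _necrosis_fraction(r, config.viable_rim_um))
        for r in radii
    )
    return GrowthTrajectory(
        days=days,
        radius_um=tuple(radii),
        protrusion_amp=tuple(amps),
        viable_volume_um3=volumes,
        condition=condition,
        dose_uM=float(dose_uM),
    )


def _boundary_radius(theta: np.ndarray, radius_um: float, amp: float,
                     n_protrusions: int, phases: np.ndarray) -> np.ndarray:
    """Radial boundary r(theta) in micrometers."""
    if amp == 0.0 or n_protrusions == 0:
        return np.full_like(theta, radius_um, dtype=float)
    mod = np.zeros_like(theta, dtype=float)
    for j, w in enumerate(_HARMONIC_WEIGHTS):
        k = n_protrusions * (j + 1)
        mod += w * np.cos(k * theta + phases[j])
    return radius_um * (1.0 + amp * mod)


def _phases_for_seed(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 2.0 * np.pi, size=len(_HARMONIC_WEIGHTS))


def boundary_polygon(
    radius_um: float,
    protrusion_amp: float,
    config: PhantomConfig,
    phase_seed: int,
    n_vertices: int = 720,
) -> np.ndarray:
    """Ground-truth boundary polygon, vertices (x, y) in pixel coordinates.

    The polygon is the analytic boundary sampled at ``n_vertices`` angles,
    centered on the image center, counter-clockwise in (x, y).
    """
    phases = _phases_for_seed(phase_seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r_um = _boundary_radius(theta, radius_um, protrusion_amp,
                            config.n_protrusions, phases)
    c = (config.image_size_px - 1) / 2.0
    r_px = r_um / config.pixel_size_um
    x = c + r_px * np.cos(theta)
    y = c + r_px * np.sin(theta)
    return np.column_stack([x, y])


def render_spheroid_image(
    radius_um: float,
    protrusion_amp: float,
    config: PhantomConfig,
    day_seed: int,
    phase_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one brightfield-like frame plus its ground-truth polygon.

    Returns ``(pixels, polygon)`` where ``pixels`` is a float32 raster in
    [0, 1] (bright background, dark spheroid, darker necrotic core) and
    ``polygon`` is the analytic boundary from :func:`boundary_polygon`.
    ``phase_seed`` fixes the protrusion directions independently of the
    per-day noise stream; it defaults to ``day_seed``.
    """
    if not math.isfinite(radius_um) or radius_um < 0:
        raise InvalidArgumentError(f"radius_um must be >= 0, got {radius_um}")
    if not math.isfinite(protrusion_amp) or protrusion_amp < 0:
        raise InvalidArgumentError("protrusion_amp must be >= 0")
    if phase_seed is None:
        phase_seed = day_seed

    n = config.image_size_px
    c = (n - 1) / 2.0
    half_field_um = c * config.pixel_size_um
    max_extent = radius_um * (1.0 + protrusion_amp)
    if max_extent > half_field_um - 2.0 * config.pixel_size_um:
        raise RenderOverflowError(
            f"spheroid extent {max_extent:.1f} um exceeds field half-width "
            f"{half_field_um:.1f} um")

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dx = (xx - c) * config.pixel_size_um
    dy = (yy - c) * config.pixel_size_um
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    phases = _phases_for_seed(phase_seed)
    r_bound = _boundary_radius(theta, radius_um, protrusion_amp,
                               config.n_protrusions, phases)

    # Smoothstep edge one pixel wide keeps the raster sub-pixel accurate.
    edge = config.pixel_size_um
    t = np.clip((rr - r_bound) / edge + 0.5, 0.0, 1.0)
    inside = 1.0 - t * t * (3.0 - 2.0 * t)

    background, body, core_val = 0.85, 0.30, 0.12
    img = background + (body - background) * inside

    core_radius = max(0.0, radius_um - config.viable_rim_um)
    if core_radius > 0:
        tc = np.clip((rr - core_radius) / edge + 0.5, 0.0, 1.0)
        in_core = 1.0 - tc * tc * (3.0 - 2.0 * tc)
        img = img + (core_val - body) * in_core * inside

    if config.noise_sd > 0:
        rng = np.random.default_rng(day_seed)
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)

    polygon = boundary_polygon(radius_um, protrusion_amp, config, phase_seed)
    return np.clip(img, 0.0, 1.0).astype(np.float32), polygon


def simulate_viability_readout(
    traj: GrowthTrajectory,
    config: PhantomConfig,
    seed: int,
    n_blanks: int = 2,
) -> pd.DataFrame:
    """Absorbance table (day, A570, A600, is_blank) for one well.

    ``A570 - A600`` equals ``viability_per_volume * viable_volume`` plus
    Gaussian noise of sd ``noise_sd`` (absorbance units). Blank rows carry
    zero viable volume for background-subtraction checks.
    """
    if len(traj.days) == 0:
        raise InvalidArgumentError("trajectory is empty")
    rng = np.random.default_rng(seed)
    rows = []
    baseline_a600 = 0.05
    for day, vol in zip(traj.days, traj.viable_volume_um3):
        signal = config.viability_per_volume * vol
        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        a600 = baseline_a600
        a570 = a600 + signal + noise
        rows.append({"day": day, "A570": a570, "A600": a600, "is_blank": False})
        for _ in range(n_blanks):
            bnoise = (rng.normal(0.0, config.noise_sd)
                      if config.noise_sd > 0 else 0.0)
            rows.append({"day": day, "A570": baseline_a600 + bnoise,
                         "A600": baseline_a600, "is_blank": True})
    return pd.DataFrame(rows)


def well_seed(master_seed: int, well_id: str) -> int:
    """Stable 63-bit seed derived from (master seed, well id)."""
    digest = hashlib.sha256(f"{master_seed}:{well_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big") >> 1


@dataclass
class PlateDataset:
    """Paths and tables of one generated plate."""

    root: Path
    layout: pd.DataFrame
    absorbance: pd.DataFrame
    truth: pd.DataFrame
    image_paths: list[Path] = field(default_factory=list)


def iter_plate_wells(
    config: PhantomConfig,
    doses_uM: Sequence[float] = DEFAULT_DOSES_UM,
    conditions: Sequence[str] = ("normoxia",),
    n_replicates: int = 6,
    n_days: int = 7,
    cell_line_label: str = "phantom",
) -> Iterator[tuple[dict, GrowthTrajectory]]:
    """Yield (well metadata dict, trajectory) for every well of the design.

    Well ids are ``W0001, W0002, ...`` in (condition, dose, replicate)
    order; per-well seeds derive from :func:`well_seed` so any well can be
    regenerated independently.
    """
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    for d in doses_uM:
        if d < 0:
            raise InvalidArgumentError(f"negative dose {d}")
    idx = 0
    for condition in conditions:
        for dose in doses_uM:
            for rep in range(1, n_replicates + 1):
                idx += 1
                wid = f"W{idx:04d}"
                meta = {
                    "well": wid,
                    "cell_line_label": cell_line_label,
                    "dose_uM": float(dose),
                    "condition": condition,
                    "replicate": rep,
                    "seed": well_seed(config.seed, wid),
                }
                traj = simulate_growth(config, condition, dose, n_days=n_days)
                yield meta, traj


def generate_plate(
    config: PhantomConfig,
    out_dir: str | Path,
    doses_uM: Sequence[float] = DEFAULT_DOSES_UM,
    conditions: Sequence[str] = ("normoxia",),
    n_replicates: int = 6,
    n_days: int = 7,
    cell_line_label: str = "phantom",
) -> PlateDataset:
    """Write a full phantom plate: images + layout/absorbance/truth CSVs.

    Layout: one 16-bit TIFF per (well, day) named ``{well}_{day:02d}.tif``
    under ``images/``; ``layout.csv``, ``absorbance.csv``, ``truth.csv``
    at the root. Fully determined by (config, design).
    """
    root = Path(out_dir)
    img_dir = root / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    layout_rows, truth_rows, absorbance_frames, image_paths = [], [], [], []
    for meta, traj in iter_plate_wells(
            config, doses_uM, conditions, n_replicates, n_days,
            cell_line_label):
        wid, wseed = meta["well"], meta["seed"]
        layout_rows.append({k: meta[k] for k in
                            ("well", "cell_line_label", "dose_uM",
                             "condition", "replicate")})
        for day, r, amp, vol in zip(traj.days, traj.radius_um,
                                    traj.protrusion_amp,
                                    traj.viable_volume_um3):
            pixels, _ = render_spheroid_image(
                r, amp, config, day_seed=wseed + day, phase_seed=wseed)
            path = img_dir / f"{wid}_{day:02d}.tif"
            tifffile.imwrite(
                path, (pixels * 65535).round().astype(np.uint16))
            image_paths.append(path)
            truth_rows.append({"well": wid, "day": day, "radius_um": r,
                               "protrusion_amp": amp,
                               "viable_volume_um3": vol})
        ab = simulate_viability_readout(traj, config, seed=wseed ^ 0xA5A5)
        ab.insert(0, "well", wid)
        absorbance_frames.append(ab)

    layout = pd.DataFrame(layout_rows)
    truth = pd.DataFrame(truth_rows)
    absorbance = pd.concat(absorbance_frames, ignore_index=True)

    layout.to_csv(root / "layout.csv", index=False)
    absorbance.to_csv(root / "absorbance.csv", index=False, float_format="%.10g")
    truth.to_csv(root / "truth.csv", index=False, float_format="%.10g")
    with open(root / "phantom_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

    return PlateDataset(root=root, layout=layout, absorbance=absorbance,
                        truth=truth, image_paths=image_paths)
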