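"""Configuration, file discovery, and the end-to-end run.

A run discovers ``{well}_{day:02d}.tif|.png`` images, measures each one,
writes ``metrics.csv``, then produces the endpoint tables. Per-well
failures are recorded in the run manifest and never abort the run.
Identical inputs and config reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boundary import SegmentationSettings, SpheroidImage
from .errors import InvalidArgumentError, SchemaError, SpherotrackError
from .metrics import measure_image
from .endpoints import summarize_plate

__all__ = ["PipelineConfig", "load_plate_layout", "discover_images",
           "run_measure", "run_pipeline", "measure_phantom_plate"]

logger = logging.getLogger("spherotrack")

_IMAGE_RE = re.compile(r"^(?P<well>.+)_(?P<day>\d{2})\.(tif|tiff|png)$")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    input_dir: str = "."
    layout_path: str = "layout.csv"
    absorbance_path: str = "absorbance.csv"
    output_dir: str = "results"
    pixel_size_um: float = 2.0
    segmentation: SegmentationSettings = field(
        default_factory=SegmentationSettings)
    terminal_day: int = 7
    first_day: int = 1
    epi_threshold: float = 0.5
    area_mode: str = "contour"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = raw.pop("segmentation", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if seg:
            cfg.segmentation = SegmentationSettings(**seg)
        if cfg.terminal_day < cfg.first_day:
            raise InvalidArgumentError("terminal_day must be >= first_day")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"] = self.segmentation.to_dict()
        return d


def load_plate_layout(path: str | Path) -> pd.DataFrame:
    """Validated plate layout: well -> (cell line, dose uM, condition, rep).

    Rejects missing columns, duplicate wells, unparsable or negative
    doses, naming the offending row.
    """
    df = pd.read_csv(path)
    required = ["well", "cell_line_label", "dose_uM", "condition", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"layout {path}: missing columns {missing}")
    dupes = df["well"][df["well"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"layout {path}: duplicate well ids {dupes[:5]}")
    try:
        df["dose_uM"] = df["dose_uM"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"layout {path}: unparsable dose_uM ({exc})") from exc
    bad = df.index[df["dose_uM"] < 0].tolist()
    if bad:
        raise SchemaError(
            f"layout {path}: negative dose at row(s) {bad[:5]}")
    if df["well"].isna().any():
        raise SchemaError(f"layout {path}: empty well id")
    return df[required]


def discover_images(input_dir: str | Path) -> list[tuple[str, int, Path]]:
    """(well, day, path) triples matching the filename pattern, sorted."""
    found = []
    for p in sorted(Path(input_dir).iterdir()):
        m = _IMAGE_RE.match(p.name)
        if m:
            found.append((m.group("well"), int(m.group("day")), p))
    return found


def run_measure(config: PipelineConfig,
                images: list[tuple[str, int, Path]] | None = None,
                ) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every discovered image; collect per-well errors.

    Returns (metrics DataFrame, error records). A failing image is
    logged and recorded; remaining images are still processed.
    """
    if images is None:
        images = discover_images(config.input_dir)
    if not images:
        raise InvalidArgumentError(
            f"no images matching '{{well}}_{{day:02d}}.tif' in "
            f"{config.input_dir}")
    records, errors = [], []
    for well, day, path in images:
        try:
            pixels = np.asarray(iio.imread(path))
            if pixels.ndim == 3:
                pixels = pixels[..., 0]
            img = SpheroidImage(pixels=pixels.astype(float),
                                pixel_size_um=config.pixel_size_um,
                                well_id=well, day=day)
            rec = measure_image(img, config.segmentation,
                                area_mode=config.area_mode)
            records.append(rec.to_dict())
        except (SpherotrackError, OSError, ValueError) as exc:
            logger.warning("well %s day %d: %s", well, day, exc)
            errors.append({"well": well, "day": day, "file": str(path),
                           "error": type(exc).__name__, "message": str(exc)})
    metrics = pd.DataFrame(
        records, columns=["well_id", "day", "S", "P_o", "P_e", "EPI",
                          "roughness", "d", "V"])
    return metrics.rename(columns={"well_id": "well"}), errors


def measure_phantom_plate(
    phantom_config,
    doses_uM=None,
    conditions=("normoxia",),
    n_replicates: int = 6,
    n_days: int = 7,
    settings: SegmentationSettings | None = None,
) -> dict[str, pd.DataFrame]:
    """Render and measure a phantom plate without touching disk.

    Convenience path for validation: every well/day frame is rendered,
    segmented, and measured in memory. Returns ``metrics``,
    ``absorbance``, ``layout``, and ``truth`` DataFrames matching the
    on-disk plate schema.
    """
    from .phantom import (DEFAULT_DOSES_UM, iter_plate_wells,
                          render_spheroid_image, simulate_viability_readout)

    if doses_uM is None:
        doses_uM = DEFAULT_DOSES_UM
    settings = settings or SegmentationSettings()
    m_rows, truth_rows, layout_rows, ab_frames = [], [], [], []
    for meta, traj in iter_plate_wells(phantom_config, doses_uM, conditions,
                                       n_replicates, n_days):
        wid, wseed = meta["well"], meta["seed"]
        layout_rows.append({k: meta[k] for k in
                            ("well", "cell_line_label", "dose_uM",
                             "condition", "replicate")})
        for day, r, amp, vol in zip(traj.days, traj.radius_um,
                                    traj.protrusion_amp,
                                    traj.viable_volume_um3):
            pixels, _ = render_spheroid_image(
                r, amp, phantom_config, day_seed=wseed + day,
                phase_seed=wseed)
            img = SpheroidImage(pixels=pixels,
                                pixel_size_um=phantom_config.pixel_size_um,
                                well_id=wid, day=day)
            rec = measure_image(img, settings)
            row = rec.to_dict()
            row["well"] = row.pop("well_id")
            m_rows.append(row)
            truth_rows.append({"well": wid, "day": day, "radius_um": r,
                               "protrusion_amp": amp,
                               "viable_volume_um3": vol})
        ab = simulate_viability_readout(traj, phantom_config,
                                        seed=wseed ^ 0xA5A5)
        ab.insert(0, "well", wid)
        ab_frames.append(ab)
    return {
        "metrics": pd.DataFrame(m_rows),
        "absorbance": pd.concat(ab_frames, ignore_index=True),
        "layout": pd.DataFrame(layout_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """measure + summarize + manifest. Returns the results directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    images = discover_images(config.input_dir)
    metrics, errors = run_measure(config, images)
    metrics.to_csv(out / "metrics.csv", index=False, float_format=_FLOAT_FMT)

    layout = load_plate_layout(config.layout_path)
    absorbance = pd.read_csv(config.absorbance_path)
    tables = summarize_plate(metrics, absorbance, layout,
                             terminal_day=config.terminal_day,
                             first_day=config.first_day,
                             epi_threshold=config.epi_threshold)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {
        "software": "spherotrack",
        "version": __version__,
        "config": config.to_dict(),
        "n_images": len(images),
        "n_measured": len(metrics),
        "inputs": [str(p) for _, _, p in images],
        "per_well_errors": errors,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote results to %s (%d measured, %d errors)",
                out, len(metrics), len(errors))
    return out
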