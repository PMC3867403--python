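"""Top-level reproducible analysis run.

``run_pipeline`` ties the stages together: read closure curves, fit and
classify kinetics per replicate, count marker-positive cells in the
wound-edge band, measure migration distances, and compare conditions.
Every numeric output is a CSV in the run directory, and a JSON manifest
(config echo, seed, package and library versions, output list) makes the
run reproducible: the same config and seed give byte-identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as wio
from .edge_band import band_fraction, distances_to_polyline, migration_distance
from .errors import InvalidInputError, WoundkinError
from .group_stats import format_report, healing_report
from .kinetics import fit_series

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("woundkin")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run; validated before any work starts."""

    output_dir: str
    closure_csv: Optional[str] = None
    cells_csv: Optional[str] = None
    edges_csv: Optional[str] = None
    alpha: float = 0.05
    band_um: float = 100.0
    floor_pct: float = 2.0
    window_h: float = 6.0
    min_biphasic_points: int = 6
    band_edge: str = "front"  # which edge the band is measured from
    reference: Optional[str] = None  # reference condition for the report
    marker: Optional[str] = None
    migration_samples: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.band_um <= 0:
            raise InvalidInputError("band_um must be positive")
        if self.floor_pct < 0:
            raise InvalidInputError("floor_pct must be >= 0")
        if self.window_h <= 0:
            raise InvalidInputError("window_h must be positive")
        if self.min_biphasic_points < 6:
            raise InvalidInputError("min_biphasic_points must be >= 6")
        if self.band_edge not in ("front", "original"):
            raise InvalidInputError("band_edge must be 'front' or 'original'")
        if self.migration_samples < 1:
            raise InvalidInputError("migration_samples must be >= 1")
        if self.closure_csv is None and (self.cells_csv is None or self.edges_csv is None):
            if self.cells_csv is not None and self.edges_csv is None:
                raise InvalidInputError("cells_csv requires edges_csv")
            if self.closure_csv is None and self.cells_csv is None and self.edges_csv is None:
                raise InvalidInputError("no inputs: need closure_csv and/or cells+edges CSVs")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except WoundkinError as exc:
                raise WoundkinError(f"stage {name}: {exc}") from exc
            log.info("stage %s: done in %.3f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("fit-kinetics")
def _fit_stage(config: RunConfig, outdir: Path) -> Optional[Path]:
    if config.closure_csv is None:
        return None
    series = wio.read_closure_csv(config.closure_csv)
    rows = []
    fits_by_cond: Dict[str, list] = {}
    for s in series:
        sel = fit_series(
            s,
            alpha=config.alpha,
            floor_pct=config.floor_pct,
            min_biphasic_points=config.min_biphasic_points,
        )
        rows.append((s.condition, s.replicate, sel.chosen))
        fits_by_cond.setdefault(s.condition, []).append(sel.chosen)
    fits_path = outdir / "fits.csv"
    wio.write_fits_csv(rows, fits_path)
    reference = config.reference or series[0].condition
    report = healing_report(fits_by_cond, reference=reference, alpha=config.alpha)
    report.to_csv(outdir / "report.csv", index=False)
    (outdir / "report.txt").write_text(
        format_report(report, alpha=config.alpha) + "\n", encoding="utf-8"
    )
    return fits_path


@_stage("band-count")
def _band_stage(config: RunConfig, outdir: Path) -> Optional[Path]:
    if config.cells_csv is None or config.edges_csv is None:
        return None
    cells = wio.read_cells_csv(config.cells_csv)
    edges = wio.read_edges_csv(config.edges_csv)
    import csv

    path = outdir / "band_counts.csv"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "marker", "band_um", "n_total", "n_positive", "fraction"])
        image_ids = sorted({c.image_id for c in cells})
        for image_id in image_ids:
            img_edges = [
                e for e in edges
                if e.image_id == image_id and e.edge_type == config.band_edge
            ]
            if not img_edges:
                raise InvalidInputError(
                    f"image {image_id!r} has no {config.band_edge!r} edge"
                )
            img_cells = [c for c in cells if c.image_id == image_id]
            if config.marker is not None:
                img_cells = [c for c in img_cells if c.marker == config.marker]
            markers = sorted({c.marker for c in img_cells})
            for marker in markers:
                mk_cells = [c for c in img_cells if c.marker == marker]
                pts = np.array([[c.x, c.y] for c in mk_cells])
                # band membership against the nearest of the image's edges
                dist = np.minimum.reduce(
                    [distances_to_polyline(pts, e) for e in img_edges]
                )
                in_band = dist <= config.band_um
                n_total = int(in_band.sum())
                n_pos = int(
                    sum(1 for c, m in zip(mk_cells, in_band) if m and c.positive)
                )
                frac = n_pos / n_total if n_total else math.nan
                w.writerow(
                    [image_id, marker, repr(config.band_um), n_total, n_pos,
                     "" if math.isnan(frac) else repr(frac)]
                )
    return path


@_stage("migration")
def _migration_stage(config: RunConfig, outdir: Path) -> Optional[Path]:
    if config.edges_csv is None:
        return None
    edges = wio.read_edges_csv(config.edges_csv)
    by_image: Dict[str, Dict[str, list]] = {}
    for e in edges:
        by_image.setdefault(e.image_id, {}).setdefault(e.edge_type, []).append(e)
    import csv

    rows = []
    for image_id in sorted(by_image):
        kinds = by_image[image_id]
        if "original" in kinds and "front" in kinds:
            res = migration_distance(
                kinds["original"][0], kinds["front"][0],
                n_samples=config.migration_samples,
            )
            rows.append((image_id, res.mean_um, res.std_um, res.per_sample_distances.size))
    if not rows:
        return None
    path = outdir / "migration.csv"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "mean_um", "std_um", "n_samples"])
        for image_id, mean, std, n in rows:
            w.writerow([image_id, repr(mean), repr(std), n])
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute every applicable stage and write a run manifest.

    Returns the run directory. Raises on the first stage error, naming
    the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level.upper())
    try:
        outputs = {}
        for name, stage in (
            ("fits", _fit_stage),
            ("band_counts", _band_stage),
            ("migration", _migration_stage),
        ):
            result = stage(config, outdir)
            if result is not None:
                outputs[name] = result.name
        if "fits" in outputs:
            outputs["report"] = "report.csv"
            outputs["report_text"] = "report.txt"
        import scipy

        from . import __version__

        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "versions": {
                "woundkin": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
            "outputs": outputs,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
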