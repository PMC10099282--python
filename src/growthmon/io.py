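"""Readers, writers and the end-to-end workflow runner.

File conventions:

* Spectrum files: delimited text (comma or tab, auto-detected) with a header
  row and columns ``freq_hz, z_re_ohm, z_im_ohm`` plus an optional
  ``timepoint_h``.  A file may hold one sweep or many (long format keyed by
  the timepoint column).
* Fit tables / coverage tables: tidy CSV, one row per timepoint (columns as
  written by :meth:`growthmon.eis.SeriesFit.to_frame` and
  :func:`growthmon.imaging.coverage_series`).
* Masks: PNG, foreground 255 / background 0.

All floats are written with 15 significant digits so a write/read round trip
preserves values beyond 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import eis, growth, imaging, simulate

logger = logging.getLogger("growthmon")

__all__ = [
    "RunConfig",
    "read_spectrum_file",
    "read_spectra",
    "write_spectrum_file",
    "write_table",
    "read_image",
    "write_mask",
    "run_workflow",
]

REQUIRED_SPECTRUM_COLUMNS = ("freq_hz", "z_re_ohm", "z_im_ohm")
FLOAT_FORMAT = "%.15g"

#: Default seeding density of the cultivation (cells/mL).
DEFAULT_SEEDING_DENSITY = 50_000.0


@dataclass
class RunConfig:
    """One structured configuration driving the full workflow.

    ``c_i`` is the seeding density used by the proportional concentration
    estimator; ``baseline_timepoint`` selects which coverage row provides
    ``SC_i`` (``None`` = earliest).  ``cutoff_h`` separates the pre/post
    windows of the modality comparison.
    """

    spectra_dir: str | None = None
    images_dir: str | None = None
    out_dir: str = "growthmon_out"
    calibration: str = "first"
    pipeline: imaging.PipelineConfig = field(default_factory=imaging.PipelineConfig)
    fit_options: eis.FitOptions = field(default_factory=eis.FitOptions)
    c_i: float = DEFAULT_SEEDING_DENSITY
    baseline_timepoint: float | None = None
    cutoff_h: float = 60.0
    seed: int = 0

    def digest(self) -> str:
        payload = {
            "spectra_dir": self.spectra_dir,
            "images_dir": self.images_dir,
            "calibration": self.calibration,
            "pipeline": asdict(self.pipeline),
            "fit_options": asdict(self.fit_options),
            "c_i": self.c_i,
            "baseline_timepoint": self.baseline_timepoint,
            "cutoff_h": self.cutoff_h,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pipeline = imaging.PipelineConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("pipeline", {}).items()
        })
        fit_options = eis.FitOptions(**raw.pop("fit_options", {}))
        return cls(pipeline=pipeline, fit_options=fit_options, **raw)


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_spectrum_file(path: str | Path) -> eis.ImpedanceSpectrum | list[eis.ImpedanceSpectrum]:
    """Parse a potentiostat-style sweep export.

    Returns one spectrum, or a list when a ``timepoint_h`` column holds
    several sweeps (long format).  Rows that fail numeric parsing raise an
    error naming the offending line; out-of-order frequencies are sorted with
    a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    numeric_cols = list(REQUIRED_SPECTRUM_COLUMNS) + (
        ["timepoint_h"] if "timepoint_h" in df.columns else []
    )
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            bad_rows = sorted(set(df.index[coerced.isna()]))
            # +2: header line plus 1-based indexing.
            lines = [int(i) + 2 for i in bad_rows]
            raise ValueError(f"{path}: non-numeric value(s) in column {col!r} at line(s) {lines}")
        df[col] = coerced

    def build(sub: pd.DataFrame, timepoint: float | None) -> eis.ImpedanceSpectrum:
        f = sub["freq_hz"].to_numpy()
        if np.any(np.diff(f) < 0):
            logger.warning("%s: frequencies out of order; sorting ascending", path)
        return eis.ImpedanceSpectrum(
            frequencies=f,
            z=sub["z_re_ohm"].to_numpy() + 1j * sub["z_im_ohm"].to_numpy(),
            timepoint=timepoint,
        )

    if "timepoint_h" in df.columns and df["timepoint_h"].nunique() > 1:
        return [
            build(sub, float(t))
            for t, sub in df.groupby("timepoint_h", sort=True)
        ]
    timepoint = float(df["timepoint_h"].iloc[0]) if "timepoint_h" in df.columns else None
    return build(df, timepoint)


def read_spectra(source: str | Path) -> list[eis.ImpedanceSpectrum]:
    """Read every sweep from a file or a directory of files."""
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob("*.csv")) + sorted(source.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no .csv/.tsv spectrum files in {source}")
    else:
        files = [source]
    spectra: list[eis.ImpedanceSpectrum] = []
    for f in files:
        out = read_spectrum_file(f)
        spectra.extend(out if isinstance(out, list) else [out])
    return spectra


def write_spectrum_file(path: str | Path, spectrum: eis.ImpedanceSpectrum) -> None:
    df = pd.DataFrame(
        {
            "freq_hz": spectrum.frequencies,
            "z_re_ohm": spectrum.real,
            "z_im_ohm": spectrum.imag,
        }
    )
    if spectrum.timepoint is not None:
        df["timepoint_h"] = spectrum.timepoint
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_image(path: str | Path) -> np.ndarray:
    return iio.imread(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def _discover_images(images_dir: Path) -> dict[float, list[Path]]:
    """Layout ``<root>/<timepoint_h>/<image>.png|tif`` or a manifest CSV."""
    manifest = images_dir / "manifest.csv"
    groups: dict[float, list[Path]] = {}
    if manifest.exists():
        df = pd.read_csv(manifest)
        for _, row in df.iterrows():
            groups.setdefault(float(row["timepoint_h"]), []).append(
                images_dir / str(row["path"])
            )
        return groups
    for sub in sorted(images_dir.iterdir()):
        if not sub.is_dir():
            continue
        try:
            t = float(sub.name)
        except ValueError:
            continue
        paths = sorted(
            p for p in sub.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if paths:
            groups[t] = paths
    if not groups:
        raise FileNotFoundError(f"no timepoint image folders or manifest under {images_dir}")
    return groups


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2f s", name, dt)
            else:
                logger.error("stage %s: FAILED after %.2f s: %s", name, dt, exc)
            return False

    return _Timer()


def run_workflow(config: RunConfig) -> Path:
    """Run fit-eis -> segment -> coverage -> analyze and write all artifacts.

    Returns the output directory.  Every artifact directory carries a
    ``run_meta.json`` with the config hash and seed; re-running on identical
    inputs reproduces byte-identical tables.
    """
    out = Path(config.out_dir)
    if config.spectra_dir is None and config.images_dir is None:
        raise ValueError("config must point at spectra_dir and/or images_dir")
    for label, p in (("spectra_dir", config.spectra_dir), ("images_dir", config.images_dir)):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{label} does not exist: {p}")
    out.mkdir(parents=True, exist_ok=True)

    fit_df = None
    if config.spectra_dir is not None:
        with _stage("fit-eis"):
            spectra = read_spectra(config.spectra_dir)
            cal_path = Path(config.spectra_dir) / "calibration.csv"
            if config.calibration == "first":
                calibration = None
                if cal_path.exists():
                    loaded = read_spectrum_file(cal_path)
                    calibration = loaded[0] if isinstance(loaded, list) else loaded
                    spectra = [s for s in spectra if s is not calibration]
                    # calibration.csv is also matched by the directory glob;
                    # drop it from the series by identity of content.
                    spectra = [
                        s
                        for s in spectra
                        if not np.array_equal(s.frequencies, calibration.frequencies)
                        or not np.array_equal(s.z, calibration.z)
                    ]
                else:
                    spectra = sorted(
                        spectra,
                        key=lambda s: s.timepoint if s.timepoint is not None else 0.0,
                    )
                    calibration = spectra[0]
                    spectra = spectra[1:]
            else:
                loaded = read_spectrum_file(config.calibration)
                calibration = loaded[0] if isinstance(loaded, list) else loaded
            series = eis.fit_series(
                spectra, electrode_calibration=calibration, options=config.fit_options
            )
            fit_df = series.to_frame()
            write_table(out / "fit_series.csv", fit_df)

    cov_summary = None
    if config.images_dir is not None:
        with _stage("segment"):
            groups = _discover_images(Path(config.images_dir))
            mask_dir = out / "masks"
            mask_dir.mkdir(exist_ok=True)
            rows = []
            images_by_t: dict[float, list[np.ndarray]] = {}
            for t, paths in sorted(groups.items()):
                images_by_t[t] = []
                for p in paths:
                    img = read_image(p)
                    result = imaging.segment_image(img, config.pipeline, provenance=str(p))
                    write_mask(mask_dir / f"{p.stem}_t{t:g}_mask.png", result.mask)
                    rows.append(
                        {
                            "timepoint_h": t,
                            "image_id": p.stem,
                            "coverage_percent": result.coverage_percent,
                        }
                    )
                    images_by_t[t].append(img)
            write_table(out / "coverage_per_image.csv", pd.DataFrame(rows))
        with _stage("coverage"):
            per_image = pd.DataFrame(rows)
            agg = per_image.groupby("timepoint_h")["coverage_percent"]
            cov_summary = pd.DataFrame(
                {
                    "timepoint_h": sorted(images_by_t),
                    "mean_coverage": agg.mean().to_numpy(),
                    "sd_coverage": agg.std(ddof=1).fillna(0.0).to_numpy(),
                    "n_images": agg.count().to_numpy(),
                }
            )
            if config.baseline_timepoint is not None:
                base_rows = cov_summary[
                    cov_summary["timepoint_h"] == config.baseline_timepoint
                ]
                if base_rows.empty:
                    raise ValueError(
                        f"baseline timepoint {config.baseline_timepoint} h not in coverage table"
                    )
                sc_i = float(base_rows["mean_coverage"].iloc[0])
            else:
                sc_i = float(cov_summary["mean_coverage"].iloc[0])
            cov_summary["est_concentration_cells_per_ml"] = [
                imaging.estimate_concentration(config.c_i, sc_i, sc)
                for sc in cov_summary["mean_coverage"]
            ]
            write_table(out / "coverage_summary.csv", cov_summary)

    with _stage("analyze"):
        report: dict = {"config_hash": config.digest(), "seed": config.seed}
        if fit_df is not None and cov_summary is not None:
            traj = growth.combine_modalities(
                fit_df["timepoint_h"].to_numpy(),
                fit_df["c_cell_f"].to_numpy(),
                cov_summary["timepoint_h"].to_numpy(),
                cov_summary["mean_coverage"].to_numpy(),
            )
        elif fit_df is not None:
            traj = growth.GrowthTrajectory(
                timepoints=fit_df["timepoint_h"].to_numpy(),
                c_cell=fit_df["c_cell_f"].to_numpy(),
            )
        else:
            traj = growth.GrowthTrajectory(
                timepoints=cov_summary["timepoint_h"].to_numpy(),
                coverage=cov_summary["mean_coverage"].to_numpy(),
            )
        annotated = growth.annotate_phases(traj)
        write_table(out / "growth_trajectory.csv", annotated.to_frame())
        report["annotation"] = annotated.annotation_meta
        report["phase_changepoints"] = _changepoints(annotated)
        if annotated.c_cell is not None and annotated.coverage is not None:
            agreement = growth.compare_modalities(annotated, cutoff=config.cutoff_h)
            report["modality_agreement"] = agreement.to_dict()
        (out / "report.json").write_text(json.dumps(report, indent=2))

    (out / "run_meta.json").write_text(
        json.dumps({"config_hash": config.digest(), "seed": config.seed}, indent=2)
    )
    return out


def _changepoints(traj: growth.GrowthTrajectory) -> dict:
    """First timepoint of each phase present in the labels."""
    points: dict[str, float] = {}
    for t, label in zip(traj.timepoints, traj.phase_labels or ()):
        points.setdefault(label, float(t))
    return points
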