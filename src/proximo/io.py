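"""File formats and run configuration.

The canonical profile table is a CSV with the exact header
``condition,replicate,dpe,x_um,rho``: one row per profile point,
positions sorted within each (condition, replicate, dpe) profile, ρ in
[0, 1] for measured profiles (forward-model outputs may exceed 1 as
mass grows; pass ``strict=False``).  Floats are written with 9
significant digits, so a read/write round trip is value-identical at
that precision.

Scenes are written as 16-bit TIFF (fluorescence) plus 8-bit PNG
(brightfield and masks), with a JSON sidecar for ground truth and the
axis polyline.
"""

from __future__ import annotations

import datetime
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .axis import LimbScene, PDAxis
from .profiles import DensityProfile

__all__ = [
    "PROFILE_COLUMNS", "read_profiles", "write_profiles",
    "profiles_to_frame", "frame_to_profiles",
    "save_scene", "load_scene", "save_axis", "load_axis",
    "load_config", "validate_config", "write_manifest",
]

PROFILE_COLUMNS = ["condition", "replicate", "dpe", "x_um", "rho"]
_FLOAT_FMT = "%.9g"


def profiles_to_frame(profiles: list[DensityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(pd.DataFrame({
            "condition": p.condition, "replicate": p.replicate,
            "dpe": p.timepoint, "x_um": p.x, "rho": p.rho}))
    if not rows:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[PROFILE_COLUMNS]


def frame_to_profiles(df: pd.DataFrame) -> list[DensityProfile]:
    out = []
    for (cond, rep, dpe), g in df.groupby(["condition", "replicate", "dpe"],
                                          sort=True):
        out.append(DensityProfile(x=g["x_um"].to_numpy(),
                                  rho=g["rho"].to_numpy(),
                                  timepoint=float(dpe), condition=str(cond),
                                  replicate=str(rep)))
    return out


def _validate_table(df: pd.DataFrame, strict: bool) -> None:
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    extra = [c for c in df.columns if c not in PROFILE_COLUMNS]
    if extra:
        raise ValueError(f"unexpected column(s): {extra}")
    if len(df) == 0:
        return
    if strict:
        bad = df.index[(df["rho"] < 0) | (df["rho"] > 1)]
        if len(bad):
            raise ValueError(
                f"rho outside [0, 1] at row {int(bad[0])} "
                f"(value {df.loc[bad[0], 'rho']!r})")
    bad = df.index[df["x_um"] < 0]
    if len(bad):
        raise ValueError(f"negative x_um at row {int(bad[0])}")
    for key, g in df.groupby(["condition", "replicate", "dpe"], sort=False):
        x = g["x_um"].to_numpy()
        if np.any(np.diff(x) <= 0):
            row = g.index[int(np.argmax(np.diff(x) <= 0)) + 1]
            raise ValueError(f"x_um not strictly increasing within profile "
                             f"{key} at row {int(row)}")
        if g.duplicated(subset=["x_um"]).any():
            raise ValueError(f"duplicate x_um within profile {key}")


def read_profiles(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate the canonical profile CSV."""
    # keep empty condition/replicate labels as empty strings, not NaN
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    _validate_table(df, strict)
    return df


def write_profiles(table, path, strict: bool = True) -> None:
    """Write profiles (DataFrame or list of DensityProfile) to CSV."""
    if not isinstance(table, pd.DataFrame):
        table = profiles_to_frame(table)
    _validate_table(table, strict)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


# --- scenes and axes -----------------------------------------------------

def save_axis(axis: PDAxis, path) -> None:
    payload = {"points": axis.points.tolist(), "pixel_size": axis.pixel_size}
    Path(path).write_text(json.dumps(payload))


def load_axis(path) -> PDAxis:
    payload = json.loads(Path(path).read_text())
    return PDAxis(points=np.asarray(payload["points"], dtype=float),
                  pixel_size=float(payload.get("pixel_size", 1.0)))


def save_scene(scene: LimbScene, outdir, stem: str = "scene") -> dict:
    """Write a scene to ``outdir``; returns the path map."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fluorescence": outdir / f"{stem}_fluor.tif",
        "brightfield": outdir / f"{stem}_bf.png",
        "roi_mask": outdir / f"{stem}_roi.png",
        "meta": outdir / f"{stem}_meta.json",
    }
    tifffile.imwrite(paths["fluorescence"],
                     scene.fluorescence.astype(np.uint16))
    iio.imwrite(paths["brightfield"], scene.brightfield.astype(np.uint8))
    iio.imwrite(paths["roi_mask"],
                (scene.roi_mask.astype(np.uint8) * 255))
    meta = {"pixel_size": scene.pixel_size, "timepoint": scene.timepoint,
            "landmarks": scene.landmarks}
    paths["meta"].write_text(json.dumps(meta))
    for i, m in enumerate(scene.exclusion_masks):
        p = outdir / f"{stem}_excl{i}.png"
        iio.imwrite(p, m.astype(np.uint8) * 255)
        paths[f"exclusion_{i}"] = p
    return {k: str(v) for k, v in paths.items()}


def load_scene(outdir, stem: str = "scene") -> LimbScene:
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    exclusions = sorted(outdir.glob(f"{stem}_excl*.png"))
    return LimbScene(
        brightfield=iio.imread(outdir / f"{stem}_bf.png"),
        fluorescence=tifffile.imread(outdir / f"{stem}_fluor.tif"),
        roi_mask=iio.imread(outdir / f"{stem}_roi.png") > 127,
        exclusion_masks=[iio.imread(p) > 127 for p in exclusions],
        pixel_size=meta["pixel_size"], timepoint=meta["timepoint"],
        landmarks=meta.get("landmarks"))


# --- configs and manifests ----------------------------------------------

def load_config(path) -> dict:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def validate_config(cfg: dict, schema: dict) -> dict:
    """Check a config block: unknown keys rejected, required keys present.

    ``schema`` maps key -> (required: bool, type or tuple of types).
    Returns the config with defaults untouched.
    """
    unknown = set(cfg) - set(schema)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, (required, types) in schema.items():
        if key not in cfg:
            if required:
                raise ValueError(f"missing required config key: {key}")
            continue
        if types is not None and not isinstance(cfg[key], types):
            raise ValueError(
                f"config key {key!r} has type {type(cfg[key]).__name__}, "
                f"expected {types}")
    return cfg


def write_manifest(path, seed, config: dict, outputs: dict | None = None) -> None:
    """JSON run manifest: seed, package/platform versions, parameters."""
    from . import __version__

    manifest = {
        "seed": seed,
        "config": config,
        "outputs": outputs or {},
        "versions": {
            "proximo": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.datetime.now(datetime.UTC).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
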