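"""File formats: cohort/score/waveform CSV, 8-bit TIFF/PNG images with JSON
sidecars (pixel spacing, plane label, run-length-encoded masks), and YAML
specs for the three generators."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .liver import BModeImage
from .synthetic import (
    CohortConfig,
    Gaussian,
    PhantomSpec,
    Region,
    WaveformSpec,
    rect_mask,
)

# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "fasting" in df.columns:
        df["fasting"] = df["fasting"].astype(bool)
    return df


def write_trace(trace, path: str | Path) -> Path:
    df = pd.DataFrame({"time_s": trace.time, "velocity_mm_s": trace.velocity})
    return write_table(df, path)


def read_trace(path: str | Path, hr_hint: float | None = None):
    from .doppler import DopplerTrace

    df = pd.read_csv(path)
    for col in ("time_s", "velocity_mm_s"):
        if col not in df.columns:
            raise ValidationError(f"waveform CSV missing column {col!r}")
    return DopplerTrace(df["time_s"].to_numpy(),
                        df["velocity_mm_s"].to_numpy(), hr_hint=hr_hint)


# --------------------------------------------------------------------------
# images + sidecars
# --------------------------------------------------------------------------


def rle_encode(mask: np.ndarray) -> list[int]:
    """Row-major run-length encoding: alternating run lengths, 0-run first."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise ValidationError("RLE length does not match the image size")
    return flat.reshape(shape)


def save_bmode(image: BModeImage, path: str | Path) -> Path:
    """Write an 8-bit TIFF or PNG plus a same-stem ``.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = np.asarray(image.pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, pixels)
    else:
        raise ValidationError(f"unsupported image format {path.suffix!r}")
    sidecar = {
        "pixel_spacing_mm": image.pixel_spacing,
        "plane_label": image.plane_label,
        "shape": list(pixels.shape),
        "masks": {name: rle_encode(mask)
                  for name, mask in image.masks.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_bmode(path: str | Path) -> BModeImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    shape = tuple(meta["shape"])
    masks = {name: rle_decode(runs, shape)
             for name, runs in meta.get("masks", {}).items()}
    return BModeImage(pixels=pixels, pixel_spacing=meta["pixel_spacing_mm"],
                      plane_label=meta.get("plane_label"), masks=masks)


# --------------------------------------------------------------------------
# YAML generator specs
# --------------------------------------------------------------------------

_GAUSSIAN_MAP_FIELDS = ("baseline_bw", "bw_slope_base", "bw_slope_wd_extra",
                        "intake_base", "biochem_base")
_GAUSSIAN_FIELDS = ("hyperphagia_delta", "late_intake_delta", "liver_weight",
                    "liver_wd_extra")


def cohort_config_from_yaml(path: str | Path, seed: int | None = None
                            ) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _GAUSSIAN_MAP_FIELDS:
            kwargs[key] = {k: Gaussian(*v) for k, v in value.items()}
        elif key in _GAUSSIAN_FIELDS:
            kwargs[key] = Gaussian(*value)
        elif key == "biochem_wd_shift":
            kwargs[key] = {a: {int(w): Gaussian(*g) for w, g in d.items()}
                           for a, d in value.items()}
        elif key in ("ages_weeks", "biochem_weeks", "sexes", "diets",
                     "hyperphagia_window"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    if seed is not None:
        kwargs["seed"] = seed
    return CohortConfig(**kwargs)


def phantom_spec_from_yaml(path: str | Path, seed: int | None = None
                           ) -> PhantomSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    shape = tuple(raw.get("image_shape", (550, 650)))
    regions = []
    for entry in raw.get("regions", []):
        if "rect" in entry:
            mask = rect_mask(shape, *entry["rect"])
        elif "circle" in entry:
            r, c, rad = entry["circle"]
            rows = np.arange(shape[0])[:, None]
            cols = np.arange(shape[1])[None, :]
            mask = (rows - r) ** 2 + (cols - c) ** 2 <= rad**2
        else:
            raise ValidationError(
                f"region {entry.get('label')!r} needs 'rect' or 'circle'")
        regions.append(Region(entry["label"], mask, entry["target_mean"],
                              entry.get("heterogeneity_sd", 0.0)))
    kwargs = {k: raw[k] for k in ("pixel_spacing", "speckle", "psf_sigma",
                                  "background_mean", "seed") if k in raw}
    if seed is not None:
        kwargs["seed"] = seed
    return PhantomSpec(regions=regions, image_shape=shape, **kwargs)


def waveform_spec_from_yaml(path: str | Path, seed: int | None = None
                            ) -> WaveformSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        raw["seed"] = seed
    return WaveformSpec(**raw)
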