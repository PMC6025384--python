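"""Readers/writers: images, feature tables, rule sets, results, config."""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .roughset import RuleSet
from .segmentation import SegmentationConfig

__all__ = [
    "PipelineConfig",
    "load_image",
    "save_image",
    "write_feature_table",
    "read_feature_table",
    "write_rules",
    "read_rules",
    "write_results",
    "save_config",
    "load_config",
]

_LUMA = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    pass


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a [0, 1] float gray array.

    8-bit data divides by 255, 16-bit by 65535; RGB(A) collapses to gray
    with the standard luma weights (0.299, 0.587, 0.114).
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises several types
        raise ImageFormatError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        img = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        img = arr.astype(float)
    else:
        raise ImageFormatError(f"unsupported pixel type {arr.dtype} in {path}")
    if img.ndim == 3:
        if img.shape[2] >= 3:
            img = img[..., :3] @ _LUMA
        else:
            img = img[..., 0]
    if img.ndim != 2:
        raise ImageFormatError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    return np.clip(img, 0.0, 1.0)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(img * 255).astype(np.uint8))


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    """CSV with full float precision (17 significant digits)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path, require_label: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if require_label and "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    return df


def write_rules(path: str | Path, rules: RuleSet) -> None:
    Path(path).write_text(rules.to_json())


def read_rules(path: str | Path) -> RuleSet:
    return RuleSet.from_json(Path(path).read_text())


def write_results(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {o!r}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one end-to-end run."""

    segmentation: SegmentationConfig = SegmentationConfig()
    transform: str = "dwpt"
    n_bins: int = 3
    discretize_method: str = "frequency"
    n_repeats: int = 100
    train_frac: float = 2 / 3
    seed: int = 0
    log_level: str = "INFO"


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {v!r} to TOML")


def save_config(path: str | Path, cfg: PipelineConfig) -> None:
    """Minimal TOML emitter for the flat two-table config schema."""
    lines = []
    top = dataclasses.asdict(cfg)
    seg = top.pop("segmentation")
    for k, v in top.items():
        lines.append(f"{k} = {_toml_scalar(v)}")
    lines.append("")
    lines.append("[segmentation]")
    for k, v in seg.items():
        lines.append(f"{k} = {_toml_scalar(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    seg_data = data.pop("segmentation", {})
    if "seed" in seg_data:
        seg_data["seed"] = tuple(seg_data["seed"])
    seg = SegmentationConfig(**seg_data)
    return PipelineConfig(segmentation=seg, **data)
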