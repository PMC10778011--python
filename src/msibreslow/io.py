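"""Readers and writers for the pipeline's file formats.

CSV tables are comma-separated UTF-8 with a mandatory header row and '.'
decimal separator; every table and JSON report carries a metadata block
(tool version, config hash, seed).  Images are 8-bit grayscale PNGs, one
per channel with suffixes ``_AF/_G/_R/_IR``, or a single 4-page TIFF;
masks are 0/255 PNGs of the same dimensions, binarized at 128 on read.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from PIL.PngImagePlugin import PngInfo

from . import __version__
from .classify import BreslowCategory
from .errors import FormatError
from .features import CHANNEL_NAMES, FeatureVector, MultispectralImage, RoiMask
from .synthetic import CohortRecord, SimulationParams

COHORT_COLUMNS = ["lesion_id", "true_breslow_mm", "subtype", "site", "hfus_measured_mm"]
FEATURE_COLUMNS = [
    "lesion_id",
    "mean_G",
    "mean_R",
    "mean_IR",
    "circularity",
    "solidity",
    "roundness",
    "area_px",
    "perimeter_px",
    "major_axis_px",
]
PREDICTION_COLUMNS = ["lesion_id", "predicted_category", "method"]


def config_hash(obj) -> str:
    """Short stable hash of a configuration object."""
    if hasattr(obj, "to_json"):
        text = obj.to_json()
    else:
        text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _metadata_lines(seed: int | None, cfg_hash: str | None) -> list[str]:
    lines = [f"# msibreslow {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    return lines


def _write_csv(df: pd.DataFrame, path: Path, seed: int | None, cfg_hash: str | None) -> None:
    buffer = _stdio.StringIO()
    for line in _metadata_lines(seed, cfg_hash):
        buffer.write(line + "\n")
    df.to_csv(buffer, index=False, float_format="%.17g")
    Path(path).write_text(buffer.getvalue(), encoding="utf-8")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_cohort_csv(
    records: Sequence[CohortRecord], path: Path, params: SimulationParams | None = None
) -> None:
    df = pd.DataFrame(
        {
            "lesion_id": [r.lesion_id for r in records],
            "true_breslow_mm": [r.true_breslow for r in records],
            "subtype": [r.subtype for r in records],
            "site": [r.site for r in records],
            "hfus_measured_mm": [r.hfus_measured for r in records],
        }
    )
    seed = params.seed if params is not None else None
    _write_csv(df, path, seed, config_hash(params) if params is not None else None)


def read_cohort_csv(path: Path) -> list[CohortRecord]:
    df = _read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        hfus = getattr(row, "hfus_measured_mm")
        records.append(
            CohortRecord(
                lesion_id=str(row.lesion_id),
                true_breslow=float(row.true_breslow_mm),
                subtype=str(row.subtype),
                site=str(row.site),
                hfus_measured=None if pd.isna(hfus) else float(hfus),
            )
        )
    return records


def write_features_csv(
    lesion_ids: Sequence[str],
    features: Sequence[FeatureVector],
    path: Path,
    seed: int | None = None,
) -> None:
    df = features_frame(lesion_ids, features)
    _write_csv(df, path, seed, None)


def features_frame(
    lesion_ids: Sequence[str], features: Sequence[FeatureVector]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lesion_id": list(lesion_ids),
            "mean_G": [f.mean_G for f in features],
            "mean_R": [f.mean_R for f in features],
            "mean_IR": [f.mean_IR for f in features],
            "circularity": [f.circularity for f in features],
            "solidity": [f.solidity for f in features],
            "roundness": [f.roundness for f in features],
            "area_px": [f.area for f in features],
            "perimeter_px": [f.perimeter for f in features],
            "major_axis_px": [f.major_axis for f in features],
        }
    )


def read_features_csv(path: Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_predictions_csv(
    lesion_ids: Sequence[str],
    categories: Sequence[BreslowCategory],
    method: str,
    path: Path,
    seed: int | None = None,
) -> None:
    if method not in ("MSI", "HFUS"):
        raise FormatError(f"method must be MSI or HFUS, got {method!r}")
    df = pd.DataFrame(
        {
            "lesion_id": list(lesion_ids),
            "predicted_category": [c.label for c in categories],
            "method": method,
        }
    )
    _write_csv(df, path, seed, None)


def read_predictions_csv(path: Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_report_json(report_dict: dict, path: Path, seed: int | None = None, cfg_hash: str | None = None) -> None:
    payload = {
        "_meta": {"tool": f"msibreslow {__version__}", "seed": seed, "config_hash": cfg_hash},
        **report_dict,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# images


def _png_info(seed: int | None) -> PngInfo:
    info = PngInfo()
    info.add_text("Software", f"msibreslow {__version__}")
    if seed is not None:
        info.add_text("Seed", str(seed))
    return info


def write_image_set(
    directory: Path,
    lesion_id: str,
    image: MultispectralImage,
    mask: RoiMask,
    seed: int | None = None,
) -> None:
    """One 8-bit grayscale PNG per channel plus a 0/255 mask PNG."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    info = _png_info(seed)
    for name in CHANNEL_NAMES:
        Image.fromarray(image.channels[name], mode="L").save(
            directory / f"{lesion_id}_{name}.png", pnginfo=info
        )
    mask_img = (mask.grid.astype(np.uint8)) * 255
    Image.fromarray(mask_img, mode="L").save(
        directory / f"{lesion_id}_mask.png", pnginfo=info
    )


def write_image_tiff(path: Path, image: MultispectralImage) -> None:
    """Single 4-page TIFF in channel order AF, G, R, IR."""
    stack = np.stack([image.channels[c] for c in CHANNEL_NAMES])
    tifffile.imwrite(
        path, stack, photometric="minisblack", software=f"msibreslow {__version__}"
    )


def _load_gray_png(path: Path) -> np.ndarray:
    if not Path(path).exists():
        raise FormatError(f"missing file: {path}")
    with Image.open(path) as img:
        if img.mode != "L":
            raise FormatError(f"{path}: expected 8-bit grayscale, got mode {img.mode!r}")
        return np.asarray(img, dtype=np.uint8)


def read_image_set(path: Path, lesion_id: str | None = None) -> tuple[MultispectralImage, RoiMask]:
    """Load a lesion's channels and mask.

    ``path`` is either a directory holding ``<id>_AF.png`` .. ``<id>_IR.png``
    and ``<id>_mask.png`` (``lesion_id`` selects the lesion; optional when
    the directory holds exactly one), or a 4-page TIFF whose sibling
    ``<stem>_mask.png`` holds the mask.
    """
    path = Path(path)
    if path.is_dir():
        if lesion_id is None:
            masks = sorted(path.glob("*_mask.png"))
            if len(masks) != 1:
                raise FormatError(
                    f"{path}: specify lesion_id; found {len(masks)} mask files"
                )
            lesion_id = masks[0].name[: -len("_mask.png")]
        channels = {
            name: _load_gray_png(path / f"{lesion_id}_{name}.png")
            for name in CHANNEL_NAMES
        }
        mask_arr = _load_gray_png(path / f"{lesion_id}_mask.png")
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] != 4:
            raise FormatError(f"{path}: expected a 4-page TIFF, got shape {stack.shape}")
        if stack.dtype != np.uint8:
            raise FormatError(
                f"{path}: expected 8-bit data, got {stack.dtype}; refusing to truncate"
            )
        channels = dict(zip(CHANNEL_NAMES, stack))
        mask_arr = _load_gray_png(path.with_name(path.stem + "_mask.png"))
    else:
        raise FormatError(f"{path}: expected a directory or a .tif/.tiff file")

    shapes = {arr.shape for arr in channels.values()}
    if len(shapes) != 1 or mask_arr.shape not in shapes:
        raise FormatError(
            f"{path}: channel/mask dimensions differ "
            f"(channels {sorted(shapes)}, mask {mask_arr.shape})"
        )
    return MultispectralImage(channels), RoiMask.from_image(mask_arr)
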