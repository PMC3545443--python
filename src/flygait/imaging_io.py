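"""Calibrated image-stack I/O and tabular output writers/readers.

Intensities are normalized to [0, 1] internally; 8- and 16-bit integer
inputs are accepted (scaled by their dtype maximum) as well as float images.
CSV output is RFC-4180 with '.' decimal separators; distances are in
micrometres unless a column is suffixed ``_norm`` (body lengths) or
``_mm_s``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile

from .core import Calibration

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class FrameStack:
    """Ordered grayscale frames of constant shape with acquisition calibration."""

    frames: np.ndarray  # (N, H, W) float32 in [0, 1]
    calibration: Calibration

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("frames must be a non-empty (N, H, W) array")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape[1:]

    @property
    def timestamps_ms(self) -> np.ndarray:
        """Time of frame i is i / fps (first frame at t = 0)."""
        return np.arange(self.n_frames) * self.calibration.frame_interval_ms


def _normalize(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float32) / 65535.0
    return img.astype(np.float32)


def _numeric_key(name: str):
    m = re.findall(r"\d+", name)
    return (int(m[-1]) if m else -1, name)


def load_image_sequence(path, calibration: Calibration) -> FrameStack:
    """Load a directory of numbered images or a multipage TIFF.

    Directory frames are ordered by the last integer in each filename
    (numeric, not lexicographic); pages of a multipage TIFF keep file order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=lambda p: _numeric_key(p.stem),
        )
        if not files:
            raise ValueError(f"no image files found in {path}")
        frames = []
        for f in files:
            try:
                if f.suffix.lower() == ".png":
                    import imageio.v3 as iio

                    img = iio.imread(f)
                else:
                    img = tifffile.imread(f)
            except Exception as exc:  # noqa: BLE001 - report the failing file
                raise ValueError(f"unreadable image file {f}: {exc}") from exc
            if img.ndim != 2:
                raise ValueError(f"expected a 2-D grayscale image in {f}")
            frames.append(_normalize(img))
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        return FrameStack(frames=np.stack(frames), calibration=calibration)

    if path.is_file():
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"unreadable image file {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        return FrameStack(frames=_normalize(arr), calibration=calibration)

    raise ValueError(f"no such image sequence: {path}")


def write_frames(stack: FrameStack, out_dir, prefix: str = "frame") -> None:
    """Write frames as zero-padded numbered 16-bit grayscale TIFFs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(stack.n_frames - 1)))
    for i, frame in enumerate(stack.frames):
        img = np.clip(frame, 0.0, 1.0)
        tifffile.imwrite(
            out / f"{prefix}_{i:0{width}d}.tif",
            (img * 65535.0 + 0.5).astype(np.uint16),
        )


# --------------------------------------------------------------------------- #
# tabular outputs

TABLE_FILES = {
    "steps": "steps.csv",
    "params": "params.csv",
    "gaitmap": "gaitmap.csv",
    "combinations": "combinations.csv",
    "stance_traces": "stance_traces.csv",
}


def write_tables(results: Dict, out_dir) -> Dict[str, Path]:
    """Write analysis tables and ``summary.json``.

    ``results`` maps table names (see :data:`TABLE_FILES`) to DataFrames and
    may include a ``summary`` dict.  Empty DataFrames produce headers-only
    CSVs.  Values round-trip losslessly through :func:`read_table`.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}") from exc

    written: Dict[str, Path] = {}
    for name, fname in TABLE_FILES.items():
        if name in results and results[name] is not None:
            df = results[name]
            p = out / fname
            # shortest round-trip float representation keeps CSVs lossless
            df.to_csv(p, index=False, float_format=lambda x: repr(float(x)))
            written[name] = p
    if "summary" in results:
        p = out / "summary.json"
        p.write_text(json.dumps(results["summary"], indent=2, allow_nan=False,
                                default=_json_default))
        written["summary"] = p
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if np.isnan(v) else v
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())
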