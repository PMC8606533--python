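"""Image-stack and track-table I/O.

The package works on single-channel time-lapse stacks ``I(x, y, t)`` stored as
multi-frame TIFF files.  Frames are held as a ``(t, y, x)`` float or integer
array; pixel indices are 0-based with ``x`` the column and ``y`` the row.
Subpixel positions are real-valued in pixel units and converted to nanometres
only at reporting time.

Tabular results (one row per tracked comet observation) are exchanged as plain
CSV with a fixed column order, see :data:`TRACK_COLUMNS`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: Camera pixel size of the acquisition setup this package targets (nm).
DEFAULT_PIXEL_SIZE_NM = 103.0
#: Default interval between frames (s).
DEFAULT_FRAME_INTERVAL_S = 0.5


class UnsupportedFormatError(ValueError):
    """Raised for inputs that are not single-channel 2D time series."""


@dataclasses.dataclass
class ImageStack:
    """A single-channel time-lapse stack with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.  A 2D array is promoted
        to a single-frame stack.  Raw camera data are non-negative integers;
        preprocessed stacks are real-valued.
    pixel_size_nm
        Physical length of one pixel in nanometres (must be positive).
    frame_interval_s
        Time between consecutive frames in seconds (must be positive).
    """

    frames: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        if frames.ndim != 3:
            raise UnsupportedFormatError(
                f"expected a (t, y, x) stack, got array of shape {frames.shape}; "
                "multi-channel and z-stack inputs are not supported"
            )
        if frames.shape[0] < 1:
            raise UnsupportedFormatError("stack contains no frames")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        """Return a new stack with the same metadata but different pixels."""
        return ImageStack(
            frames=frames,
            pixel_size_nm=self.pixel_size_nm,
            frame_interval_s=self.frame_interval_s,
        )

    def crop(self, x0: int, y0: int, x1: int, y1: int) -> "ImageStack":
        """Crop every frame to the rectangle ``[y0:y1, x0:x1]``."""
        return self.with_frames(self.frames[:, y0:y1, x0:x1])


def _metadata_from_tiff(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Best-effort (pixel_size_nm, frame_interval_s) from TIFF/ImageJ tags."""
    pixel_size_nm = None
    frame_interval_s = None
    try:
        meta = tif.imagej_metadata or {}
        if meta.get("finterval"):
            frame_interval_s = float(meta["finterval"])
        unit = meta.get("unit", "")
        tags = tif.pages[0].tags
        if "XResolution" in tags and unit in ("um", "micron", "µm"):
            num, den = tags["XResolution"].value
            if num:
                pixel_size_nm = 1000.0 * den / num  # px/um -> nm/px
    except Exception:  # metadata is advisory only
        pass
    return pixel_size_nm, frame_interval_s


def read_stack(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a multi-frame single-channel TIFF into an :class:`ImageStack`.

    Metadata precedence: explicit argument > TIFF/ImageJ tags > package
    defaults (103 nm, 0.5 s).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedFormatError
        For multi-channel, RGB or z-stack inputs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_px, meta_dt = _metadata_from_tiff(tif)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise UnsupportedFormatError("RGB/multi-channel TIFF is not supported")
    if arr.ndim > 3:
        raise UnsupportedFormatError(
            f"TIFF has {arr.ndim} dimensions; only single-channel 2D time series "
            "are supported (no z-stacks or channels)"
        )
    px = pixel_size_nm if pixel_size_nm is not None else (meta_px or DEFAULT_PIXEL_SIZE_NM)
    dt = (
        frame_interval_s
        if frame_interval_s is not None
        else (meta_dt or DEFAULT_FRAME_INTERVAL_S)
    )
    stack = ImageStack(arr, pixel_size_nm=px, frame_interval_s=dt)
    logger.info("read %d frame(s) of %s from %s", stack.n_frames, stack.frame_shape, path)
    return stack


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as an ImageJ-compatible TIFF.

    Integer stacks are written bit-exactly; float stacks are stored as
    float32.  Pixel size and frame interval go into the ImageJ metadata so a
    later :func:`read_stack` recovers them.
    """
    frames = stack.frames
    if frames.dtype.kind in "ui":
        data = frames.astype(np.uint16) if frames.dtype != np.uint16 else frames
        if not np.array_equal(data, frames):
            data = frames  # keep original integer dtype rather than clip
    else:
        data = frames.astype(np.float32)
    px_per_um = 1000.0 / stack.pixel_size_nm
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(px_per_um, px_per_um),
        metadata={
            "unit": "um",
            "finterval": stack.frame_interval_s,
            "axes": "TYX",
        },
    )


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------

#: Fixed column order of the per-observation results table.
TRACK_COLUMNS = [
    "track_id",
    "frame_index",
    "x_end",        # fitted tip, global x (px)
    "y_end",        # fitted tip, global y (px)
    "x_max",        # brightest pixel, global x (px)
    "y_max",        # brightest pixel, global y (px)
    "L_px",         # comet decay length (px)
    "x_c_px",       # tip shift along the profile axis (px, <=0 toward head)
    "d_px",         # Gaussian PSF width (px)
    "T",            # fitted threshold offset (intensity units)
    "A",            # fitted amplitude (intensity units)
    "phi_head_rad", # head-horde angle (rad, x axis = 0)
    "residual",     # sum of squared fit residuals
    "clipped_fraction",
    "low_anisotropy",
    "crowded",
    "accepted",
    "x_end_nm",
    "y_end_nm",
    "L_nm",
]

_TRACK_DTYPES = {
    "track_id": np.int64,
    "frame_index": np.int64,
    "low_anisotropy": bool,
    "crowded": bool,
    "accepted": bool,
}


def new_track_table(rows: list[dict] | None = None) -> pd.DataFrame:
    """Create an (optionally empty) track table with the canonical columns."""
    df = pd.DataFrame(rows or [], columns=TRACK_COLUMNS)
    for col, dtype in _TRACK_DTYPES.items():
        if len(df):
            df[col] = df[col].astype(dtype)
    return df


def validate_track_table(table: pd.DataFrame) -> None:
    """Check the one-row-per-(track, frame) / increasing-frame invariants."""
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table is missing columns: {missing}")
    if len(table) == 0:
        return
    if table.duplicated(subset=["track_id", "frame_index"]).any():
        raise ValueError("duplicate (track_id, frame_index) rows")
    for tid, grp in table.groupby("track_id"):
        fi = grp["frame_index"].to_numpy()
        if not np.all(np.diff(fi) > 0):
            raise ValueError(f"frame_index not strictly increasing in track {tid}")


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as CSV in the canonical column order."""
    validate_track_table(table)
    table = table[TRACK_COLUMNS]
    table.to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track table written by :func:`write_tracks`."""
    df = pd.read_csv(path)
    for col, dtype in _TRACK_DTYPES.items():
        if col in df.columns and len(df):
            df[col] = df[col].astype(dtype)
    df = new_track_table(df.to_dict("records")) if len(df) else new_track_table()
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML config; returns the flat ``pipeline:`` namespace."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    pipeline = cfg.get("pipeline", cfg)
    if not isinstance(pipeline, dict):
        raise ValueError("'pipeline' section must be a mapping")
    return pipeline
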