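"""Calibrated image volumes, label volumes and parameter files.

Conventions used throughout the package:

* coordinates are 0-based ``(x, y, z)`` with ``z`` the plane index;
* planes are 2D arrays indexed ``[y, x]``;
* calibration ``(dx, dy, dz)`` is in micrometres per voxel and converts
  pixel measurements to the physical units used by thresholds such as the
  maximum inter-centroid distance and the volume constraints.

Volumes expose a plane accessor (:meth:`IntensityVolume.plane`) so the
segmentation pipeline never needs the full stack in memory: a volume backed
by a TIFF file reads pages lazily, and a volume backed by an array simply
views into it.  Both paths return identical values for identical voxels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityVolume",
    "LabelVolume",
    "SegmentationParams",
    "MissingFileError",
    "AxisOrderError",
    "HyperstackIndexError",
    "LabelOverflowError",
    "ParamFileError",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "load_params",
    "save_params",
]


class MissingFileError(FileNotFoundError):
    """The requested image file does not exist."""


class AxisOrderError(ValueError):
    """The TIFF axis layout could not be resolved to X/Y/Z(/C/T)."""


class HyperstackIndexError(IndexError):
    """Requested channel or timepoint outside the file's range."""


class LabelOverflowError(ValueError):
    """More instance labels than the 16-bit label format can hold."""


class ParamFileError(ValueError):
    """Malformed or inconsistent segmentation parameter file."""


def _as_zyx(data: np.ndarray) -> np.ndarray:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got shape {data.shape}")
    return data


@dataclass
class IntensityVolume:
    """A calibrated 3D intensity image (one channel, one timepoint).

    ``shape`` is ``(nx, ny, nz)`` voxel counts; ``calibration`` is
    ``(dx, dy, dz)`` in micrometres per voxel.  Intensities are stored as
    the acquisition integers (``bit_depth`` bits) but the accessor returns
    whatever dtype the backing store holds.
    """

    data: np.ndarray  # (nz, ny, nx)
    calibration: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 16
    channel_index: Optional[int] = None
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = _as_zyx(np.asarray(self.data))
        if any(c <= 0 for c in self.calibration):
            raise ValueError("calibration steps must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def plane(self, z: int) -> np.ndarray:
        """Random access to plane ``z`` as a ``[y, x]`` array."""
        if not 0 <= z < self.n_planes:
            raise IndexError(f"plane {z} outside [0, {self.n_planes})")
        return np.asarray(self.data[z])

    def voxel_volume(self) -> float:
        dx, dy, dz = self.calibration
        return dx * dy * dz


@dataclass
class LabelVolume:
    """Instance labels on the same grid as an :class:`IntensityVolume`.

    0 is background; each positive integer is one instance.  Masks are
    disjoint by construction (a voxel holds exactly one label).
    """

    data: np.ndarray  # (nz, ny, nx) integer
    calibration: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = _as_zyx(np.asarray(self.data))
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if any(c <= 0 for c in self.calibration):
            raise ValueError("calibration steps must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def plane(self, z: int) -> np.ndarray:
        return np.asarray(self.data[z])

    def ids(self) -> np.ndarray:
        """Sorted instance ids present (background excluded)."""
        u = np.unique(self.data)
        return u[u > 0]


class _TiffPlaneStore:
    """Lazy plane provider over a (z, y, x) hyperslab of a TIFF series.

    Keeps the file handle open and reads one page per request, so the whole
    stack never has to reside in memory at once.
    """

    def __init__(self, path: Path, page_indices: list[int], shape_yx: tuple[int, int], dtype):
        self._path = path
        self._pages = page_indices
        self.shape = (len(page_indices),) + shape_yx
        self.dtype = dtype

    def __getitem__(self, z):
        if isinstance(z, tuple):  # full-array style access
            raise TypeError("plane store supports plane indexing only")
        with tifffile.TiffFile(self._path) as tf:
            return tf.pages[self._pages[z]].asarray()

    @property
    def ndim(self):
        return 3


@dataclass
class _LazyVolume(IntensityVolume):
    """IntensityVolume whose data is a plane store (duck-typed array)."""

    def __post_init__(self) -> None:  # skip ndarray coercion
        if any(c <= 0 for c in self.calibration):
            raise ValueError("calibration steps must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def plane(self, z: int) -> np.ndarray:
        if not 0 <= z < self.n_planes:
            raise IndexError(f"plane {z} outside [0, {self.n_planes})")
        return np.asarray(self.data[z])

    def materialise(self) -> IntensityVolume:
        stack = np.stack([self.plane(z) for z in range(self.n_planes)])
        return IntensityVolume(stack, self.calibration, self.bit_depth,
                               self.channel_index, self.time_index)


def _guess_bit_depth(arr_dtype, sample_max: int) -> int:
    if np.dtype(arr_dtype).itemsize == 1:
        return 8
    return 12 if sample_max <= 4095 else 16


def _resolve_axes(series) -> str:
    axes = series.axes.upper().replace("S", "C").replace("Q", "Z")
    if not set(axes) <= set("TZCYX"):
        raise AxisOrderError(f"cannot resolve TIFF axes {series.axes!r}")
    if "Y" not in axes or "X" not in axes:
        raise AxisOrderError(f"TIFF axes {series.axes!r} lack a Y/X plane")
    return axes


def _read_calibration(tf: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    dx = dy = dz = None
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        if xres[0] > 0 and yres[0] > 0:
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        pass
    meta = tf.imagej_metadata or {}
    if "spacing" in meta:
        dz = float(meta["spacing"])
    if dx and dy and dz:
        return (float(dx), float(dy), float(dz))
    return None


def read_volume(path, channel: int = 0, timepoint: int = 0, *,
                lazy: bool = False) -> IntensityVolume:
    """Read one channel / timepoint of a TIFF stack as a calibrated volume.

    Axis order is taken from TIFF/ImageJ metadata when present; a plain
    multi-page file is assumed to be ZYX page order (logged).  Missing
    calibration falls back to 1 um isotropic with a warning, never an
    error.  With ``lazy=True`` planes are read from disk on demand.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        try:
            axes = _resolve_axes(series)
        except AxisOrderError:
            raise
        shp = dict(zip(axes, series.shape))
        n_c, n_t = shp.get("C", 1), shp.get("T", 1)
        n_z = shp.get("Z", 1)
        if not 0 <= channel < n_c:
            raise HyperstackIndexError(f"channel {channel} outside [0, {n_c})")
        if not 0 <= timepoint < n_t:
            raise HyperstackIndexError(f"timepoint {timepoint} outside [0, {n_t})")
        if "Z" not in axes and "C" not in axes and "T" not in axes:
            logger.info("single-plane TIFF %s read as a 1-plane volume", path)
        calib = _read_calibration(tf)
        if calib is None:
            warnings.warn(
                f"{path.name}: no pixel calibration in metadata; assuming 1 um isotropic",
                stacklevel=2,
            )
            calib = (1.0, 1.0, 1.0)
        # page index for (t, z, c) in the series' on-file order
        non_yx = [a for a in axes if a not in "YX"]
        sizes = [shp[a] for a in non_yx]
        page_indices = []
        for z in range(n_z):
            idx = {"T": timepoint, "Z": z, "C": channel}
            flat = 0
            for a, s in zip(non_yx, sizes):
                flat = flat * s + idx.get(a, 0)
            page_indices.append(flat)
        shape_yx = (shp["Y"], shp["X"])
        dtype = series.dtype
        if lazy:
            store = _TiffPlaneStore(path, page_indices, shape_yx, dtype)
            probe = store[0]
            depth = _guess_bit_depth(dtype, int(probe.max(initial=0)))
            return _LazyVolume(store, calib, depth, channel, timepoint)
        stack = np.stack([tf.pages[i].asarray() for i in page_indices])
    depth = _guess_bit_depth(stack.dtype, int(stack.max(initial=0)))
    return IntensityVolume(stack, calib, depth, channel, timepoint)


def _imagej_write(path, data, calibration) -> None:
    dx, dy, dz = calibration
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def write_volume(volume: IntensityVolume, path) -> Path:
    """Write an intensity volume as a calibrated multi-page TIFF."""
    path = Path(path)
    data = np.stack([volume.plane(z) for z in range(volume.n_planes)])
    _imagej_write(path, data, volume.calibration)
    return path


def write_label_volume(labels: LabelVolume, path) -> Path:
    """Write instance labels as a 16-bit TIFF; round-trips exactly."""
    path = Path(path)
    max_label = int(labels.data.max(initial=0))
    if max_label >= 65536:
        raise LabelOverflowError(f"label {max_label} does not fit in 16 bits")
    if int(labels.data.min(initial=0)) < 0:
        raise LabelOverflowError("negative labels are not representable")
    _imagej_write(path, labels.data.astype(np.uint16), labels.calibration)
    return path


def read_label_volume(path) -> LabelVolume:
    vol = read_volume(path)
    return LabelVolume(vol.data.astype(np.int64), vol.calibration)


# ---------------------------------------------------------------------------
# segmentation parameters


@dataclass
class SegmentationParams:
    """The user-set variables of the segmentation method.

    Pixel-unit variables (``ridge_scale``, the DoG sigmas, trace distance)
    operate on 2D planes; micrometre-unit variables (inter-centroid
    distance, volume constraints) are converted through the calibration.
    """

    smoothing_sigma: float = 0.0          # px; 0 = off
    ridge_scale: float = 1.5              # px, ~ envelope half-thickness
    dog_sigma_small: float = 1.0          # px
    dog_sigma_large: float = 3.0          # px
    seed_threshold: float = 40.0          # intensity units on the DoG plane
    min_seed_separation: float = 0.0      # px; 0 -> 2 * dog_sigma_small
    max_trace_distance: float = 200.0     # px of cumulative path length
    intensity_drop_fraction: float = 0.12  # fraction of root response
    sharp_turn_max_angle: float = 135.0   # degrees over the turn window
    turn_window: int = 5                  # steps used for the turn angle
    max_intercentroid_distance: float = 4.0  # um
    overlap_threshold: float = 0.35       # fraction in (0, 1]
    overlap_mode: str = "max"             # 'max' (default) or 'min' dialect
    max_jump: int = 2                     # planes
    min_volume: float = 40.0              # um^3
    max_volume: float = 2000.0            # um^3
    posterior_cut: float = 0.5            # classifier acceptance
    enable_ir_split: bool = True
    enable_cd_split: bool = True
    enable_smoothing: bool = True
    # plausibility gate: a nucleus volume's mean intensity must exceed the
    # image background by this fraction of the local foreground relief
    min_foreground_fraction: float = 0.25
    ir_prominence: float = 1.5
    cd_prominence: float = 3.0
    classifier_path: str = ""

    def validate(self) -> "SegmentationParams":
        if self.smoothing_sigma < 0:
            raise ParamFileError("smoothing_sigma must be >= 0")
        if self.ridge_scale <= 0:
            raise ParamFileError("ridge_scale must be > 0")
        if not 0 < self.dog_sigma_small < self.dog_sigma_large:
            raise ParamFileError("need 0 < dog_sigma_small < dog_sigma_large")
        if not 0 < self.intensity_drop_fraction < 1:
            raise ParamFileError("intensity_drop_fraction must be in (0, 1)")
        if not 0 < self.overlap_threshold <= 1:
            raise ParamFileError("overlap_threshold must be in (0, 1]")
        if self.overlap_mode not in ("max", "min"):
            raise ParamFileError("overlap_mode must be 'max' or 'min'")
        if self.max_jump < 1:
            raise ParamFileError("max_jump must be >= 1")
        if not self.min_volume < self.max_volume:
            raise ParamFileError("min_volume must be < max_volume")
        return self

    @property
    def seed_separation(self) -> float:
        return self.min_seed_separation or 2.0 * self.dog_sigma_small


def save_params(params: SegmentationParams, path) -> Path:
    """Write parameters as flat ``key = value`` text."""
    params.validate()
    path = Path(path)
    lines = []
    for f in fields(params):
        v = getattr(params, f.name)
        if isinstance(v, bool):
            v = "true" if v else "false"
        lines.append(f"{f.name} = {v}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_params(path) -> SegmentationParams:
    """Load a parameter file; unknown keys are rejected, missing keys keep
    their defaults (omitting ``smoothing_sigma`` therefore leaves smoothing
    of the input off)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    known = {f.name: f for f in fields(SegmentationParams)}
    values = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamFileError(f"{path.name}:{ln}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ParamFileError(f"{path.name}:{ln}: unknown parameter {key!r}")
        ftype = known[key].type
        try:
            if ftype == "bool":
                if val.lower() not in ("true", "false", "0", "1"):
                    raise ValueError(val)
                parsed = val.lower() in ("true", "1")
            elif ftype == "int":
                parsed = int(val)
            elif ftype == "float":
                parsed = float(val)
            else:
                parsed = val
        except ValueError as e:
            raise ParamFileError(f"{path.name}:{ln}: bad value for {key}: {val!r}") from e
        values[key] = parsed
    return replace(SegmentationParams(), **values).validate()
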