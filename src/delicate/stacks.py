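"""Plane-per-file TIFF stacks and isotropic 3D volume reconstruction.

Time-lapse confocal movies of labelled nuclei arrive as one grayscale TIFF
per focal plane per time point, named ``{name}_t{TTT}_z{ZZ}.tif`` (both
indices 1-based, zero-padded, following the AceTree-era convention).  The
voxels are strongly anisotropic (e.g. 0.09 µm in x/y vs ~0.42 µm in z), so
the first pipeline step reconstructs each time point into an isotropic
volume (default 0.18 µm) by linear interpolation along z and area-average /
linear resampling in x/y.  After enhancement the volume is re-sliced back to
the original plane geometry so the output stack is a drop-in replacement for
the input.

Physical spacings are carried in a sidecar ``manifest.json`` because plain
TIFF resolution tags are unreliable in practice.

Internals use (z, y, x) axis order and 0-based indices; file names are
1-based.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import map_coordinates
from skimage.transform import resize_local_mean

_FNAME_RE = re.compile(r"^(?P<name>.+)_t(?P<t>\d+)_z(?P<z>\d+)\.tiff?$")


@dataclass
class VoxelGrid:
    """A 3D volume with per-axis physical spacing.

    ``data`` is indexed (z, y, x); ``spacing`` is µm per voxel along the
    same axes.  ``kind`` is ``"intensity"``, ``"label"`` or ``"binary"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelGrid data must be 3D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if self.kind == "label" and not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label grids must hold integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9


@dataclass
class ImageStack:
    """Ordered 2D focal planes of one time point."""

    time: int
    planes: list[np.ndarray]
    xy_spacing: float
    z_spacing: float
    name: str = "embryo"
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("ImageStack needs at least one plane")
        shp = self.planes[0].shape
        if any(p.shape != shp for p in self.planes):
            raise ValueError("all planes must have the same shape")
        if self.xy_spacing <= 0 or self.z_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def dtype(self) -> np.dtype:
        return self.planes[0].dtype

    def as_array(self) -> np.ndarray:
        return np.stack(self.planes, axis=0)


# ---------------------------------------------------------------------------
# file naming / manifest
# ---------------------------------------------------------------------------

def plane_filename(name: str, t: int, z: int) -> str:
    """1-based file name for time point ``t``, plane ``z``."""
    return f"{name}_t{t:03d}_z{z:02d}.tif"


def write_manifest(directory: str | Path, name: str, xy_spacing: float,
                   z_spacing: float, extra: dict | None = None) -> Path:
    path = Path(directory) / f"{name}_manifest.json"
    payload = {"name": name, "xy_spacing_um": xy_spacing, "z_spacing_um": z_spacing}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_manifest(directory: str | Path, name: str) -> dict:
    path = Path(directory) / f"{name}_manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return json.loads(path.read_text())


def list_timepoints(directory: str | Path, name: str) -> list[int]:
    """Time indices (1-based) for which at least one plane file exists."""
    ts = set()
    for p in Path(directory).glob(f"{name}_t*_z*.tif*"):
        m = _FNAME_RE.match(p.name)
        if m and m.group("name") == name:
            ts.add(int(m.group("t")))
    return sorted(ts)


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_stack(directory: str | Path, name: str, t: int,
               xy_spacing: float | None = None,
               z_spacing: float | None = None) -> ImageStack:
    """Read all planes of one time point.

    Spacings default to the sidecar manifest.  Missing intermediate planes
    are an error: a gap in the z index almost always means a truncated
    transfer, and silently closing it would corrupt the geometry.
    """
    directory = Path(directory)
    if xy_spacing is None or z_spacing is None:
        man = read_manifest(directory, name)
        xy_spacing = xy_spacing or man["xy_spacing_um"]
        z_spacing = z_spacing or man["z_spacing_um"]

    found: dict[int, Path] = {}
    for p in directory.glob(f"{name}_t*_z*.tif*"):
        m = _FNAME_RE.match(p.name)
        if m and m.group("name") == name and int(m.group("t")) == t:
            found[int(m.group("z"))] = p
    if not found:
        raise FileNotFoundError(f"no planes for '{name}' at t={t} in {directory}")
    zmax = max(found)
    missing = [z for z in range(1, zmax + 1) if z not in found]
    if missing:
        raise FileNotFoundError(
            f"missing plane index(es) {missing} for '{name}' t={t}")

    planes, sources = [], []
    for z in range(1, zmax + 1):
        arr = tifffile.imread(found[z])
        if arr.ndim != 2:
            raise ValueError(f"{found[z].name}: expected a single 2D plane")
        if not np.issubdtype(arr.dtype, np.unsignedinteger):
            raise ValueError(f"{found[z].name}: unsupported sample format {arr.dtype}")
        planes.append(arr)
        sources.append(found[z].name)
    return ImageStack(time=t, planes=planes, xy_spacing=float(xy_spacing),
                      z_spacing=float(z_spacing), name=name, sources=sources)


def write_stack(stack: ImageStack, directory: str | Path,
                name: str | None = None) -> list[Path]:
    """Write one single-plane TIFF per focal plane; returns paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or stack.name
    paths = []
    for i, plane in enumerate(stack.planes):
        p = directory / plane_filename(name, stack.time, i + 1)
        tifffile.imwrite(p, plane)
        paths.append(p)
    write_manifest(directory, name, stack.xy_spacing, stack.z_spacing)
    return paths


# ---------------------------------------------------------------------------
# reconstruction / contrast / reslicing
# ---------------------------------------------------------------------------

def _n_samples(extent: float, spacing: float) -> int:
    # grid points k*spacing for k = 0..floor(extent/spacing); tolerate fp fuzz
    return int(np.floor(extent / spacing + 1e-9)) + 1


def _resample_z_linear(vol: np.ndarray, in_spacing: float,
                       target: float) -> np.ndarray:
    nz = vol.shape[0]
    extent = (nz - 1) * in_spacing
    n_out = _n_samples(extent, target)
    pos = np.arange(n_out) * target / in_spacing  # fractional input indices
    lo = np.minimum(np.floor(pos).astype(int), nz - 1)
    hi = np.minimum(lo + 1, nz - 1)
    frac = (pos - lo).astype(vol.dtype if vol.dtype.kind == "f" else np.float64)
    out = (1.0 - frac)[:, None, None] * vol[lo] + frac[:, None, None] * vol[hi]
    return out


def _resample_xy(vol: np.ndarray, in_spacing: float, target: float) -> np.ndarray:
    if abs(in_spacing - target) < 1e-12:
        return vol
    ny, nx = vol.shape[1], vol.shape[2]
    n_out_y = _n_samples((ny - 1) * in_spacing, target)
    n_out_x = _n_samples((nx - 1) * in_spacing, target)
    if target > in_spacing:
        # downsampling: area average preserves integrated intensity
        out = np.empty((vol.shape[0], n_out_y, n_out_x), dtype=np.float32)
        for k in range(vol.shape[0]):
            out[k] = resize_local_mean(vol[k].astype(np.float32), (n_out_y, n_out_x))
        return out
    # upsampling: plane-wise bilinear at physical grid positions
    yy = np.arange(n_out_y) * target / in_spacing
    xx = np.arange(n_out_x) * target / in_spacing
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    out = np.empty((vol.shape[0], n_out_y, n_out_x), dtype=np.float32)
    for k in range(vol.shape[0]):
        out[k] = map_coordinates(vol[k].astype(np.float32), [gy, gx], order=1,
                                 mode="nearest")
    return out


def reconstruct_volume(stack: ImageStack, target_spacing: float = 0.18,
                       keep_xy: bool = False) -> VoxelGrid:
    """Rebuild an isotropic 3D volume from anisotropic focal planes.

    z is resampled by linear interpolation between the two bracketing
    planes; x/y are resampled to the same target spacing (area average when
    coarsening, bilinear when refining) unless ``keep_xy``, in which case
    the native pixel grid is kept and only z is made to match it is NOT
    enforced — the caller accepts an anisotropic result.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    vol = stack.as_array().astype(np.float32)
    vol = _resample_z_linear(vol, stack.z_spacing, target_spacing)
    if keep_xy:
        return VoxelGrid(vol, (target_spacing, stack.xy_spacing, stack.xy_spacing))
    vol = _resample_xy(vol, stack.xy_spacing, target_spacing)
    return VoxelGrid(vol, (target_spacing,) * 3)


def contrast_refine(vol: VoxelGrid, p_low: float = 1.0,
                    p_high: float = 99.8) -> VoxelGrid:
    """Percentile-normalize intensities to [0, 1].

    The value at the ``p_low`` percentile maps to 0, ``p_high`` to 1, then
    the result is clipped.  A constant volume maps to all zeros.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError("need 0 <= p_low < p_high <= 100")
    data = vol.data.astype(np.float32)
    lo, hi = np.percentile(data, [p_low, p_high])
    if hi <= lo:
        return VoxelGrid(np.zeros_like(data), vol.spacing, "intensity")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return VoxelGrid(out, vol.spacing, "intensity")


def reslice(vol: VoxelGrid, stack: ImageStack) -> ImageStack:
    """Cut a volume back into the focal-plane geometry of ``stack``.

    One output plane per original plane, sampled at the original physical z
    positions (linear interpolation) and resampled back to the original
    pixel grid.  Values are rounded and clipped into the original dtype.
    """
    sz, sy, sx = vol.spacing
    extent_z = (vol.shape[0] - 1) * sz
    want_z = (stack.n_planes - 1) * stack.z_spacing
    if want_z > extent_z + max(sz, stack.z_spacing) + 1e-6:
        raise ValueError("volume does not cover the stack's z extent")

    # z sampling at original plane positions
    pos = np.arange(stack.n_planes) * stack.z_spacing / sz
    lo = np.minimum(np.floor(pos + 1e-9).astype(int), vol.shape[0] - 1)
    hi = np.minimum(lo + 1, vol.shape[0] - 1)
    frac = np.clip(pos - lo, 0.0, 1.0).astype(np.float32)
    planes3d = ((1.0 - frac)[:, None, None] * vol.data[lo].astype(np.float32)
                + frac[:, None, None] * vol.data[hi].astype(np.float32))

    # x/y back to the original pixel lattice
    ny, nx = stack.planes[0].shape
    if abs(sy - stack.xy_spacing) > 1e-12:
        yy = np.arange(ny) * stack.xy_spacing / sy
        xx = np.arange(nx) * stack.xy_spacing / sx
        gy, gx = np.meshgrid(yy, xx, indexing="ij")
        resampled = np.empty((stack.n_planes, ny, nx), dtype=np.float32)
        for k in range(stack.n_planes):
            resampled[k] = map_coordinates(planes3d[k], [gy, gx], order=1,
                                           mode="nearest")
        planes3d = resampled
    elif planes3d.shape[1:] != (ny, nx):
        raise ValueError("volume x/y shape does not match the stack geometry")

    dtype = stack.dtype
    info = np.iinfo(dtype)
    out_planes = [np.clip(np.rint(p), info.min, info.max).astype(dtype)
                  for p in planes3d]
    return ImageStack(time=stack.time, planes=out_planes,
                      xy_spacing=stack.xy_spacing, z_spacing=stack.z_spacing,
                      name=stack.name)
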