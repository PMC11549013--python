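"""Synthetic embryo generator: lineages, ground-truth volumes, degraded movies.

Emulates the failure modes that make automated lineage tracing of labelled
nuclei hard in real time-lapse confocal data:

* sphere-like nuclei of heterogeneous radii that divide on a stochastic
  cell-cycle clock, daughters displaced along a random axis with
  volume-conserving radii (r_parent / 2^(1/3));
* sublineage-specific marker dimness — a configurable fraction of founder
  cells (and all their descendants) express the marker at a fraction of the
  base level, as the D/E/germline-progenitor sublineages do with common
  histone-fusion markers;
* photobleaching (exponential intensity decay across time points);
* depth-dependent attenuation (exponential decay with z, mimicking light
  scattering in thick samples);
* Gaussian blur, mean-preserving shot noise, and additive read noise.

Every downstream stage (reconstruction, segmentation, Φ-merge, metrics,
error classification) is testable against the exact ground truth this
module also emits: integer label volumes with one label per nucleus and a
CD-file-like lineage table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .lineage import COLUMNS, LineageTable
from .stacks import ImageStack, VoxelGrid, write_manifest, write_stack

#: fluorescence base level on the unsigned 16-bit scale; leaves headroom
#: for noise before clipping.
BASE_INTENSITY = 10000.0


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the embryo simulation.

    Spatial fields are physical (µm); the grid is specified in voxels with
    per-axis spacing so anisotropic acquisition (fine x/y, coarse z) can be
    emulated.  One global RNG stream is derived from ``seed`` and split per
    operation by fixed labels, so results do not depend on call order.
    """

    grid_shape: tuple[int, int, int] = (36, 128, 128)  # voxels, (z, y, x)
    spacing: tuple[float, float, float] = (0.72, 0.36, 0.36)  # µm, (z, y, x)
    n_timepoints: int = 10
    n_founders: int = 8
    cycle_length_mean: float = 3.2  # time points
    cycle_length_sd: float = 0.4
    radius_range: tuple[float, float] = (1.8, 2.8)  # µm
    motion_sd: float = 0.25  # µm per step
    dim_fraction: float = 0.25  # fraction of founders flagged dim
    dim_factor: float = 0.3  # intensity factor of dim sublineages
    intensity_jitter_sd: float = 0.3  # per-cell lognormal expression spread
    bleach_rate: float = 0.05  # per time point
    attenuation_rate: float = 0.05  # per µm of depth
    blur_sigma: float = 0.3  # µm
    texture_sd: float = 0.5  # chromatin-like intra-nucleus mottle (relative)
    texture_scale_um: float = 0.8  # correlation length of the mottle
    n_debris: int = 6  # bright autofluorescent specks (polar-body-like)
    debris_intensity: float = 2.5  # relative to base; condensed polar-body chromatin is bright
    debris_radius_range: tuple[float, float] = (0.4, 0.6)  # µm
    shot_noise_scale: float = 0.01  # variance = scale * intensity * base
    read_noise_sd: float = 150.0  # additive, 16-bit units
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dim_factor <= 1):
            raise ValueError("dim factor must lie in (0, 1]")
        for name in ("bleach_rate", "attenuation_rate", "blur_sigma",
                     "shot_noise_scale", "read_noise_sd", "motion_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius range")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing)]
        if min(extent) < 4 * self.radius_range[1]:
            raise ValueError("grid too small for the configured nucleus radii")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))

    def rng(self, label: str) -> np.random.Generator:
        """Operation-scoped RNG split from the global seed."""
        ss = np.random.SeedSequence([self.seed,
                                     zlib.crc32(label.encode()) % (2 ** 31)])
        return np.random.default_rng(ss)


class GridOverflowError(RuntimeError):
    """A nucleus could not be placed inside the grid bounds."""


# ---------------------------------------------------------------------------
# lineage generation
# ---------------------------------------------------------------------------

def _founder_names(n: int) -> list[str]:
    return [f"F{i + 1}" for i in range(n)]


def _jitter(base: float, config: SimConfig, rng: np.random.Generator,
            half: bool = False) -> float:
    """Heritable lognormal expression spread around a lineage's base level."""
    sd = config.intensity_jitter_sd * (0.5 if half else 1.0)
    if sd <= 0:
        return base
    return float(np.clip(base * np.exp(rng.normal(0.0, sd)), 0.05, 1.0))


def generate_lineage(config: SimConfig) -> LineageTable:
    """Simulate a dividing, drifting population of nuclei.

    Founders are placed on a jittered grid with a radius margin from the
    borders; a configurable fraction of founders (deterministically the
    first ones after a seeded shuffle) is flagged dim, inherited by all
    descendants.  Divisions fire when a cell's age reaches its drawn cycle
    length; daughters get binary-suffix names (``X`` → ``Xa``, ``Xp``),
    volume-conserving radii and ±0.8·radius displacement along a random
    unit vector.  Deterministic for a fixed seed.
    """
    rng = config.rng("lineage")
    ez, ey, ex = config.extent_um
    rmin, rmax = config.radius_range
    margin = rmax * 1.1

    names = _founder_names(config.n_founders)
    n_dim = int(round(config.dim_fraction * config.n_founders))
    dim_idx = rng.permutation(config.n_founders)[:n_dim]
    dim_founders = {names[i] for i in dim_idx}

    def draw_cycle() -> float:
        return max(1.0, rng.normal(config.cycle_length_mean,
                                   config.cycle_length_sd))

    # place founders with rejection sampling against overlap
    cells: dict[str, dict] = {}
    placed: list[np.ndarray] = []
    for name in names:
        radius = rng.uniform(rmin, rmax)
        for _ in range(2000):
            pos = np.array([rng.uniform(margin, e - margin) for e in (ez, ey, ex)])
            if all(np.linalg.norm(pos - q) > 2.2 * rmax for q in placed):
                break
        else:
            raise GridOverflowError(
                f"could not place founder {name} at t=0 inside the grid")
        placed.append(pos)
        base_factor = config.dim_factor if name in dim_founders else 1.0
        cells[name] = {
            "pos": pos, "radius": radius, "birth": 0.0,
            "cycle": draw_cycle(),
            "factor": _jitter(base_factor, config, rng),
            "parent": "",
        }

    rows: list[tuple] = []

    def record(t: int, name: str, c: dict, parent: str) -> None:
        z, y, x = c["pos"]
        if not (0 <= z <= ez and 0 <= y <= ey and 0 <= x <= ex):
            raise GridOverflowError(
                f"nucleus {name} left the grid at time point {t}")
        rows.append((t, name, parent, x, y, z, c["radius"], c["factor"]))

    for t in range(config.n_timepoints):
        # record state at t (parent only on birth frame)
        for name, c in sorted(cells.items()):
            parent = c["parent"] if c["birth"] == t else ""
            record(t, name, c, parent)
        if t == config.n_timepoints - 1:
            break
        # advance to t+1: motion then divisions
        next_cells: dict[str, dict] = {}
        for name, c in sorted(cells.items()):
            drift = rng.normal(0.0, config.motion_sd, size=3)
            age = t + 1 - c["birth"]
            if age >= c["cycle"]:
                axis = rng.normal(size=3)
                axis /= max(np.linalg.norm(axis), 1e-12)
                r_d = c["radius"] / 2.0 ** (1.0 / 3.0)
                offset = 0.8 * c["radius"] * axis
                base = np.clip(c["pos"] + drift,
                               [margin] * 3, [ez - margin, ey - margin, ex - margin])
                for suffix, sgn in (("a", 1.0), ("p", -1.0)):
                    dpos = np.clip(base + sgn * offset, [r_d] * 3,
                                   [ez - r_d, ey - r_d, ex - r_d])
                    next_cells[name + suffix] = {
                        "pos": dpos, "radius": r_d, "birth": float(t + 1),
                        "cycle": draw_cycle(),
                        "factor": _jitter(c["factor"], config, rng, half=True),
                        "parent": name,
                    }
            else:
                c2 = dict(c)
                c2["pos"] = np.clip(c["pos"] + drift, [margin] * 3,
                                    [ez - margin, ey - margin, ex - margin])
                c2["parent"] = c["parent"]
                next_cells[name] = c2
        cells = next_cells

    df = pd.DataFrame(rows, columns=COLUMNS)
    return LineageTable(df)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_ground_truth(lineage: LineageTable, t: int,
                        grid_shape: tuple[int, int, int],
                        spacing: tuple[float, float, float]) -> VoxelGrid:
    """Render nuclei at time ``t`` as spheres in an integer label volume.

    Voxel v gets label i iff the physical distance from v to nucleus i's
    centre is ≤ its radius; where spheres overlap the nearest centre wins
    (ties to the lower label id).  Labels are 1-based in the row order of
    the lineage records at ``t``; 0 is background.
    """
    sub = lineage.at_time(t)
    out = np.zeros(grid_shape, dtype=np.int32)
    if sub.empty:
        return VoxelGrid(out, spacing, "label")
    centers = sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    radii = sub["radius_um"].to_numpy(dtype=float)
    sp = np.asarray(spacing, dtype=float)
    best = np.full(grid_shape, np.inf, dtype=np.float32)
    for i, (c, r) in enumerate(zip(centers, radii)):
        lo = np.maximum(np.floor((c - r) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / sp).astype(int) + 1,
                        np.array(grid_shape))
        if np.any(hi <= lo):
            continue
        ax = [np.arange(lo[d], hi[d]) * sp[d] - c[d] for d in range(3)]
        zz, yy, xx = np.meshgrid(*ax, indexing="ij")
        d2 = zz ** 2 + yy ** 2 + xx ** 2
        inside = d2 <= r * r + 1e-9
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        closer = inside & (d2 < best[sl])
        out[sl][closer] = i + 1
        best[sl][closer] = d2[closer]
    return VoxelGrid(out, spacing, "label")


def render_fluorescence(gt: VoxelGrid, lineage: LineageTable, t: int,
                        config: SimConfig) -> VoxelGrid:
    """Degrade the ground truth into a realistic fluorescence image.

    intensity = base × per-cell factor × exp(−bleach·t) × exp(−atten·depth)
    inside nuclei, 0 outside; then Gaussian blur, mean-preserving shot
    noise, additive read noise, clipped to the 16-bit range.  Deterministic
    per (seed, t).
    """
    sub = lineage.at_time(t)
    labels = gt.data
    img = np.zeros(labels.shape, dtype=np.float64)
    factors = sub["intensity_factor"].to_numpy(dtype=float)
    for i, f in enumerate(factors):
        img[labels == i + 1] = BASE_INTENSITY * f
    if config.n_debris > 0:
        # static specks of marker-rich debris (polar bodies): not part of
        # the ground truth, but bleaching and attenuating like the nuclei
        img += _debris_field(labels.shape, gt.spacing, config)
    img *= np.exp(-config.bleach_rate * t)
    if config.texture_sd > 0:
        # multiplicative chromatin-like mottle inside nuclei: smooth
        # correlated field, zero mean, clipped so intensity stays positive
        trng = config.rng(f"texture-t{t}")
        sig_vox = [config.texture_scale_um / s for s in gt.spacing]
        fld = gaussian_filter(trng.standard_normal(labels.shape), sig_vox)
        sd = fld.std()
        if sd > 0:
            fld *= config.texture_sd / sd
        img *= np.clip(1.0 + fld, 0.1, None)
    if config.attenuation_rate > 0:
        depth = np.arange(labels.shape[0]) * gt.spacing[0]
        img *= np.exp(-config.attenuation_rate * depth)[:, None, None]
    if config.blur_sigma > 0:
        sigma_vox = [config.blur_sigma / s for s in gt.spacing]
        img = gaussian_filter(img, sigma=sigma_vox)
    rng = config.rng(f"noise-t{t}")
    if config.shot_noise_scale > 0:
        var = config.shot_noise_scale * BASE_INTENSITY * np.maximum(img, 0.0)
        img = img + rng.normal(size=img.shape) * np.sqrt(var)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return VoxelGrid(img, gt.spacing, "intensity")


def _debris_field(shape, spacing, config: SimConfig) -> np.ndarray:
    """Static bright specks; positions drawn once per simulation seed."""
    rng = config.rng("debris")
    sp = np.asarray(spacing, float)
    extent = [(n - 1) * s for n, s in zip(shape, sp)]
    out = np.zeros(shape, dtype=np.float64)
    for _ in range(config.n_debris):
        # polar bodies / eggshell debris sit in the shallow layers,
        # toward the objective, where they stay conspicuous
        pos = np.array([rng.uniform(0.05 * extent[0], 0.45 * extent[0]),
                        rng.uniform(0.05 * extent[1], 0.95 * extent[1]),
                        rng.uniform(0.05 * extent[2], 0.95 * extent[2])])
        r = rng.uniform(*config.debris_radius_range)
        lo = np.maximum(np.floor((pos - r) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((pos + r) / sp).astype(int) + 1, np.array(shape))
        if np.any(hi <= lo):
            continue
        ax = [np.arange(lo[d], hi[d]) * sp[d] - pos[d] for d in range(3)]
        zz, yy, xx = np.meshgrid(*ax, indexing="ij")
        inside = zz ** 2 + yy ** 2 + xx ** 2 <= r * r
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        out[sl][inside] = config.debris_intensity * BASE_INTENSITY
    return out


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(lineage: LineageTable, images: list[VoxelGrid],
                  out_dir: str | Path, name: str = "sim") -> dict:
    """Write per-plane TIFFs plus the lineage CSV; round-trips losslessly.

    ``images`` holds one intensity volume per time point, in voxel (grid)
    geometry; planes are written with 1-based t/z indices.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {"tiffs": [], "lineage": None}
    for ti, vol in enumerate(images):
        stack = ImageStack(
            time=ti + 1,
            planes=[np.ascontiguousarray(vol.data[k]) for k in range(vol.shape[0])],
            xy_spacing=vol.spacing[2], z_spacing=vol.spacing[0], name=name)
        written["tiffs"].extend(write_stack(stack, out_dir, name))
    csv_path = out_dir / f"{name}_lineage.csv"
    lineage.to_csv(csv_path)
    written["lineage"] = csv_path
    if images:
        write_manifest(out_dir, name, images[0].spacing[2], images[0].spacing[0],
                       extra={"n_timepoints": len(images)})
    return written


def simulate(config: SimConfig) -> tuple[LineageTable, list[VoxelGrid], list[VoxelGrid]]:
    """Full simulation: lineage, GT label volumes, fluorescence volumes."""
    lin = generate_lineage(config)
    gts, raws = [], []
    for t in range(config.n_timepoints):
        gt = render_ground_truth(lin, t, config.grid_shape, config.spacing)
        gts.append(gt)
        raws.append(render_fluorescence(gt, lin, t, config))
    return lin, gts, raws


def benchmark_config(seed: int = 0) -> SimConfig:
    """The standard synthetic benchmark: 10 time points growing to ≥32
    cells, a dim sublineage at factor 0.3, bleaching and depth attenuation
    on, moderate blur and noise."""
    return SimConfig(seed=seed)


def training_config(seed: int = 0) -> SimConfig:
    """Desk-scale training volumes: single 64³ isotropic grids with a
    handful of bright, well-separated nuclei and mild degradation."""
    return replace(
        benchmark_config(seed),
        grid_shape=(64, 64, 64), spacing=(0.36, 0.36, 0.36),
        n_timepoints=1, n_founders=6, cycle_length_mean=99.0,
        dim_fraction=0.0, intensity_jitter_sd=0.1, bleach_rate=0.0,
        attenuation_rate=0.01, radius_range=(1.6, 2.6), blur_sigma=0.25,
        texture_sd=0.2, n_debris=2,
        shot_noise_scale=0.005, read_noise_sd=100.0, seed=seed,
    )
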