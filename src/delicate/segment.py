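"""Nucleus instance segmentation of isotropic volumes.

Two interchangeable backends emit the same :class:`SegmentationResult`
contract, so the enhancement stage never branches on which one produced a
segmentation:

* :class:`StarConvexNet3D` — a light 3D U-Net with residual blocks that
  predicts a per-voxel objectness probability plus 64 radial boundary
  distances in star-convex form.  Candidates are objectness local maxima
  above a (possibly auto-calibrated) probability threshold, pruned by
  greedy non-maximum suppression.  Trained with Adam/AMSGrad on the loss
  L = L_obj + η·L_dist (binary cross-entropy + masked L1), keeping the
  epoch snapshot with the smallest validation loss.

* :class:`ClassicalDetector` — a deterministic multiscale blob detector
  (difference of Gaussians) feeding a marker watershed; each watershed
  region is converted to a star-convex instance by encoding radial
  distances at its centroid.  No training required, which makes it the
  oracle backend for exercising the full pipeline at desk scale.

Both are scikit-learn style estimators (``fit``/``predict``, fitted
attributes with trailing underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

from . import nn
from .geometry import (PolyhedronSet, RaySet, encode_distances, nms,
                       rasterize, ray_directions)
from .stacks import VoxelGrid

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule for the star-convex network.

    The reference schedule is 128³ crops, 400 epochs, batch 8, Adam with
    learning rate 5e-3, weight decay 1e-5 and AMSGrad; :meth:`desk`
    returns a CPU-sized preset (32³ crops from 64³ volumes, 30 epochs,
    2 pooling levels) with identical semantics.
    """

    crop_size: int = 128
    epochs: int = 400
    batch_size: int = 8
    learning_rate: float = 5e-3
    weight_decay: float = 1e-5
    amsgrad: bool = True
    eta: float = 0.2  # distance-loss weight
    depth: int = 4
    base_channels: int = 16
    n_rays: int = 64
    augment_noise: bool = True
    augment_flip: bool = True
    noise_sd: float = 0.02
    val_fraction: float = 0.25
    crops_per_epoch: int | None = None  # default: one crop per training volume
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.crop_size % 2 ** self.depth:
            raise ValueError("crop size must be divisible by 2**depth")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        base = cls(crop_size=32, epochs=30, batch_size=2, depth=2,
                   base_channels=4, crops_per_epoch=16)
        return replace(base, **overrides) if overrides else base


@dataclass
class SegmentationResult:
    """Accepted instances plus their rasterization."""

    polys: PolyhedronSet
    labels: VoxelGrid
    threshold: float
    backend: str

    def __post_init__(self) -> None:
        n_label = int(self.labels.data.max())
        if n_label != len(self.polys):
            raise ValueError("label count must equal instance count")

    @property
    def n_instances(self) -> int:
        return len(self.polys)

    def centers_um(self) -> np.ndarray:
        """Instance centres in physical (z, y, x) µm."""
        return self.polys.centers * np.asarray(self.labels.spacing)


def _require_isotropic(vol: VoxelGrid) -> None:
    if not vol.is_isotropic:
        raise ValueError("segmentation requires an isotropic volume; "
                         "run reconstruct_volume first")


# ---------------------------------------------------------------------------
# DNN backend
# ---------------------------------------------------------------------------

class StarConvexNet3D(BaseEstimator):
    """U-Net star-convex instance segmenter.

    Parameters mirror :class:`TrainConfig`; ``nms_iou`` and
    ``prob_threshold`` control inference.  After :meth:`fit` the estimator
    exposes ``net_`` (best-validation-loss weights), ``val_losses_``,
    ``train_losses_``, ``best_epoch_``, ``rays_`` and — after
    :meth:`calibrate_threshold` — ``threshold_``.
    """

    def __init__(self, config: TrainConfig | None = None,
                 nms_iou: float = 0.3, prob_threshold: float | None = None):
        self.config = config
        self.nms_iou = nms_iou
        self.prob_threshold = prob_threshold

    # -- training ---------------------------------------------------------
    def fit(self, X: list[VoxelGrid], y: list[VoxelGrid]) -> "StarConvexNet3D":
        """Train on (contrast-refined volume, instance label) pairs.

        At least one pair is held out for validation; the returned weights
        are the epoch snapshot with the smallest validation loss, not the
        final epoch.
        """
        cfg = self.config or TrainConfig()
        if len(X) != len(y) or len(X) < 2:
            raise ValueError("need >=2 volume/label pairs (one held out)")
        for v in X:
            _require_isotropic(v)
            if min(v.shape) < cfg.crop_size:
                raise ValueError("crop size exceeds a training volume")
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        rays = ray_directions(cfg.n_rays)

        n_val = max(1, int(round(cfg.val_fraction * len(X))))
        order = rng.permutation(len(X))
        val_idx = order[:n_val]
        train_idx = order[n_val:]
        if len(train_idx) == 0:
            raise ValueError("empty training set after validation split")

        vols = [np.asarray(v.data, dtype=np.float32) for v in X]
        targets = [self._encode_targets(lab.data, rays) for lab in y]

        net = nn.UNet3D(cfg.n_rays, cfg.depth, cfg.base_channels, cfg.seed)
        opt = nn.Adam(net.params(), lr=cfg.learning_rate,
                      weight_decay=cfg.weight_decay, amsgrad=cfg.amsgrad)

        # deterministic validation crops: one foreground-centred crop per
        # validation volume
        val_crops = [self._crop(vols[i], targets[i], cfg, rng, centered=True)
                     for i in val_idx]

        self.train_losses_, self.val_losses_ = [], []
        best = (np.inf, None, -1)
        crops = cfg.crops_per_epoch or len(train_idx)
        steps = max(1, crops // max(1, cfg.batch_size))
        for epoch in range(cfg.epochs):
            perm = rng.permutation(np.repeat(train_idx,
                                             max(1, cfg.batch_size * steps
                                                 // len(train_idx) + 1)))
            ep_loss, n_steps = 0.0, 0
            for s in range(steps):
                net.zero_grad()
                batch_loss = 0.0
                for b in range(cfg.batch_size):
                    i = perm[s * cfg.batch_size + b]
                    x, obj_t, dist_t = self._crop(vols[i], targets[i], cfg, rng)
                    x, obj_t, dist_t = self._augment(x, obj_t, dist_t, cfg, rng)
                    batch_loss += self._step(net, x, obj_t, dist_t, cfg.eta)
                for _, g in net.params():
                    g /= cfg.batch_size
                opt.step()
                ep_loss += batch_loss / cfg.batch_size
                n_steps += 1
            self.train_losses_.append(ep_loss / n_steps)

            vloss = 0.0
            for x, obj_t, dist_t in val_crops:
                vloss += self._loss_only(net, x, obj_t, dist_t, cfg.eta)
            vloss /= len(val_crops)
            self.val_losses_.append(vloss)
            if vloss < best[0]:
                best = (vloss, net.get_weights(), epoch)

        net.set_weights(best[1])
        self.net_ = net
        self.best_epoch_ = best[2]
        self.rays_ = rays
        self.spacing_ = X[0].spacing
        self.config_ = cfg
        if self.prob_threshold is not None:
            self.threshold_ = float(self.prob_threshold)
        return self

    @staticmethod
    def _encode_targets(label: np.ndarray, rays: RaySet):
        obj, dist_fg = encode_distances(label, rays)
        full = np.zeros((len(rays),) + label.shape, dtype=np.float32)
        fg = np.argwhere(label > 0)
        if len(fg):
            full[:, fg[:, 0], fg[:, 1], fg[:, 2]] = dist_fg.T
        return obj.astype(np.float32), full

    @staticmethod
    def _crop(vol, targets, cfg, rng, centered: bool = False):
        obj_t, dist_t = targets
        c = cfg.crop_size
        shape = vol.shape
        if centered or rng.random() < 0.8:
            fg = np.argwhere(obj_t > 0)
            if len(fg):
                pick = fg[len(fg) // 2] if centered else fg[rng.integers(len(fg))]
                lo = np.clip(pick - c // 2, 0, np.array(shape) - c)
            else:
                lo = np.array([rng.integers(0, s - c + 1) for s in shape])
        else:
            lo = np.array([rng.integers(0, s - c + 1) for s in shape])
        sl = tuple(slice(int(l), int(l) + c) for l in lo)
        return (vol[sl][None].copy(), obj_t[sl].copy(),
                dist_t[(slice(None),) + sl].copy())

    @staticmethod
    def _augment(x, obj_t, dist_t, cfg, rng):
        if cfg.augment_flip:
            for ax in range(3):
                if rng.random() < 0.5:
                    x = np.flip(x, axis=ax + 1)
                    obj_t = np.flip(obj_t, axis=ax)
                    dist_t = np.flip(dist_t, axis=ax + 1)
            x, obj_t, dist_t = x.copy(), obj_t.copy(), dist_t.copy()
        if cfg.augment_noise:
            x = x + rng.normal(0.0, cfg.noise_sd,
                               size=x.shape).astype(np.float32)
        return x, obj_t, dist_t

    @staticmethod
    def _step(net, x, obj_t, dist_t, eta) -> float:
        logits, pre = net.forward(x.astype(np.float32), train=True)
        lobj, gobj = nn.bce_with_logits(logits, obj_t)
        ldist, gdist = nn.masked_l1(pre, dist_t, obj_t > 0.5)
        net.backward((gobj + 0.0).astype(np.float32),
                     (eta * gdist).astype(np.float32))
        return lobj + eta * ldist

    @staticmethod
    def _loss_only(net, x, obj_t, dist_t, eta) -> float:
        logits, pre = net.forward(x.astype(np.float32), train=False)
        lobj, _ = nn.bce_with_logits(logits, obj_t)
        ldist, _ = nn.masked_l1(pre, dist_t, obj_t > 0.5)
        return lobj + eta * ldist

    # -- inference --------------------------------------------------------
    def _forward_tiled(self, data: np.ndarray):
        """Objectness probability and distance maps for a whole volume."""
        cfg = self.config_
        tile = cfg.crop_size
        overlap = 8
        div = 2 ** cfg.depth
        shape = np.array(data.shape)
        prob = np.zeros(data.shape, dtype=np.float32)
        dist = np.zeros((cfg.n_rays,) + data.shape, dtype=np.float32)

        starts = [self._tile_starts(shape[a], tile, overlap) for a in range(3)]
        for z0 in starts[0]:
            for y0 in starts[1]:
                for x0 in starts[2]:
                    sl = tuple(slice(o, min(o + tile, s))
                               for o, s in zip((z0, y0, x0), shape))
                    sub = data[sl]
                    pad = [(0, -s % div) for s in sub.shape]
                    subp = np.pad(sub, pad, mode="reflect")
                    logits, pre = self.net_.forward(
                        subp[None].astype(np.float32), train=False)
                    crop = tuple(slice(0, s) for s in sub.shape)
                    p = nn.sigmoid(logits)[crop]
                    d = nn.softplus(pre)[(slice(None),) + crop]
                    # keep the max-probability prediction on tile overlaps
                    cur = prob[sl]
                    take = p > cur
                    cur[take] = p[take]
                    prob[sl] = cur
                    dv = dist[(slice(None),) + sl]
                    dv[:, take] = d[:, take]
                    dist[(slice(None),) + sl] = dv
        return prob, dist

    @staticmethod
    def _tile_starts(n: int, tile: int, overlap: int) -> list[int]:
        if n <= tile:
            return [0]
        step = tile - overlap
        starts = list(range(0, n - tile, step)) + [n - tile]
        return sorted(set(starts))

    def candidates(self, vol: VoxelGrid,
                   threshold: float) -> PolyhedronSet:
        """Local-maximum candidate extraction at a given threshold."""
        prob, dist = self._maps(vol)
        return self._extract(prob, dist, threshold)

    def _maps(self, vol: VoxelGrid):
        _require_isotropic(vol)
        return self._forward_tiled(np.asarray(vol.data, dtype=np.float32))

    MAX_CANDIDATES = 256  # bounds the NMS cost on noisy probability maps

    def _extract(self, prob, dist, threshold) -> PolyhedronSet:
        maxf = ndi.maximum_filter(prob, size=5, mode="nearest")
        peaks = np.argwhere((prob >= maxf) & (prob > threshold))
        if len(peaks) == 0:
            return PolyhedronSet.empty(self.rays_)
        scores = prob[peaks[:, 0], peaks[:, 1], peaks[:, 2]]
        if len(peaks) > self.MAX_CANDIDATES:
            top = np.argsort(-scores)[:self.MAX_CANDIDATES]
            peaks, scores = peaks[top], scores[top]
        dists = dist[:, peaks[:, 0], peaks[:, 1], peaks[:, 2]].T
        return PolyhedronSet(peaks.astype(float), dists,
                             np.clip(scores, 0, 1), self.rays_)

    def predict(self, vol: VoxelGrid,
                threshold: float | None = None) -> SegmentationResult:
        """Segment a contrast-refined isotropic volume into instances."""
        if threshold is None:
            threshold = getattr(self, "threshold_", None)
            if threshold is None:
                raise ValueError("no probability threshold: pass one or run "
                                 "calibrate_threshold first")
        prob, dist = self._maps(vol)
        cands = self._extract(prob, dist, float(threshold))
        kept = nms(cands, self.nms_iou)
        kept = self._dedupe_centers(kept)
        labels = rasterize(kept, vol.shape)
        return SegmentationResult(kept, VoxelGrid(labels, vol.spacing, "label"),
                                  float(threshold), "dnn")

    @staticmethod
    def _dedupe_centers(polys: PolyhedronSet) -> PolyhedronSet:
        """Drop candidates whose centre sits inside a stronger instance.

        Polyhedron-IoU suppression alone lets duplicate candidates with
        underestimated radii survive; two centres closer than the sum of
        the instances' mean radii cannot be two real nuclei.
        """
        n = len(polys)
        if n <= 1:
            return polys
        order = sorted(range(n), key=lambda i: (-polys.scores[i],
                                                tuple(polys.centers[i])))
        mean_r = polys.distances.mean(axis=1)
        accepted: list[int] = []
        for i in order:
            if all(np.linalg.norm(polys.centers[i] - polys.centers[j])
                   >= 1.0 * (mean_r[i] + mean_r[j]) for j in accepted):
                accepted.append(i)
        return polys.subset(accepted)

    # -- threshold calibration -------------------------------------------
    def calibrate_threshold(self, volumes: list[VoxelGrid],
                            gt_lineups: list[np.ndarray],
                            tolerance_vox: float = 6.0) -> float:
        """Pick the probability threshold maximizing instance accuracy.

        Scans 0.10..0.90 in steps of 0.05, runs full inference at each and
        keeps the threshold with the best mean TP/(TP+FP+FN) against the
        ground-truth centre lists (voxel coordinates); ties go to the
        lower threshold.
        """
        from .evaluation import match_detections, prf

        grid = np.round(np.arange(0.10, 0.901, 0.05), 2)
        maps = [self._maps(v) for v in volumes]
        best_thr, best_acc = None, -1.0
        for thr in grid:
            accs = []
            for (prob, dist), gt in zip(maps, gt_lineups):
                cands = self._extract(prob, dist, float(thr))
                kept = self._dedupe_centers(nms(cands, self.nms_iou))
                tp, fp, fn, _ = match_detections(kept.centers, np.asarray(gt),
                                                 tolerance=tolerance_vox)
                accs.append(prf(tp, fp, fn)[2])
            acc = float(np.mean(accs)) if accs else 0.0
            if acc > best_acc + 1e-12:
                best_acc, best_thr = acc, float(thr)
        self.threshold_ = best_thr
        return best_thr

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config_),
            "nms_iou": self.nms_iou,
            "threshold": getattr(self, "threshold_", None),
            "spacing": list(self.spacing_),
            "best_epoch": self.best_epoch_,
            "val_losses": self.val_losses_,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.net_.get_weights())}
        arrays["rays"] = self.rays_.directions
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "StarConvexNet3D":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError("unsupported checkpoint version")
            cfg = TrainConfig(**meta["config"])
            est = cls(config=cfg, nms_iou=meta["nms_iou"])
            net = nn.UNet3D(cfg.n_rays, cfg.depth, cfg.base_channels, cfg.seed)
            weights = [z[f"w{i}"] for i in range(len(net.params()))]
            net.set_weights(weights)
            est.net_ = net
            est.rays_ = RaySet(z["rays"])
            est.config_ = cfg
            est.spacing_ = tuple(meta["spacing"])
            est.best_epoch_ = meta["best_epoch"]
            est.val_losses_ = meta["val_losses"]
            if meta["threshold"] is not None:
                est.threshold_ = meta["threshold"]
        return est


# ---------------------------------------------------------------------------
# classical backend
# ---------------------------------------------------------------------------

class ClassicalDetector(BaseEstimator):
    """Deterministic blob-detection + watershed segmenter.

    ``intensity_scale`` fixes the normalization denominator (e.g. the
    nominal camera full scale); when ``None`` the volume maximum is used,
    which makes the detector contrast-invariant.  A *fixed* scale makes it
    sensitivity-limited like production tracers whose intensity thresholds
    are absolute — dim nuclei then genuinely drop out on raw images.
    """

    def __init__(self, min_radius_um: float = 1.2, max_radius_um: float = 3.0,
                 blob_threshold: float = 0.01, mask_fraction: float = 0.05,
                 half_fraction: float = 0.5, merge_radius_um: float | None = 1.2,
                 merge_factor: float = 0.7, seed_method: str = "edt",
                 intensity_scale: float | None = None, nms_iou: float = 0.3,
                 n_rays: int = 64):
        self.min_radius_um = min_radius_um
        self.max_radius_um = max_radius_um
        self.blob_threshold = blob_threshold
        self.mask_fraction = mask_fraction
        self.half_fraction = half_fraction
        self.merge_radius_um = merge_radius_um
        self.merge_factor = merge_factor
        self.seed_method = seed_method
        self.intensity_scale = intensity_scale
        self.nms_iou = nms_iou
        self.n_rays = n_rays

    def fit(self, X=None, y=None) -> "ClassicalDetector":
        """No training needed; present for estimator-API compatibility."""
        self.rays_ = ray_directions(self.n_rays)
        return self

    def predict(self, vol: VoxelGrid) -> SegmentationResult:
        _require_isotropic(vol)
        if self.min_radius_um >= self.max_radius_um:
            raise ValueError("empty radius range")
        if not hasattr(self, "rays_"):
            self.fit()
        spacing = vol.spacing[0]
        data = np.asarray(vol.data, dtype=np.float32)
        scale = self.intensity_scale or max(float(data.max()), 1e-9)
        img = data / scale

        # band-pass blob detection: maximum DoG response over the radius
        # range, seeds = its local maxima above the response threshold
        sig_lo = max(self.min_radius_um / spacing / np.sqrt(3.0), 1.0)
        sig_hi = max(self.max_radius_um / spacing / np.sqrt(3.0), sig_lo + 0.5)
        min_dist = max(1, int(self.min_radius_um / spacing))
        seed_set: set[tuple[int, int, int]] = set()
        if self.seed_method in ("dog", "dog-union", "both"):
            per_scale = self.seed_method == "dog-union"
            resp = None
            for sig in np.geomspace(sig_lo, sig_hi, 4):
                dog = (ndi.gaussian_filter(img, sig)
                       - ndi.gaussian_filter(img, sig * 1.6))
                if per_scale:
                    # seeds from every scale separately: sensitive and
                    # split-prone on uneven nuclei, the way production
                    # tracers behave at fixed intensity thresholds
                    pk = peak_local_max(dog, min_distance=min_dist,
                                        threshold_abs=self.blob_threshold,
                                        exclude_border=False)
                    seed_set.update(map(tuple, pk))
                resp = dog if resp is None else np.maximum(resp, dog)
            if not per_scale:
                pk = peak_local_max(resp, min_distance=min_dist,
                                    threshold_abs=self.blob_threshold,
                                    exclude_border=False)
                seed_set.update(map(tuple, pk))
        if self.seed_method in ("edt", "both"):
            # multi-level distance-transform peaks: these split touching
            # nuclei that a single intensity blob would fuse and ignore
            # intra-nucleus texture (they only see thresholded masks);
            # high levels isolate bright cores, low levels catch dim
            # nuclei, and the centroid-merge step absorbs duplicates
            rmin_vox = self.min_radius_um / spacing
            sm_seed = ndi.gaussian_filter(img, max(1.0, rmin_vox / 3.0))
            for level in np.geomspace(self.mask_fraction, 0.75, 6):
                edt = ndi.distance_transform_edt(sm_seed > level)
                pk2 = peak_local_max(edt, min_distance=max(2, int(rmin_vox)),
                                     threshold_abs=max(2.0, 0.5 * rmin_vox),
                                     exclude_border=False)
                seed_set.update(map(tuple, pk2))
        seeds = np.array(sorted(seed_set), dtype=int).reshape(-1, 3)
        if len(seeds) == 0:
            empty = PolyhedronSet.empty(self.rays_)
            return SegmentationResult(
                empty, VoxelGrid(np.zeros(vol.shape, np.int32), vol.spacing,
                                 "label"), self.blob_threshold, "classical")

        smoothed = ndi.gaussian_filter(img, sigma=sig_lo)
        mask = img > self.mask_fraction
        markers = np.zeros(vol.shape, dtype=np.int32)
        order = np.lexsort((seeds[:, 2], seeds[:, 1], seeds[:, 0]))
        for i, s in enumerate(seeds[order]):
            markers[s[0], s[1], s[2]] = i + 1
        regions = watershed(-smoothed, markers=markers, mask=mask)

        # trim each watershed region at half its near-peak brightness
        # (measured on the smoothed image, so intra-nucleus texture does
        # not fragment the region) so the instance tracks the blurred
        # sphere's half-maximum boundary instead of the blur halo
        groups: list[np.ndarray] = []
        for lbl in range(1, len(seeds) + 1):
            vox = np.argwhere(regions == lbl)
            if len(vox) < 8:  # sub-resolution speckle
                continue
            vals = smoothed[tuple(vox.T)]
            local_thr = self.half_fraction * vals.max()
            keep = vox[vals >= local_thr]
            if len(keep) >= 8:
                groups.append(keep)

        # optionally merge split detections of a single nucleus: two
        # fragments whose centroids sit closer than ~0.8x the sum of
        # their equivalent-sphere radii cannot be two real nuclei
        # (daughters are born about two radii apart); the configured
        # merge radius is the floor for tiny fragments
        if self.merge_radius_um:
            floor_vox = self.merge_radius_um / spacing
            merged = True
            while merged and len(groups) > 1:
                merged = False
                cents = np.array([g.mean(axis=0) for g in groups])
                r_eq = np.array([(3 * len(g) / (4 * np.pi)) ** (1 / 3)
                                 for g in groups])
                dmat = cdist(cents, cents)
                thr = np.maximum(floor_vox, self.merge_factor
                                 * (r_eq[:, None] + r_eq[None, :]))
                np.fill_diagonal(dmat, np.inf)
                gap = dmat - thr
                i, j = np.unravel_index(np.argmin(gap), gap.shape)
                if gap[i, j] < 0:
                    groups[i] = np.vstack([groups[i], groups[j]])
                    del groups[j]
                    merged = True

        # instances smaller than a sphere of ~0.8x the minimum radius are
        # sub-nuclear specks (debris, polar bodies), not nuclei
        size_floor = max(8, int(4.0 / 3.0 * np.pi
                                * (0.8 * self.min_radius_um / spacing) ** 3))
        refined = np.zeros_like(regions)
        centers, scores, keep_labels = [], [], []
        lbl_next = 0
        for keep in groups:
            if len(keep) < size_floor:
                continue
            lbl_next += 1
            refined[tuple(keep.T)] = lbl_next
            centers.append(keep.mean(axis=0))
            scores.append(min(1.0, float(smoothed[tuple(keep.T)].mean())))
            keep_labels.append(lbl_next)
        regions = refined
        if not centers:
            empty = PolyhedronSet.empty(self.rays_)
            return SegmentationResult(
                empty, VoxelGrid(np.zeros(vol.shape, np.int32), vol.spacing,
                                 "label"), self.blob_threshold, "classical")

        cvox = np.rint(np.array(centers)).astype(int)
        # snap centroids that fell outside their region back onto it
        for i, lbl in enumerate(keep_labels):
            if regions[tuple(cvox[i])] != lbl:
                vox = np.argwhere(regions == lbl)
                j = np.argmin(((vox - centers[i]) ** 2).sum(axis=1))
                cvox[i] = vox[j]
        _, dists = encode_distances(regions, self.rays_, voxels=cvox)
        # reject sub-nuclear instances by star-convex extent: specks have
        # mean radii well under the minimum credible nucleus radius
        mean_r = dists.mean(axis=1)
        ok = mean_r >= 0.8 * self.min_radius_um / spacing
        if not ok.all():
            centers = [c for c, k in zip(centers, ok) if k]
            scores = [s for s, k in zip(scores, ok) if k]
            dists = dists[ok]
            if not centers:
                empty = PolyhedronSet.empty(self.rays_)
                return SegmentationResult(
                    empty, VoxelGrid(np.zeros(vol.shape, np.int32),
                                     vol.spacing, "label"),
                    self.blob_threshold, "classical")
        polys = PolyhedronSet(np.array(centers), dists, np.array(scores),
                              self.rays_)
        kept = nms(polys, self.nms_iou)
        labels = rasterize(kept, vol.shape)
        return SegmentationResult(kept, VoxelGrid(labels, vol.spacing, "label"),
                                  self.blob_threshold, "classical")


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train(volumes: list[VoxelGrid], labels: list[VoxelGrid],
          config: TrainConfig | None = None) -> StarConvexNet3D:
    return StarConvexNet3D(config=config).fit(volumes, labels)


def predict_instances(model: StarConvexNet3D, vol: VoxelGrid,
                      threshold: float | None = None) -> SegmentationResult:
    return model.predict(vol, threshold)


def auto_threshold(model: StarConvexNet3D, volumes: list[VoxelGrid],
                   gt_centers: list[np.ndarray], **kw) -> float:
    return model.calibrate_threshold(volumes, gt_centers, **kw)


def classical_segment(vol: VoxelGrid, **params) -> SegmentationResult:
    return ClassicalDetector(**params).fit().predict(vol)
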