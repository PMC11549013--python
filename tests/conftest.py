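"""Shared fixtures: the standard synthetic benchmark and a desk-trained model.

Both are expensive, so they are computed once per session.  All data is
generated programmatically; nothing is read from disk except what the
tests themselves write to tmp directories.
"""

from __future__ import annotations

import numpy as np
import pytest

import delicate as d
from delicate.evaluation import SliceLinkTracer
from delicate.segment import ClassicalDetector, StarConvexNet3D, TrainConfig
from delicate.stacks import ImageStack, contrast_refine
from delicate.synthetic import training_config

BENCHMARK_SEED = 0


def stack_from_volume(vol, t=1, name="sim"):
    """Wrap a simulated (anisotropic) volume as an ImageStack."""
    return ImageStack(
        time=t,
        planes=[np.ascontiguousarray(vol.data[k]) for k in range(vol.shape[0])],
        xy_spacing=vol.spacing[2], z_spacing=vol.spacing[0], name=name)


@pytest.fixture(scope="session")
def benchmark():
    """The standard benchmark: simulate, enhance, evaluate raw vs enhanced.

    Ten time points growing to >=32 cells, a dim sublineage at factor 0.3,
    bleaching, depth attenuation, texture and debris on; classical backend;
    one fixed tracer configuration applied to raw and enhanced stacks.
    """
    cfg = d.SimConfig(seed=BENCHMARK_SEED)
    lineage, gts, raws = d.simulate(cfg)
    backend = ClassicalDetector().fit()
    tracer = SliceLinkTracer()
    rows = []
    for t in range(cfg.n_timepoints):
        stack = stack_from_volume(raws[t], t + 1)
        enh_stack, res = d.enhance_timepoint(stack, backend,
                                             target_spacing=0.36)
        vol = d.reconstruct_volume(stack, 0.36)
        gt = d.render_ground_truth(lineage, t, vol.shape, vol.spacing)
        ref = d.reference_image(gt.data, float(vol.data.max()))
        row = {"t": t, "n_cells": lineage.cell_count(t),
               "n_instances": res.n_instances}
        for kind, stk, v in (("raw", stack, vol),
                             ("enh", enh_stack, res.volume)):
            centers = tracer.detect_centers(stk)
            tp, fp, fn, _ = d.match_detections(
                centers, lineage.positions(t), gt_radii=lineage.radii(t))
            prec, rec, acc = d.prf(tp, fp, fn)
            row[kind] = {
                "mse": d.mse(v.data, ref),
                "snr": d.snr(v.data, gt.data > 0),
                "tp": tp, "fp": fp, "fn": fn,
                "precision": prec, "recall": rec, "accuracy": acc,
                "centers": centers,
            }
        rows.append(row)
    return {"config": cfg, "lineage": lineage, "rows": rows}


@pytest.fixture(scope="session")
def training_set():
    """Eight easy 64-cube volumes with ground-truth labels and lineages."""
    vols, labs, lineages = [], [], []
    for i in range(8):
        cfg = training_config(seed=100 + i)
        lineage, gts, raws = d.simulate(cfg)
        vols.append(contrast_refine(raws[0]))
        labs.append(gts[0])
        lineages.append(lineage)
    return vols, labs, lineages


@pytest.fixture(scope="session")
def desk_model(training_set):
    """Star-convex network trained with the desk preset (30 epochs)."""
    vols, labs, _ = training_set
    cfg = TrainConfig.desk(seed=0)
    model = StarConvexNet3D(config=cfg).fit(vols, labs)
    return model


@pytest.fixture(scope="session")
def heldout_easy():
    """A held-out easy volume (well-separated bright spheres, high SNR)."""
    cfg = training_config(seed=999)
    lineage, gts, raws = d.simulate(cfg)
    return contrast_refine(raws[0]), gts[0], lineage
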