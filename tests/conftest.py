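"""Shared fixtures: the default synthetic cohort and its derived products.

The expensive session-scoped fixtures (16-subject cohort, per-subject seed
connectivity, per-subject parcellation) are computed once and shared by the
unit, property and acceptance tests.
"""

import numpy as np
import pytest

from restparc import parcellation as parc
from restparc import preprocess as pp
from restparc import seedfc
from restparc import synthetic as syn


@pytest.fixture(scope="session")
def default_atlas():
    return syn.make_default_atlas()


@pytest.fixture(scope="session")
def default_cohort(default_atlas):
    """16 subjects, 200 volumes, TR 2 s, snr 1, seed 42."""
    cfg = syn.SimulationConfig(seed=42)
    runs, truth = syn.simulate_cohort(cfg, default_atlas)
    return cfg, runs, truth


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects on a small grid for fast unit tests."""
    atlas = syn.make_default_atlas(grid_shape=(16, 16, 12))
    cfg = syn.SimulationConfig(n_subjects=4, n_volumes=120, seed=7)
    runs, truth = syn.simulate_cohort(cfg, atlas)
    return atlas, cfg, runs, truth


@pytest.fixture(scope="session")
def fc_maps(default_atlas, default_cohort):
    """Per-subject seed-connectivity stat maps and binary positive maps."""
    _, runs, _ = default_cohort
    rois = seedfc.default_seed_rois(default_atlas)
    k_thr = seedfc.monte_carlo_cluster_threshold(
        runs[0].brain_mask, 8.0, default_atlas.voxel_size_mm,
        voxel_p=0.01, alpha=0.05, n_iter=500, seed=1,
    )
    stat_maps = []
    binary_pos = {roi.label: [] for roi in rois}
    for run in runs:
        frun = pp.preprocess_run(run, 0.01, 0.1, fwhm_mm=8.0, smooth=True)
        maps = seedfc.seed_fc_map(frun, rois)
        stat_maps.append(maps)
        for lab, sm in maps.items():
            thr = seedfc.threshold_clusters(sm, 0.01, k_thr)
            binary_pos[lab].append((thr.labels > 0).astype(float))
    return {"rois": rois, "k": k_thr, "stat_maps": stat_maps, "binary_pos": binary_pos}


@pytest.fixture(scope="session")
def parcellations(default_atlas, default_cohort):
    """Per-subject PCA-reduced target matrices and c = 4 partitions."""
    _, runs, _ = default_cohort
    reduced, raw, partitions = [], [], []
    voxel_index = None
    for run in runs:
        prun = pp.preprocess_run(run, 0.01, 0.1, smooth=False)
        X, voxel_index = parc.target_timecourses(prun, default_atlas.target_mask)
        red, _, kept = parc.pca_reduce(X, 0.9)
        voxel_index = voxel_index[kept]
        best = None
        for r in range(10):
            s = int(
                np.random.SeedSequence(entropy=42, spawn_key=(999, r))
                .generate_state(1)[0] % (2**31)
            )
            p = parc.fcm(red, 4, seed=s, metric="cosine")
            if best is None or p.objective < best.objective:
                best = p
        reduced.append(red)
        raw.append(X[kept])
        partitions.append(best)
    return {
        "reduced": reduced,
        "raw": raw,
        "partitions": partitions,
        "voxel_index": voxel_index,
    }
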