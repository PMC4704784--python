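import numpy as np
import pytest

import bbquant as bq


def star_polygon(rng, center=(8.0, 8.0), r_mean=5.0, n_vertices=8):
    """A random simple (star-shaped) polygon around a center point."""
    # jittered evenly spaced angles keep every angular gap well below pi,
    # which (with bounded radius variation) guarantees a simple polygon
    angles = (np.arange(n_vertices) + rng.uniform(0.05, 0.95, n_vertices)) * (
        2 * np.pi / n_vertices
    )
    radii = rng.uniform(0.4, 1.0, n_vertices) * r_mean
    # offset vertices off the integer lattice so no pixel center sits on an edge
    return np.stack(
        [
            center[0] + radii * np.cos(angles) + 0.137,
            center[1] + radii * np.sin(angles) + 0.211,
        ],
        axis=1,
    )


def random_blob(rng, shape=(10, 12, 12), p=0.12):
    """Sparse random boolean volume for component/labeling tests."""
    return rng.random(shape) < p


@pytest.fixture(scope="session")
def cleft_recovery():
    """Median recovered fold per generative enrichment factor (50 oocytes each).

    Session-scoped: shared by the parameter-recovery and monotonicity checks.
    """
    cfg = bq.default_config("cleft")
    medians = {}
    folds_by_factor = {}
    for factor in (1.0, 1.6, 2.0, 5.0):
        folds = []
        for s in range(50):
            spec = bq.SyntheticSpec(mode="oocyte_cleft", enrichment_factor=factor)
            stack, rois, _ = bq.generate_oocyte(spec, seed=10_000 + s)
            res = bq.analyze_cleft(stack, rois.units[0], cfg)
            assert res.fold is not None
            folds.append(res.fold)
        medians[factor] = float(np.median(folds))
        folds_by_factor[factor] = folds
    return medians, folds_by_factor


@pytest.fixture(scope="session")
def nest_recovery():
    """Recovered folds for 50 eight-cell nests at generative factor 1.6."""
    cfg = bq.default_config("nest")
    folds = []
    for s in range(50):
        spec = bq.SyntheticSpec(mode="nest", n_cells=8, enrichment_factor=1.6)
        stack, rois, _ = bq.generate_nest(spec, seed=20_000 + s)
        res = bq.analyze_nest(stack, rois.units[0], cfg)
        assert res.fold is not None
        folds.append(res.fold)
    return folds


@pytest.fixture(scope="session")
def null_nests():
    """Twenty nests with a spatially uniform experimental channel."""
    cfg = bq.default_config("nest")
    results = []
    for s in range(20):
        spec = bq.SyntheticSpec(mode="dispersed_control", n_cells=8)
        stack, rois, _ = bq.generate_nest(spec, seed=30_000 + s)
        results.append(bq.analyze_nest(stack, rois.units[0], cfg))
    return results


@pytest.fixture
def small_oocyte():
    """A quick-to-render oocyte stack for plumbing tests."""
    spec = bq.SyntheticSpec(mode="oocyte_cleft", cell_diameter_um=14.0, enrichment_factor=2.0)
    return bq.generate_oocyte(spec, seed=7), spec
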