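"""Shared fixtures: simulated state pools, inference fixtures, toy ensembles.

Heavy simulation products are session-scoped so the polymer sampler runs
once per object; constructed (non-simulated) fixtures are cheap and rebuilt
per test where mutation is a risk.
"""

import warnings

import numpy as np
import pytest

from sbsphase.core import (
    Ensemble,
    PolymerModel,
    SimulationParams,
    simulate_ensemble,
)
from sbsphase.metrics import DistanceMatrix, ensemble_distance_matrices
from sbsphase.prismr import forward_contact_map, get_templates
from sbsphase.synth import generate_coloring, synthesize_hic


@pytest.fixture(scope="session")
def templates60():
    return get_templates(60, 1)


@pytest.fixture(scope="session")
def truth60():
    return generate_coloring(60, 3, 1, seed=5)


@pytest.fixture(scope="session")
def clean60(truth60, templates60):
    return forward_contact_map(truth60.model, templates60)


@pytest.fixture(scope="session")
def noisy60(clean60):
    return synthesize_hic(clean60, depth=1e4, seed=9)


def _interleaved_model(n_windows=40, block=10):
    reps = n_windows // block
    colors = np.concatenate(
        [np.full(block, 1 + k % 2, dtype=np.int64) for k in range(reps)]
    )
    return PolymerModel(colors=colors, n=2)


@pytest.fixture(scope="session")
def state_pools():
    """260-molecule coil and globule pools of a 40-window 2-color chain.

    The globule pool is prepared in its basin (compact starts) at the top of
    the scanned concentration range; the coil pool from open starts at a
    near-zero concentration.  Both carry their state label.
    """
    model = _interleaved_model()
    base = dict(
        n_steps=9000,
        equilibration_steps=6000,
        samples_per_chain=10,
        decorrelation_sweeps=250,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coil = simulate_ensemble(
            model, SimulationParams(concentration=0.005e-6, seed=101, **base), 260
        )
        globule = simulate_ensemble(
            model,
            SimulationParams(
                concentration=0.5e-6, seed=202, initial_state="compact", **base
            ),
            260,
        )
    coil.state_label = "coil"
    globule.state_label = "globule"
    return coil, globule


@pytest.fixture(scope="session")
def state_pool_matrices(state_pools):
    coil, globule = state_pools
    return ensemble_distance_matrices(coil), ensemble_distance_matrices(globule)


def make_ball_matrices(
    n_molecules=80,
    n_windows=64,
    block=16,
    separation=9.0,
    jitter=0.3,
    seed=1234,
):
    """Distance matrices of molecules folded into well-separated block balls.

    Deterministic block-copolymer-like geometry: windows of each block
    cluster tightly around a block center, centers sit far apart, so the
    separation profile dips exactly at the designed junctions and nowhere
    else (the small jitter leaves no spurious internal structure).
    """
    rng = np.random.default_rng(seed)
    n_blocks = n_windows // block
    mats = []
    for _ in range(n_molecules):
        centers = rng.normal(scale=0.25, size=(n_blocks, 3))
        centers += separation * np.eye(3)[np.arange(n_blocks) % 3] * (
            1 + np.arange(n_blocks)
        )[:, None]
        coords = np.empty((n_windows, 3))
        for b in range(n_blocks):
            # each block is a short straight fiber segment: within-block
            # distance grows linearly with genomic separation, so the
            # decay-corrected separation profile is exactly flat inside
            # blocks and dips only at the designed junctions
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offsets = (np.arange(block) - (block - 1) / 2)[:, None] * 0.12
            coords[b * block : (b + 1) * block] = (
                centers[b] + offsets * direction
            )
        coords = coords + rng.normal(scale=jitter * 0.05, size=coords.shape)
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        mats.append(DistanceMatrix(values=d))
    return mats


@pytest.fixture(scope="session")
def ball_matrices():
    return make_ball_matrices()


@pytest.fixture(scope="session")
def coil40_matrices():
    from sbsphase.core import saw_ensemble

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ens = saw_ensemble(40, 200, seed=77)
    ens.model = PolymerModel(colors=np.zeros(40, dtype=np.int64), n=0, r=1)
    return ensemble_distance_matrices(ens)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
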