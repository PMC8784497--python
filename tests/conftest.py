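"""Shared fixtures.

The expensive artefacts (registrations, a memorization training run, the
cross-validated phantom experiment) are session-scoped and shared between
the unit tests and the acceptance suite, so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from psoasseg import (
    BinaryMask,
    ImageVolume,
    PhantomParams,
    generate_case,
    generate_cohort,
)
from psoasseg.gan import GanConfig, build_slice_samples, train
from psoasseg.mas import Atlas, register_pair


def random_mask(rng: np.random.Generator, shape=(4, 8, 8), p=0.3,
                spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p, spacing)


@pytest.fixture(scope="session")
def desk_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def phantom_case(desk_params):
    """One deterministic phantom exam with its ground truth."""
    return generate_case(desk_params, 5)


@pytest.fixture(scope="session")
def small_cohort(desk_params):
    return generate_cohort(4, desk_params, master_seed=3)


@pytest.fixture(scope="session")
def self_registration(desk_params):
    """Registering an exam onto itself (identity recovery)."""
    vol, gt = generate_case(desk_params, 11)
    atlas = Atlas(vol, gt, "self")
    return register_pair(vol, atlas, seed=1), vol, gt


@pytest.fixture(scope="session")
def translation_recovery(desk_params):
    """Target is the atlas translated by (4, 4, 0) voxels, rigid content."""
    vol, gt = generate_case(desk_params, 11)
    shifted = ImageVolume(
        np.roll(np.roll(vol.voxels, 4, axis=1), 4, axis=2),
        desk_params.spacing, case_id="shifted",
    )
    shifted_gt = BinaryMask(
        np.roll(np.roll(gt.voxels, 4, axis=1), 4, axis=2),
        desk_params.spacing, case_id="shifted",
    )
    outcome = register_pair(shifted, Atlas(vol, gt, "atlas"), seed=1)
    return outcome, gt, shifted, shifted_gt


@pytest.fixture(scope="session")
def energy_ordering(desk_params):
    """Three candidate atlases, one identical to the target."""
    vol, gt = generate_case(desk_params, 11)
    atlases = [Atlas(vol, gt, "identical")]
    for s in (21, 22):
        av, am = generate_case(desk_params, s)
        atlases.append(Atlas(av, am, f"other_{s}"))
    outcomes = [register_pair(vol, a, seed=1) for a in atlases]
    return outcomes, gt


@pytest.fixture(scope="session")
def memorization_run(phantom_case):
    """Single-case overfit: 30 epochs on one exam's 22 slice samples."""
    vol, gt = phantom_case
    cfg = GanConfig.desk(epochs=30, seed=0)
    samples = build_slice_samples(vol, gt, cfg)
    result = train(samples, cfg)
    return result, cfg, vol, gt


@pytest.fixture(scope="session")
def phantom_experiment(desk_params):
    """Cross-validated desk experiment: 10 phantoms, 5 folds."""
    from psoasseg.evalstats import run_experiment

    cohort = generate_cohort(10, desk_params, master_seed=1)
    table, summary = run_experiment(cohort, k=5, seed=1)
    return table, summary
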