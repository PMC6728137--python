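"""Shared fixtures: registries, recombination specs, and the session-scoped
training study reused by the model-level statistical tests."""

from __future__ import annotations

import numpy as np
import pytest

import tcrvae as tv


@pytest.fixture(scope="session")
def registry() -> tv.GeneRegistry:
    return tv.GeneRegistry.default()


@pytest.fixture(scope="session")
def spec() -> tv.RecombSpec:
    return tv.default_spec()


@pytest.fixture(scope="session")
def plant(spec) -> tv.PlantedSelection:
    return tv.default_planted_selection(spec)


@pytest.fixture(scope="session")
def tiny_spec() -> tv.RecombSpec:
    """Fully enumerable spec (two insertion residues, short insertions)."""
    return tv.RecombSpec(
        v_choices=[
            tv.SegmentChoice("TCRBV05-01", 0.6, "CAS", {0: 0.7, 1: 0.3}),
            tv.SegmentChoice("TCRBV30-01", 0.4, "CAW", {0: 1.0}),
        ],
        j_choices=[
            tv.SegmentChoice("TCRBJ01-01", 0.5, "EAFF", {0: 0.8, 1: 0.2}),
            tv.SegmentChoice("TCRBJ01-02", 0.5, "GYTF", {0: 1.0}),
        ],
        insertion_length_pmf={0: 0.5, 1: 0.3, 2: 0.2},
        insertion_residue_pmf={"S": 0.6, "T": 0.4},
        max_cdr3_length=30,
    )


@pytest.fixture(scope="session")
def training_study(spec, plant, registry):
    """The scaled-down frequency-prediction study: a basic model trained on
    5,000 sequences simulated from the default spec with planted selection,
    plus held-out evaluation draws.  Trained once per session."""
    train_data = tv.sample_with_selection(spec, plant, 5000, seed=101)
    held_500 = tv.sample_with_selection(spec, plant, 500, seed=202)
    held_200 = tv.sample_with_selection(spec, plant, 200, seed=303)
    model, report = tv.train(
        train_data, "basic", tv.TrainConfig(seed=7), registry=registry
    )
    return {
        "model": model,
        "report": report,
        "train_data": train_data,
        "held_500": held_500,
        "held_200": held_200,
    }


@pytest.fixture(scope="session")
def selection_study(spec, plant):
    """Selection-stack study: Q fitted on 10^5 planted-selection draws, a
    null fit on unselected draws, and a 10^5 rejection sample from the
    fitted table.  Computed once per session."""
    n = 100_000
    data = tv.sample_with_selection(spec, plant, n, seed=11)
    qtable = tv.fit_q(data, spec, q_max=8.0)
    null_data = tv.sample_recomb(spec, n, seed=12)
    null_qtable = tv.fit_q(null_data, spec, q_max=8.0)
    resampled = tv.rejection_sample(spec, qtable, n, seed=13)
    return {
        "n": n,
        "qtable": qtable,
        "null_qtable": null_qtable,
        "resampled": resampled,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
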