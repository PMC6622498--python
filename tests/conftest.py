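"""Shared fixtures: tiny hand-built inputs plus one small simulated cohort."""

import warnings

import numpy as np
import pytest

import lexgaze as lg
from lexgaze import gaze as G
from lexgaze import model as M
from lexgaze.network import FeatureNorms, NormsAdjacency
from lexgaze.simulate import gen_norms, make_checklist
from lexgaze.vocab import ChecklistDefinition


@pytest.fixture(scope="session")
def full_checklist():
    return make_checklist()


@pytest.fixture(scope="session")
def shared_norms(full_checklist):
    """One norms database shared across simulated cohorts, like a real study."""
    return gen_norms(lg.SimConfig(seed=999), full_checklist)


@pytest.fixture(scope="session")
def shared_adjacency(shared_norms):
    return NormsAdjacency(shared_norms)


@pytest.fixture(scope="session")
def small_cohort(shared_norms, shared_adjacency):
    """A 20-child cohort under default generative settings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lg.simulate_cohort(
            lg.SimConfig(seed=5, n_children=20),
            norms=shared_norms,
            adjacency=shared_adjacency,
        )


@pytest.fixture(scope="session")
def small_design(small_cohort):
    accs = [G.trial_log_gaze(t) for t in small_cohort.trials]
    retained, _ = G.filter_trials(small_cohort.trials, accs)
    return M.build_design(
        retained,
        small_cohort.metrics,
        small_cohort.density,
        small_cohort.groups,
        lg.EXPERIMENTAL_ITEMS,
    )


@pytest.fixture
def toy_checklist():
    """Six experimental categories at two items each."""
    items = {}
    for cat in lg.EXPERIMENTAL_CATEGORIES:
        stem = cat.lower().replace("-", "_")
        items[f"{stem}_a"] = cat
        items[f"{stem}_b"] = cat
    return ChecklistDefinition(items=items)


@pytest.fixture
def toy_norms():
    """Five concepts with a hand-built shared-feature matrix.

    Qualifying (perceptual/functional) shared-feature counts:
      a-b: 2, a-c: 1, a-d: 0, a-e: 2, b-c: 3, b-d: 0, b-e: 0,
      c-d: 2, c-e: 0, d-e: 0
    All concepts also share one taxonomic feature, which must not count.
    """
    return FeatureNorms(features={
        "a": {"p1": "perceptual", "p2": "perceptual",
              "pe1": "perceptual", "pe2": "functional", "tax": "taxonomic"},
        "b": {"p1": "perceptual", "p2": "perceptual", "f1": "functional",
              "f2": "functional", "tax": "taxonomic"},
        "c": {"p2": "perceptual", "f1": "functional", "f2": "functional",
              "pc1": "perceptual", "pc2": "functional", "tax": "taxonomic"},
        "d": {"pc1": "perceptual", "pc2": "functional", "tax": "taxonomic"},
        "e": {"pe1": "perceptual", "pe2": "functional", "tax": "taxonomic"},
    })


def make_trial(states, trial_id="t0", child="c0", rating=4, condition="related",
               target="dog", distractor="bird"):
    """Build a GazeTrial from an int state-code sequence at 2 ms spacing."""
    states = np.asarray(states, dtype=np.int8)
    return G.GazeTrial(
        trial_id=trial_id,
        child_id=child,
        condition=condition,
        target=target,
        distractor=distractor,
        comprehension_rating=rating,
        times=np.arange(len(states)) * G.SAMPLE_MS,
        states=states,
    )
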