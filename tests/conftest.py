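"""Shared builders for synthetic study designs used across the suite."""

import numpy as np
import pytest

import larvodec as lv


def make_trial(neuron="n0", odor="oA", stim=10, spont=(2, 3, 1, 0, 4, 2, 3, 1, 2, 0), **kw):
    return lv.TrialRecord(neuron, odor, stim, tuple(spont), **kw)


def uniform_tuning_spec(n_neurons, n_odors, trials_per_pair, seed, mu=20.0, sigma=4.0,
                        spont_mean=3.0):
    """Every (neuron, odor) pair responds with the *same* distribution:
    the decoder should perform exactly at chance in expectation."""
    neurons = tuple(lv.NeuronSpec(f"n{i}", spont_mean) for i in range(n_neurons))
    odors = tuple(f"o{i}" for i in range(n_odors))
    tuning = {(n.label, o): lv.Tuning(1.0, mu, sigma) for n in neurons for o in odors}
    return lv.GeneratorSpec(neurons, odors, tuning, trials_per_pair=trials_per_pair, seed=seed)


def separable_spec(n=6, trials_per_pair=8, seed=5):
    """Diagonal tuning, huge excitations: a perfectly decodable code."""
    neurons = tuple(lv.NeuronSpec(f"n{i}", 2.0) for i in range(n))
    odors = tuple(f"o{i}" for i in range(n))
    tuning = {(f"n{i}", f"o{i}"): lv.Tuning(1.0, 80.0, 3.0) for i in range(n)}
    return lv.GeneratorSpec(neurons, odors, tuning, trials_per_pair=trials_per_pair, seed=seed)


def two_odor_spec(mu_a, mu_b, sigma=4.0, trials_per_pair=100, seed=7, n_extra_neurons=0):
    """One informative neuron, two odors; optional pure-background neurons."""
    neurons = [lv.NeuronSpec("n0", 3.0)]
    neurons += [lv.NeuronSpec(f"bg{i}", 3.0) for i in range(n_extra_neurons)]
    tuning = {
        ("n0", "A"): lv.Tuning(1.0, mu_a, sigma),
        ("n0", "B"): lv.Tuning(1.0, mu_b, sigma),
    }
    return lv.GeneratorSpec(tuple(neurons), ("A", "B"), tuning,
                            trials_per_pair=trials_per_pair, seed=seed)


def dataset_and_responding(spec):
    ds = lv.generate(spec)
    rs = lv.reliability_matrix(ds).responding_set()
    return ds, rs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def recording_like_dataset():
    spec = lv.recording_like_spec(seed=1)
    ds = lv.generate(spec)
    rs = lv.reliability_matrix(ds).responding_set()
    return spec, ds, rs
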