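"""Seeded generator of trial datasets with the statistical structure of
single-OSN larval recordings.

Each neuron has a spontaneous firing-rate model (truncated, rounded
Gaussian by default; Poisson available) from which its ten pre-stimulus
bins are drawn. A tuned (neuron, odor) pair responds on any given trial
with probability ``reliability``; responding trials draw the stimulation
count from the pair's truncated-Gaussian response model (a low mean for
inhibitory pairs), non-responding trials and untuned pairs draw it from
the neuron's spontaneous model. The same seed yields a byte-identical
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .io_data import Dataset, TrialRecord
from .response_models import TruncatedGaussian

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

N_SPONT_BINS = 10


@dataclass(frozen=True)
class NeuronSpec:
    """Label plus spontaneous-rate model of one neuron. ``spont_sigma``
    defaults to max(1, mean / 2) Hz, wide enough to reproduce the large
    per-trial ranges seen in recordings."""

    label: str
    spont_mean: float
    spont_sigma: Optional[float] = None

    @property
    def sigma(self) -> float:
        if self.spont_sigma is not None:
            return self.spont_sigma
        return max(1.0, self.spont_mean / 2.0)


@dataclass(frozen=True)
class Tuning:
    """Response model of one tuned (neuron, odor) pair."""

    reliability: float
    mu: float
    sigma: float
    sign: str = EXCITATORY

    def __post_init__(self):
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError(f"reliability must be in [0, 1], got {self.reliability}")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.sign not in (EXCITATORY, INHIBITORY):
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass
class GeneratorSpec:
    neurons: Tuple[NeuronSpec, ...]
    odors: Tuple[str, ...]
    tuning: Dict[Tuple[str, str], Tuning]
    trials_per_pair: int = 8
    seed: int = 0
    spont_family: str = "truncnorm"  # or "poisson"

    def validate(self) -> None:
        if self.trials_per_pair < 2:
            raise ValueError("trials_per_pair must be >= 2")
        if self.spont_family not in ("truncnorm", "poisson"):
            raise ValueError(f"unknown spont_family {self.spont_family!r}")
        labels = {n.label for n in self.neurons}
        if len(labels) != len(self.neurons):
            raise ValueError("duplicate neuron labels")
        if len(set(self.odors)) != len(self.odors):
            raise ValueError("duplicate odor labels")
        for (n, o), t in self.tuning.items():
            if n not in labels:
                raise ValueError(f"tuning references unknown neuron {n!r}")
            if o not in self.odors:
                raise ValueError(f"tuning references unknown odor {o!r}")
            if not isinstance(t, Tuning):
                raise ValueError("tuning values must be Tuning instances")


def _spont_draws(neuron: NeuronSpec, size, rng, family: str) -> np.ndarray:
    if family == "poisson":
        return rng.poisson(neuron.spont_mean, size=size).astype(int)
    tg = TruncatedGaussian(neuron.spont_mean, neuron.sigma)
    return np.rint(tg.rvs(rng, size=size)).astype(int)


def generate(spec: GeneratorSpec) -> Dataset:
    """Generate a fully seeded dataset from ``spec``.

    Trials are emitted neuron-major, then odor, then trial index, so a
    given seed always produces the identical file.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_t = spec.trials_per_pair
    trials = []
    for neuron in spec.neurons:
        for odor in spec.odors:
            spont = _spont_draws(neuron, (n_t, N_SPONT_BINS), rng, spec.spont_family)
            tuning = spec.tuning.get((neuron.label, odor))
            if tuning is None:
                stim = _spont_draws(neuron, n_t, rng, spec.spont_family)
            else:
                responds = rng.random(n_t) < tuning.reliability
                resp_tg = TruncatedGaussian(tuning.mu, tuning.sigma)
                resp_draws = np.rint(resp_tg.rvs(rng, size=n_t)).astype(int)
                spont_draws = _spont_draws(neuron, n_t, rng, spec.spont_family)
                stim = np.where(responds, resp_draws, spont_draws)
            for t in range(n_t):
                trials.append(
                    TrialRecord(
                        neuron_id=neuron.label,
                        odor_id=odor,
                        stim_count=int(stim[t]),
                        spont_bins=tuple(int(b) for b in spont[t]),
                        trial_index=t,
                    )
                )
    return Dataset(trials, [n.label for n in spec.neurons], list(spec.odors))


# The 15 neuron classes retained in the decoding analyses, with their mean
# spontaneous rates (Hz), and the 18-odor panel (octanal excluded because
# no neuron class responds to it).
_NEURON_SPONT_MEANS = (
    ("Or1a", 3.2),
    ("Or13a", 1.5),
    ("Or24a", 7.3),
    ("Or30a", 3.8),
    ("Or33b/47a", 0.7),
    ("Or35a", 7.0),
    ("Or42a", 4.0),
    ("Or42b", 5.5),
    ("Or45a", 2.7),
    ("Or49a", 5.2),
    ("Or59a", 1.2),
    ("Or63a", 1.2),
    ("Or67b", 6.0),
    ("Or74a", 4.9),
    ("Or83a", 7.9),
)

_ODORS = (
    "butanol",
    "pentanol",
    "hexanol",
    "octanol",
    "nonanol",
    "ethyl acetate",
    "propyl acetate",
    "butyl acetate",
    "iso-amyl acetate",
    "pentyl acetate",
    "methyl caproate",
    "benzyl acetate",
    "anisole",
    "heptanal",
    "2-heptanone",
    "r-carvone",
    "hexanoic acid",
    "nonanoic acid",
)

# Qualitative anchors of the recorded response matrix: pentyl acetate
# excites seven neuron classes (Or33b/47a responds to nothing else), one
# broadly tuned class covers 13 odors, and there are exactly three
# inhibitory pairs.
_PENTYL_RESPONDERS = ("Or33b/47a", "Or42a", "Or35a", "Or42b", "Or45a", "Or30a", "Or74a")
_BROAD_NEURON = "Or42a"
_INHIBITORY_PAIRS = (
    ("Or49a", "butanol"),
    ("Or49a", "2-heptanone"),
    ("Or67b", "anisole"),
)
_INHIBITION_DEPTH = 5.0  # Hz below the spontaneous mean


def recording_like_spec(seed: int = 0, trials_per_pair: int = 8) -> GeneratorSpec:
    """A 15-neuron x 18-odor preset emulating the recorded response matrix:
    roughly one in six pairs responding, reliabilities spread over
    10-100%, excitatory magnitudes up to ~100 Hz above background, three
    inhibitory pairs, and spontaneous means between 0.7 and 7.9 Hz."""
    rng = np.random.default_rng(seed)
    neurons = tuple(NeuronSpec(label, mean) for label, mean in _NEURON_SPONT_MEANS)
    spont = dict(_NEURON_SPONT_MEANS)
    tuning: Dict[Tuple[str, str], Tuning] = {}

    def add_excitatory(neuron: str, odor: str) -> None:
        if (neuron, odor) in tuning:
            return
        delta = float(rng.uniform(8.0, 90.0))
        mu = spont[neuron] + delta
        sigma = max(2.0, 0.2 * delta)
        reliability = float(rng.uniform(0.1, 1.0))
        tuning[(neuron, odor)] = Tuning(reliability, mu, sigma, EXCITATORY)

    for neuron in _PENTYL_RESPONDERS:
        add_excitatory(neuron, "pentyl acetate")
    broad_odors = list(rng.choice(
        [o for o in _ODORS if o != "pentyl acetate"], size=12, replace=False
    ))
    for odor in broad_odors:
        add_excitatory(_BROAD_NEURON, odor)
    for neuron, odor in _INHIBITORY_PAIRS:
        tuning[(neuron, odor)] = Tuning(
            reliability=float(rng.uniform(0.2, 0.6)),
            mu=max(0.0, spont[neuron] - _INHIBITION_DEPTH),
            sigma=1.5,
            sign=INHIBITORY,
        )
    # remaining classes are narrowly tuned (1-3 odors each)
    narrow = [
        n for n, _ in _NEURON_SPONT_MEANS
        if n not in (_BROAD_NEURON, "Or33b/47a", "Or49a", "Or67b")
    ]
    candidates = [o for o in _ODORS if o != "pentyl acetate"]
    for neuron in narrow:
        k = int(rng.integers(1, 4))
        for odor in rng.choice(candidates, size=k, replace=False):
            add_excitatory(neuron, str(odor))
    return GeneratorSpec(
        neurons=neurons,
        odors=_ODORS,
        tuning=tuning,
        trials_per_pair=trials_per_pair,
        seed=seed,
    )


def spec_to_dict(spec: GeneratorSpec) -> dict:
    return {
        "neurons": [
            {"label": n.label, "spont_mean": n.spont_mean, "spont_sigma": n.spont_sigma}
            for n in spec.neurons
        ],
        "odors": list(spec.odors),
        "tuning": [
            {
                "neuron": n,
                "odor": o,
                "reliability": t.reliability,
                "mu": t.mu,
                "sigma": t.sigma,
                "sign": t.sign,
            }
            for (n, o), t in sorted(spec.tuning.items())
        ],
        "trials_per_pair": spec.trials_per_pair,
        "seed": spec.seed,
        "spont_family": spec.spont_family,
    }


def spec_from_dict(d: dict) -> GeneratorSpec:
    return GeneratorSpec(
        neurons=tuple(
            NeuronSpec(n["label"], n["spont_mean"], n.get("spont_sigma")) for n in d["neurons"]
        ),
        odors=tuple(d["odors"]),
        tuning={
            (t["neuron"], t["odor"]): Tuning(
                t["reliability"], t["mu"], t["sigma"], t.get("sign", EXCITATORY)
            )
            for t in d["tuning"]
        },
        trials_per_pair=int(d.get("trials_per_pair", 8)),
        seed=int(d.get("seed", 0)),
        spont_family=d.get("spont_family", "truncnorm"),
    )
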