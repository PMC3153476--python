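"""Naive-Bayes population decoding of odor identity from OSN spike counts.

The decoder scores each candidate odor ``o_i`` by

    P(o_i | r)  propto  P(o_i) * prod_j P(r_j | o_i)

where ``r_j`` is the spike count of neuron *j* on the test trial and the
per-neuron likelihood is the fitted truncated-Gaussian *response*
distribution when *j* responds significantly to ``o_i`` and the neuron's
pooled *background* distribution otherwise. Likelihoods are accumulated
in log space (densities floored at 1e-300) and the predicted odor is the
posterior argmax, with exact ties broken uniformly at random.

Accuracy is estimated by leave-one-out cross-validation: each cycle holds
out one trial per (neuron, odor) pair uniformly at random, refits every
distribution on the remainder, synthesizes a population response to each
target odor (held-out stimulation counts for responding neurons, a
background draw for the rest), and decodes it. Chance levels come from
re-running the identical pipeline after permuting, within each neuron,
which odor is credited with each trial.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp

from .io_data import Dataset, InsufficientDataError, TrialRecord
from .response_criterion import reliability_matrix
from .response_models import (
    DEFAULT_SIGMA_FLOOR,
    DecoderModel,
    GroupedTrials,
    _as_grouped,
    _fit_from_stats,
    normalize_responding_set,
    uniform_priors,
)

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
LOG_DENSITY_FLOOR = math.log(1e-300)
_TIE_TOL = 1e-10


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _log_likelihood_matrix(r: np.ndarray, mu, sigma, log_norm, lower) -> np.ndarray:
    """(odors x neurons) log densities of the response vector ``r``."""
    z = (r[None, :] - mu) / sigma
    ll = -np.log(sigma) - 0.5 * z * z - 0.5 * _LOG_2PI - log_norm
    ll = np.where(r[None, :] < lower, -np.inf, ll)
    return np.maximum(ll, LOG_DENSITY_FLOOR)


def log_posterior(model: DecoderModel, r) -> pd.Series:
    """Normalized log posterior over the model's odors for one population
    response ``r`` (mapping neuron -> count, or an array in neuron order)."""
    arrays = model.param_arrays()
    if isinstance(r, Mapping):
        if set(r) != set(model.neuron_ids):
            raise ValueError("response must cover exactly the model's neuron set")
        rv = np.array([r[n] for n in model.neuron_ids], dtype=float)
    else:
        rv = np.asarray(r, dtype=float)
        if rv.shape != (len(model.neuron_ids),):
            raise ValueError("response length does not match the model's neuron set")
    if np.any(rv < 0):
        raise ValueError("spike counts must be >= 0")
    if model.discrete:
        ll = np.array(
            [
                [model.dist_for(n, o).logprob(x, discrete=True) for n, x in zip(model.neuron_ids, rv)]
                for o in model.odor_ids
            ]
        )
        ll = np.maximum(ll, LOG_DENSITY_FLOOR)
    else:
        ll = _log_likelihood_matrix(
            rv, arrays["mu"], arrays["sigma"], arrays["log_norm"], arrays["lower"]
        )
    unnorm = arrays["log_priors"] + ll.sum(axis=1)
    total = logsumexp(unnorm)
    if not np.isfinite(total):
        warnings.warn("all posteriors numerically zero; returning uniform posterior")
        return pd.Series(-math.log(len(model.odor_ids)), index=list(model.odor_ids))
    return pd.Series(unnorm - total, index=list(model.odor_ids))


def posterior(model: DecoderModel, r) -> Dict[str, float]:
    """Posterior odor probabilities P(o_i | r), summing to 1."""
    lp = log_posterior(model, r)
    return {o: float(v) for o, v in np.exp(lp).items()}


def _argmax_with_ties(values: np.ndarray, rng: np.random.Generator) -> Tuple[int, bool]:
    top = values.max()
    winners = np.flatnonzero(values >= top - _TIE_TOL)
    if winners.size == 1:
        return int(winners[0]), False
    return int(rng.choice(winners)), True


def decode(model: DecoderModel, r, rng=None) -> str:
    """Predicted odor for one population response (posterior argmax)."""
    lp = log_posterior(model, r)
    idx, _ = _argmax_with_ties(lp.to_numpy(), _as_rng(rng))
    return model.odor_ids[idx]


def synthesize_response(
    ds,
    model: DecoderModel,
    target_odor: str,
    rng=None,
    holdout: Optional[Mapping[tuple, int]] = None,
) -> Dict[str, int]:
    """Synthesize one population response to ``target_odor``: for each
    neuron responding to the target, one of its recorded stimulation
    counts for that odor, drawn uniformly; for every other neuron, one
    draw from its background pool. ``holdout`` excludes the given trial
    positions (leave-one-out bookkeeping)."""
    grouped = _as_grouped(ds)
    rng = _as_rng(rng)
    holdout = holdout or {}
    responding = model.responding_set.get(target_odor, frozenset())
    responding_odors_by_neuron = {
        n: {o for o, js in model.responding_set.items() if n in js} for n in grouped.neuron_ids
    }
    out = {}
    for n in grouped.neuron_ids:
        if n in responding:
            stim = grouped.stim.get((n, target_odor))
            if stim is None or stim.size == 0:
                raise InsufficientDataError(f"no recorded responses for ({n}, {target_odor})")
            h = holdout.get((n, target_odor))
            pool = stim if h is None else np.delete(stim, h)
        else:
            pool = grouped.background_pool(n, responding_odors_by_neuron[n], holdout)
        if pool.size == 0:
            raise InsufficientDataError(f"empty synthesis pool for neuron {n!r}")
        out[n] = int(pool[rng.integers(pool.size)])
    return out


@dataclass
class DecodingResult:
    """Cross-validated identification accuracy.

    ``per_odor`` has one row per target odor with columns ``accuracy``
    (percent correct), ``se`` (binomial standard error, percent) and
    ``n_correct``. ``confusion`` rows are targets, columns predictions;
    each row sums to ``n_cycles``.
    """

    per_odor: pd.DataFrame
    confusion: pd.DataFrame
    mean_accuracy: float
    mean_se: float
    n_cycles: int
    n_ties: int

    def __eq__(self, other):
        if not isinstance(other, DecodingResult):
            return NotImplemented
        return (
            self.per_odor.equals(other.per_odor)
            and self.confusion.equals(other.confusion)
            and self.mean_accuracy == other.mean_accuracy
            and self.n_cycles == other.n_cycles
            and self.n_ties == other.n_ties
        )


class _CycleDecoder:
    """Shared machinery for one cross-validation refit + decode cycle."""

    def __init__(self, grouped: GroupedTrials, responding, priors, sigma_floor):
        self.g = grouped
        self.responding = responding
        self.neurons = grouped.neuron_ids
        self.odors = grouped.odor_ids
        self.neuron_index = {n: j for j, n in enumerate(self.neurons)}
        self.sigma_floor = sigma_floor
        if priors is None:
            pri = uniform_priors(self.odors)
        else:
            total = float(sum(priors[o] for o in self.odors))
            pri = {o: priors[o] / total for o in self.odors}
        self.log_priors = np.log([pri[o] for o in self.odors])
        self.pairs = [(n, o) for n in self.neurons for o in self.odors if grouped.n_trials(n, o)]
        self.responding_odors_by_neuron = {
            n: {o for o, js in responding.items() if n in js} for n in self.neurons
        }
        # precondition: every responding pair needs >= 3 trials so that the
        # training split (n - 1) keeps at least 2 observations
        for o, js in responding.items():
            for n in js:
                if grouped.n_trials(n, o) < 3:
                    raise InsufficientDataError(
                        f"responding pair ({n}, {o}) has {grouped.n_trials(n, o)} trials; "
                        "leave-one-out needs >= 3"
                    )

    def draw_holdout(self, rng) -> Dict[tuple, int]:
        return {key: int(rng.integers(self.g.n_trials(*key))) for key in self.pairs}

    def fit(self, holdout) -> tuple:
        """Fit all distributions for this cycle; returns parameter matrices
        plus the per-neuron background pools (reused for synthesis)."""
        n_o, n_j = len(self.odors), len(self.neurons)
        mu = np.empty((n_o, n_j))
        sigma = np.empty((n_o, n_j))
        pools = []
        for j, n in enumerate(self.neurons):
            pool = self.g.background_pool(n, self.responding_odors_by_neuron[n], holdout)
            if pool.size < 2:
                raise InsufficientDataError(f"background pool for {n!r} too small")
            m, s = _fit_from_stats(
                float(pool.size), float(pool.sum()), float((pool * pool).sum()),
                0.0, self.sigma_floor,
            )
            mu[:, j] = m
            sigma[:, j] = s
            pools.append(pool)
        for i, o in enumerate(self.odors):
            for n in self.responding.get(o, frozenset()):
                j = self.neuron_index[n]
                stim = self.g.stim[(n, o)]
                h = holdout.get((n, o))
                train = stim if h is None else np.delete(stim, h)
                m, s = _fit_from_stats(
                    float(train.size), float(train.sum()), float((train * train).sum()),
                    0.0, self.sigma_floor,
                )
                mu[i, j], sigma[i, j] = m, s
        log_norm = log_ndtr(mu / sigma)
        return mu, sigma, log_norm, pools

    def synthesize(self, target: str, holdout, pools, rng) -> np.ndarray:
        r = np.empty(len(self.neurons))
        responding = self.responding.get(target, frozenset())
        for j, n in enumerate(self.neurons):
            if n in responding:
                r[j] = self.g.stim[(n, target)][holdout[(n, target)]]
            else:
                pool = pools[j]
                r[j] = pool[rng.integers(pool.size)]
        return r

    def decode(self, r, params, rng) -> Tuple[int, bool]:
        mu, sigma, log_norm, _ = params
        ll = _log_likelihood_matrix(r, mu, sigma, log_norm, 0.0)
        logpost = self.log_priors + ll.sum(axis=1)
        return _argmax_with_ties(logpost, rng)


def identify(
    ds,
    responding_set: Mapping[str, Iterable[str]],
    n_cycles: int = 4000,
    rng=None,
    *,
    targets: Optional[Sequence[str]] = None,
    priors: Optional[Mapping[str, float]] = None,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> DecodingResult:
    """Leave-one-out cross-validated odor identification.

    Each cycle independently holds out one trial per (neuron, odor) pair,
    refits the model on the remainder, synthesizes one population response
    per target odor and decodes it by posterior argmax. Accuracies are
    percent correct over ``n_cycles`` with binomial standard errors; the
    overall figure is the unweighted mean over targets.
    """
    grouped = _as_grouped(ds)
    responding = normalize_responding_set(responding_set)
    rng = _as_rng(rng)
    cyc = _CycleDecoder(grouped, responding, priors, sigma_floor)
    targets = list(grouped.odor_ids if targets is None else targets)
    odor_index = {o: i for i, o in enumerate(grouped.odor_ids)}

    confusion = np.zeros((len(targets), len(grouped.odor_ids)), dtype=int)
    n_ties = 0
    for _ in range(n_cycles):
        holdout = cyc.draw_holdout(rng)
        params = cyc.fit(holdout)
        for ti, target in enumerate(targets):
            r = cyc.synthesize(target, holdout, params[3], rng)
            pred, tied = cyc.decode(r, params, rng)
            n_ties += tied
            confusion[ti, pred] += 1

    n_correct = np.array([confusion[ti, odor_index[t]] for ti, t in enumerate(targets)])
    p_hat = n_correct / n_cycles
    acc = 100.0 * p_hat
    se = 100.0 * np.sqrt(p_hat * (1.0 - p_hat) / n_cycles)
    per_odor = pd.DataFrame(
        {"accuracy": acc, "se": se, "n_correct": n_correct}, index=targets
    )
    mean_acc = float(acc.mean())
    mean_se = float(np.sqrt((se**2).sum()) / len(targets))
    if n_ties:
        logger.info("broke %d posterior ties uniformly at random", n_ties)
    return DecodingResult(
        per_odor=per_odor,
        confusion=pd.DataFrame(confusion, index=targets, columns=list(grouped.odor_ids)),
        mean_accuracy=mean_acc,
        mean_se=mean_se,
        n_cycles=n_cycles,
        n_ties=n_ties,
    )


def permute_labels_within_neuron(ds: Dataset, rng=None) -> Dataset:
    """Null-hypothesis dataset: within each neuron, permute which odor is
    credited with each trial (stimulation count and spontaneous bins move
    together, so each neuron's marginal response distribution and each
    pair's trial count are preserved)."""
    rng = _as_rng(rng)
    new_trials: List[TrialRecord] = []
    by_neuron: Dict[str, List[TrialRecord]] = {n: [] for n in ds.neuron_ids}
    for t in ds.trials:
        by_neuron[t.neuron_id].append(t)
    shuffled: Dict[str, List[TrialRecord]] = {}
    for n in ds.neuron_ids:
        trials = by_neuron[n]
        order = rng.permutation(len(trials))
        shuffled[n] = [trials[i] for i in order]
    cursors = {n: 0 for n in ds.neuron_ids}
    for t in ds.trials:
        src = shuffled[t.neuron_id][cursors[t.neuron_id]]
        cursors[t.neuron_id] += 1
        new_trials.append(
            TrialRecord(
                neuron_id=t.neuron_id,
                odor_id=t.odor_id,
                stim_count=src.stim_count,
                spont_bins=src.spont_bins,
                larva_id=src.larva_id,
                trial_index=t.trial_index,
            )
        )
    return Dataset(new_trials, ds.neuron_ids, ds.odor_ids)


@dataclass
class ChanceBand:
    """Null distribution of mean accuracy under randomized odor labels."""

    band: float  # upper (1 - alpha) quantile, percent correct
    alpha: float
    null_accuracies: np.ndarray
    n_randomizations: int
    cycles_per_randomization: int

    @property
    def null_mean(self) -> float:
        return float(self.null_accuracies.mean())


def chance_band(
    ds: Dataset,
    responding_set: Optional[Mapping[str, Iterable[str]]] = None,
    n_randomizations: int = 4000,
    alpha: float = 0.01,
    rng=None,
    *,
    cycles_per_randomization: int = 20,
    threshold_hz: float = 5.0,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> ChanceBand:
    """Upper confidence level of decoding accuracy under the null.

    Each randomization permutes odor labels within every neuron, re-derives
    the responding set with the response criterion, re-runs the full
    leave-one-out identification pipeline, and records its mean accuracy;
    the band is the (1 - alpha) quantile of those accuracies. The
    ``responding_set`` argument is accepted for interface symmetry but the
    null pipeline re-derives it from each permuted dataset (pairs left with
    fewer than 3 trials after permutation are dropped from the set).
    """
    rng = _as_rng(rng)
    null_acc = np.empty(n_randomizations)
    for k in range(n_randomizations):
        permuted = permute_labels_within_neuron(ds, rng)
        rel = reliability_matrix(permuted, threshold_hz)
        rs = {
            o: frozenset(
                n for n in js if len(permuted.trials_for(n, o)) >= 3
            )
            for o, js in rel.responding_set().items()
        }
        res = identify(
            permuted, rs, n_cycles=cycles_per_randomization, rng=rng, sigma_floor=sigma_floor
        )
        null_acc[k] = res.mean_accuracy
    band = float(np.quantile(null_acc, 1.0 - alpha))
    return ChanceBand(band, alpha, null_acc, n_randomizations, cycles_per_randomization)


@dataclass(frozen=True)
class AblationStep:
    removed: Optional[str]  # None for the full model
    n_neurons: int
    mean_accuracy: float
    se: float


@dataclass
class AblationCurve:
    steps: List[AblationStep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "removed": s.removed,
                    "n_neurons": s.n_neurons,
                    "mean_accuracy": s.mean_accuracy,
                    "se": s.se,
                }
                for s in self.steps
            ]
        )


def _restrict_responding(responding, neurons) -> Dict[str, FrozenSet[str]]:
    keep = set(neurons)
    return {o: frozenset(js & keep) for o, js in responding.items()}


def ablate(
    ds: Dataset,
    responding_set: Mapping[str, Iterable[str]],
    n_cycles: int = 200,
    rng=None,
    *,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> AblationCurve:
    """Greedy backward elimination of neurons.

    At each stage every leave-one-neuron-out subset is scored with
    :func:`identify` and the neuron whose removal costs least accuracy is
    eliminated, down to a single neuron. Ties are broken by lexicographic
    neuron label (logged). The curve starts with the full model, so its
    length equals the number of neurons.
    """
    if len(ds.neuron_ids) < 2:
        raise ValueError("ablation needs at least 2 neurons")
    rng = _as_rng(rng)
    responding = normalize_responding_set(responding_set)
    current = list(ds.neuron_ids)

    full = identify(ds, _restrict_responding(responding, current), n_cycles, rng,
                    sigma_floor=sigma_floor)
    steps = [AblationStep(None, len(current), full.mean_accuracy, full.mean_se)]
    while len(current) > 1:
        best_label, best_res = None, None
        for candidate in sorted(current):
            rest = [n for n in current if n != candidate]
            sub = ds.subset(neurons=rest)
            res = identify(
                sub, _restrict_responding(responding, rest), n_cycles, rng,
                sigma_floor=sigma_floor,
            )
            if best_res is None or res.mean_accuracy > best_res.mean_accuracy:
                best_label, best_res = candidate, res
            elif res.mean_accuracy == best_res.mean_accuracy:
                logger.info(
                    "ablation tie between %s and %s; keeping lexicographic winner",
                    best_label,
                    candidate,
                )
        current.remove(best_label)
        steps.append(
            AblationStep(best_label, len(current), best_res.mean_accuracy, best_res.mean_se)
        )
    return AblationCurve(steps)


class DiscriminationMatrix:
    """Ordered-pair percent-correct table; cell (A, B) is how often the
    decoder named A when A was the target of a 2-odor model of {A, B}."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def cell(self, target: str, alternative: str) -> float:
        return float(self.table.loc[target, alternative])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="target_odor")


def discriminate_pairs(
    ds: Dataset,
    responding_set: Mapping[str, Iterable[str]],
    odor_pairs: Optional[Iterable[Tuple[str, str]]] = None,
    n_cycles: int = 4000,
    rng=None,
    *,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> DiscriminationMatrix:
    """Pairwise 2-odor discrimination with equal priors.

    For every requested ordered pair (A, B) a 2-odor model is fitted on
    the data restricted to {A, B} and cell (A, B) records the percent of
    cycles on which target A was decoded as A. Both orderings of a pair
    are evaluated from the same cross-validation run, so the matrix need
    not be symmetric. Chance is 50%.
    """
    rng = _as_rng(rng)
    responding = normalize_responding_set(responding_set)
    if odor_pairs is None:
        odor_pairs = [
            (a, b) for a, b in itertools.permutations(ds.odor_ids, 2)
        ]
    requested = list(odor_pairs)
    for a, b in requested:
        if a == b:
            raise ValueError("diagonal cells are undefined")

    by_unordered: Dict[frozenset, set] = {}
    for a, b in requested:
        by_unordered.setdefault(frozenset((a, b)), set()).add(a)

    table = pd.DataFrame(np.nan, index=list(ds.odor_ids), columns=list(ds.odor_ids))
    for pair, targets in sorted(by_unordered.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        sub = ds.subset(odors=[a, b])
        rs = {o: responding.get(o, frozenset()) for o in (a, b)}
        res = identify(
            sub, rs, n_cycles=n_cycles, rng=rng, targets=sorted(targets),
            sigma_floor=sigma_floor,
        )
        for t in sorted(targets):
            other = b if t == a else a
            table.loc[t, other] = res.per_odor.loc[t, "accuracy"]
    return DiscriminationMatrix(table)
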