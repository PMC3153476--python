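"""Truncated-Gaussian spike-count models and decoder-model construction.

Spike counts of a responding (neuron, odor) pair are modelled as a
Gaussian truncated at zero, fitted by maximum likelihood. Counts of a
neuron under odors that are not ligands for it are pooled with its
pre-stimulus spontaneous counts (the second before each stimulation)
into a single per-neuron *background* truncated Gaussian.

The truncated Gaussian with lower bound ``a`` has density

    f(x; mu, sigma) = phi((x - mu)/sigma) / (sigma * Phi((mu - a)/sigma))

for x >= a and 0 below. It is an exponential family in (x, x**2), so the
log-likelihood is a function of (n, sum x, sum x**2) only, which keeps
repeated refits (cross-validation, permutation nulls, ablation) cheap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

from .io_data import Dataset, InsufficientDataError, ModelArchive

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_FLOOR = 0.5  # spikes/s; prevents degenerate zero-width fits
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class TruncatedGaussian:
    """Gaussian truncated below at ``lower`` (default 0 spikes)."""

    mu: float
    sigma: float
    lower: float = 0.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def _log_norm(self) -> float:
        # log P(X >= lower) under the untruncated Gaussian
        return float(log_ndtr((self.mu - self.lower) / self.sigma))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mu) / self.sigma
        out = -np.log(self.sigma) - 0.5 * z * z - 0.5 * _LOG_2PI - self._log_norm
        return np.where(x < self.lower, -np.inf, out)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def _frozen(self):
        a = (self.lower - self.mu) / self.sigma
        return stats.truncnorm(a, np.inf, loc=self.mu, scale=self.sigma)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def logprob(self, x, discrete: bool = False, bin_width: float = 1.0):
        """Log density at ``x``, or log mass of the width-1 bin around ``x``
        when ``discrete`` is set (sensitivity-analysis variant)."""
        if not discrete:
            return self.logpdf(x)
        x = np.asarray(x, dtype=float)
        fr = self._frozen()
        lo = np.maximum(x - bin_width / 2.0, self.lower)
        mass = fr.cdf(x + bin_width / 2.0) - fr.cdf(lo)
        return np.log(np.maximum(mass, 1e-300))

    def rvs(self, rng: np.random.Generator, size=None):
        return self._frozen().rvs(size=size, random_state=rng)

    def mean(self) -> float:
        return float(self._frozen().mean())


def _nll_and_grad(theta, n, s1, s2, lower):
    """Negative log-likelihood (up to the n/2*log(2*pi) constant included)
    and its gradient in (mu, log sigma), from sufficient statistics."""
    mu, ls = theta
    sigma = math.exp(ls)
    q = s2 - 2.0 * mu * s1 + n * mu * mu  # sum (x - mu)^2
    beta = (mu - lower) / sigma
    log_phi_beta = float(log_ndtr(beta))
    nll = n * ls + q / (2.0 * sigma * sigma) + n * log_phi_beta + 0.5 * n * _LOG_2PI
    # hazard ratio phi(beta)/Phi(beta), computed in log space for stability
    r = math.exp(min(-0.5 * beta * beta - 0.5 * _LOG_2PI - log_phi_beta, 700.0))
    d_mu = (n * mu - s1) / (sigma * sigma) + n * r / sigma
    d_ls = n - q / (sigma * sigma) - n * r * beta
    return nll, np.array([d_mu, d_ls])


def _fit_from_stats(
    n: float,
    s1: float,
    s2: float,
    lower: float = 0.0,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> Tuple[float, float]:
    """Maximum-likelihood (mu, sigma) from (n, sum x, sum x^2)."""
    mean = s1 / n
    var = max(s2 / n - mean * mean, 0.0)
    sd = math.sqrt(var)
    if sd < 1e-9:
        warnings.warn(
            "all observations identical; returning sigma at the configured floor",
            stacklevel=2,
        )
        return mean, sigma_floor
    x0 = np.array([mean, math.log(max(sd, sigma_floor))])
    scale = max(sd, abs(mean), 1.0)
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=(n, s1, s2, lower),
        jac=True,
        method="L-BFGS-B",
        bounds=[
            (mean - 50.0 * scale, mean + 50.0 * scale),
            (math.log(sigma_floor / 100.0), x0[1] + 10.0),
        ],
        options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 200},
    )
    nll0, _ = _nll_and_grad(x0, n, s1, s2, lower)
    if not np.isfinite(res.fun) or res.fun > nll0:
        # keep the moment initializer if the line search went astray
        mu, ls = x0
    else:
        mu, ls = res.x
    return float(mu), float(max(math.exp(ls), sigma_floor))


def fit_truncated_gaussian(
    counts: Sequence[float],
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    lower: float = 0.0,
) -> TruncatedGaussian:
    """Fit a truncated-at-``lower`` Gaussian to spike counts by maximum
    likelihood. Requires at least 2 observations; identical observations
    yield ``sigma`` at the configured floor with a warning."""
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 observations, got {x.size}")
    if np.any(x < lower):
        raise ValueError("observations below the truncation bound")
    mu, sigma = _fit_from_stats(
        float(x.size), float(x.sum()), float((x * x).sum()), lower, sigma_floor
    )
    return TruncatedGaussian(mu, sigma, lower)


class GroupedTrials:
    """Per-(neuron, odor) numpy views of a dataset: stimulation counts and
    final pre-stimulus spontaneous counts. Built once, reused across the
    many refits of cross-validation and permutation testing."""

    def __init__(self, ds: Dataset):
        self.neuron_ids = ds.neuron_ids
        self.odor_ids = ds.odor_ids
        self.stim: Dict[tuple, np.ndarray] = {}
        self.spont_last: Dict[tuple, np.ndarray] = {}
        for n, o in ds.pairs():
            trials = ds.trials_for(n, o)
            self.stim[(n, o)] = np.array([t.stim_count for t in trials], dtype=float)
            self.spont_last[(n, o)] = np.array([t.spont_last for t in trials], dtype=float)

    def n_trials(self, neuron: str, odor: str) -> int:
        return len(self.stim.get((neuron, odor), ()))

    def background_pool(
        self,
        neuron: str,
        responding_odors: Iterable[str],
        holdout: Optional[Mapping[tuple, int]] = None,
    ) -> np.ndarray:
        """Pooled background sample for one neuron: final pre-stimulus
        spontaneous counts of all its trials, plus stimulation counts of
        trials with non-ligand odors. ``holdout`` maps (neuron, odor) to a
        trial position excluded from the pool (leave-one-out)."""
        responding = set(responding_odors)
        holdout = holdout or {}
        parts = []
        for o in self.odor_ids:
            key = (neuron, o)
            if key not in self.stim:
                continue
            h = holdout.get(key)
            spont = self.spont_last[key]
            if h is None:
                parts.append(spont)
            else:
                parts.append(np.delete(spont, h))
            if o not in responding:
                stim = self.stim[key]
                parts.append(stim if h is None else np.delete(stim, h))
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)


def _as_grouped(ds) -> GroupedTrials:
    return ds if isinstance(ds, GroupedTrials) else GroupedTrials(ds)


def fit_background(
    ds,
    neuron_id: str,
    responding_odors: Iterable[str],
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    holdout: Optional[Mapping[tuple, int]] = None,
) -> TruncatedGaussian:
    """Fit the pooled background distribution of one neuron (spontaneous
    counts plus stimulation counts under non-ligand odors)."""
    grouped = _as_grouped(ds)
    pool = grouped.background_pool(neuron_id, responding_odors, holdout)
    if pool.size < 2:
        raise InsufficientDataError(f"background pool for {neuron_id!r} has {pool.size} points")
    return fit_truncated_gaussian(pool, sigma_floor=sigma_floor)


def normalize_responding_set(responding_set: Mapping[str, Iterable[str]]) -> Dict[str, FrozenSet[str]]:
    return {odor: frozenset(neurons) for odor, neurons in responding_set.items()}


def uniform_priors(odor_ids: Sequence[str]) -> Dict[str, float]:
    p = 1.0 / len(odor_ids)
    return {o: p for o in odor_ids}


@dataclass
class DecoderModel:
    """Per-(neuron, odor) response distributions, per-neuron background
    distributions, odor priors and the responding-set partition.

    At decode time neuron *j* contributes its response distribution to the
    likelihood of odor *i* when *j* responds significantly to *i*, and its
    background distribution otherwise."""

    neuron_ids: tuple
    odor_ids: tuple
    response_dists: Dict[tuple, TruncatedGaussian]
    background_dists: Dict[str, TruncatedGaussian]
    priors: Dict[str, float]
    responding_set: Dict[str, FrozenSet[str]]
    discrete: bool = False
    _arrays: Optional[dict] = field(default=None, repr=False, compare=False)

    def dist_for(self, neuron: str, odor: str) -> TruncatedGaussian:
        if neuron in self.responding_set.get(odor, frozenset()):
            return self.response_dists[(neuron, odor)]
        return self.background_dists[neuron]

    def param_arrays(self) -> dict:
        """(odor x neuron) parameter matrices for vectorized decoding."""
        if self._arrays is None:
            n_o, n_j = len(self.odor_ids), len(self.neuron_ids)
            mu = np.empty((n_o, n_j))
            sigma = np.empty((n_o, n_j))
            lower = np.empty((n_o, n_j))
            for i, o in enumerate(self.odor_ids):
                for j, n in enumerate(self.neuron_ids):
                    d = self.dist_for(n, o)
                    mu[i, j], sigma[i, j], lower[i, j] = d.mu, d.sigma, d.lower
            log_norm = log_ndtr((mu - lower) / sigma)
            log_priors = np.log([self.priors[o] for o in self.odor_ids])
            self._arrays = {
                "mu": mu,
                "sigma": sigma,
                "lower": lower,
                "log_norm": log_norm,
                "log_priors": log_priors,
            }
        return self._arrays

    def to_params(self) -> dict:
        return {
            "neuron_ids": list(self.neuron_ids),
            "odor_ids": list(self.odor_ids),
            "priors": dict(self.priors),
            "responding_set": {o: sorted(v) for o, v in self.responding_set.items()},
            "response_dists": [
                [n, o, d.mu, d.sigma, d.lower] for (n, o), d in sorted(self.response_dists.items())
            ],
            "background_dists": [
                [n, d.mu, d.sigma, d.lower] for n, d in sorted(self.background_dists.items())
            ],
            "discrete": self.discrete,
        }

    @classmethod
    def from_params(cls, params: dict) -> "DecoderModel":
        return cls(
            neuron_ids=tuple(params["neuron_ids"]),
            odor_ids=tuple(params["odor_ids"]),
            response_dists={
                (n, o): TruncatedGaussian(mu, sigma, lower)
                for n, o, mu, sigma, lower in params["response_dists"]
            },
            background_dists={
                n: TruncatedGaussian(mu, sigma, lower)
                for n, mu, sigma, lower in params["background_dists"]
            },
            priors=dict(params["priors"]),
            responding_set={o: frozenset(v) for o, v in params["responding_set"].items()},
            discrete=bool(params.get("discrete", False)),
        )


def build_model(
    ds,
    responding_set: Mapping[str, Iterable[str]],
    priors: Optional[Mapping[str, float]] = None,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    discrete: bool = False,
    holdout: Optional[Mapping[tuple, int]] = None,
) -> DecoderModel:
    """Fit all response and background distributions of a decoder model.

    ``responding_set`` maps each odor to the neurons with a significant
    response to it (see :mod:`larvodec.response_criterion`). ``holdout``
    optionally maps (neuron, odor) to a trial position excluded from every
    fit — the leave-one-out bookkeeping used during cross-validation.
    Priors default to uniform over the dataset's odors; explicit priors
    are renormalized to sum to 1.
    """
    grouped = _as_grouped(ds)
    responding = normalize_responding_set(responding_set)
    holdout = holdout or {}

    if priors is None:
        pri = uniform_priors(grouped.odor_ids)
    else:
        total = float(sum(priors[o] for o in grouped.odor_ids))
        pri = {o: priors[o] / total for o in grouped.odor_ids}

    response_dists = {}
    for o in grouped.odor_ids:
        for n in responding.get(o, frozenset()):
            key = (n, o)
            stim = grouped.stim.get(key)
            if stim is None:
                raise InsufficientDataError(f"no trials for responding pair {key}")
            h = holdout.get(key)
            train = stim if h is None else np.delete(stim, h)
            if train.size < 2:
                raise InsufficientDataError(
                    f"responding pair {key} has {train.size} training trials; need >= 2"
                )
            response_dists[key] = fit_truncated_gaussian(train, sigma_floor=sigma_floor)

    responding_odors_by_neuron = {
        n: {o for o, js in responding.items() if n in js} for n in grouped.neuron_ids
    }
    background_dists = {
        n: fit_background(grouped, n, responding_odors_by_neuron[n], sigma_floor, holdout)
        for n in grouped.neuron_ids
    }
    return DecoderModel(
        neuron_ids=grouped.neuron_ids,
        odor_ids=grouped.odor_ids,
        response_dists=response_dists,
        background_dists=background_dists,
        priors=pri,
        responding_set={o: responding.get(o, frozenset()) for o in grouped.odor_ids},
        discrete=discrete,
    )


def model_to_archive(
    model: DecoderModel,
    fingerprint: Optional[str] = None,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> ModelArchive:
    return ModelArchive(
        params=model.to_params(), fingerprint=fingerprint, seed=seed, config=config or {}
    )


def model_from_archive(archive: ModelArchive) -> DecoderModel:
    return DecoderModel.from_params(archive.params)
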