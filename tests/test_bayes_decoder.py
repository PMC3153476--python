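"""Posterior computation, cross-validated identification, nulls, ablation
and pairwise discrimination."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

import larvodec as lv
from larvodec.response_models import DecoderModel, TruncatedGaussian

from conftest import (
    dataset_and_responding,
    make_trial,
    separable_spec,
    two_odor_spec,
    uniform_tuning_spec,
)


def toy_model(priors=(0.5, 0.3, 0.2)):
    """Hand-set 3-odor x 2-neuron model."""
    neurons = ("nA", "nB")
    odors = ("o1", "o2", "o3")
    return DecoderModel(
        neuron_ids=neurons,
        odor_ids=odors,
        response_dists={
            ("nA", "o1"): TruncatedGaussian(30, 4),
            ("nB", "o2"): TruncatedGaussian(22, 3),
        },
        background_dists={"nA": TruncatedGaussian(3, 2), "nB": TruncatedGaussian(5, 2.5)},
        priors=dict(zip(odors, priors)),
        responding_set={"o1": frozenset({"nA"}), "o2": frozenset({"nB"}), "o3": frozenset()},
    )


class TestPosterior:
    def test_sums_to_one(self):
        model = toy_model()
        for r in ({"nA": 12, "nB": 18}, {"nA": 0, "nB": 0}, {"nA": 80, "nB": 1}):
            assert sum(lv.posterior(model, r).values()) == pytest.approx(1.0, abs=1e-9)

    def test_likelihood_dominance(self):
        model = DecoderModel(
            neuron_ids=("n",),
            odor_ids=("o1", "o2"),
            response_dists={("n", "o1"): TruncatedGaussian(10, 1), ("n", "o2"): TruncatedGaussian(20, 1)},
            background_dists={"n": TruncatedGaussian(3, 2)},
            priors={"o1": 0.5, "o2": 0.5},
            responding_set={"o1": frozenset({"n"}), "o2": frozenset({"n"})},
        )
        post = lv.posterior(model, {"n": 19})
        assert max(post, key=post.get) == "o2"

    def test_matches_brute_force_product_of_densities(self):
        """Independent direct evaluation of prior x product of truncated
        normal densities, normalized, matches to 1e-12 in log space."""
        model = toy_model()
        r = {"nA": 12, "nB": 18}
        lp = lv.log_posterior(model, r)
        brute = []
        for o in model.odor_ids:
            tot = math.log(model.priors[o])
            for n in model.neuron_ids:
                d = model.dist_for(n, o)
                a = (0 - d.mu) / d.sigma
                tot += stats.truncnorm(a, np.inf, loc=d.mu, scale=d.sigma).logpdf(r[n])
            brute.append(tot)
        brute = np.asarray(brute) - logsumexp(brute)
        assert np.max(np.abs(lp.to_numpy() - brute)) < 1e-12

    def test_invariant_to_common_prior_rescaling(self):
        model = toy_model(priors=(0.5, 0.3, 0.2))
        scaled = toy_model(priors=(5.0, 3.0, 2.0))
        # normalize the scaled priors the way build_model would
        total = sum(scaled.priors.values())
        scaled.priors = {o: v / total for o, v in scaled.priors.items()}
        r = {"nA": 25, "nB": 7}
        assert np.allclose(
            lv.log_posterior(model, r).to_numpy(),
            lv.log_posterior(scaled, r).to_numpy(),
        )

    def test_mismatched_neuron_set_rejected(self):
        with pytest.raises(ValueError):
            lv.posterior(toy_model(), {"nA": 5})


class TestSynthesizeResponse:
    def _setup(self):
        ds, rs = dataset_and_responding(two_odor_spec(30, 38, trials_per_pair=3, seed=11))
        model = lv.build_model(ds, rs)
        return ds, model

    def test_responding_neuron_draws_recorded_count(self, rng):
        ds, model = self._setup()
        recorded = {t.stim_count for t in ds.trials_for("n0", "A")}
        for _ in range(20):
            r = lv.synthesize_response(ds, model, "A", rng)
            assert r["n0"] in recorded

    def test_nonresponding_neuron_draws_from_background_pool(self, rng):
        ds, rs = dataset_and_responding(
            two_odor_spec(30, 38, trials_per_pair=4, seed=12, n_extra_neurons=1)
        )
        model = lv.build_model(ds, rs)
        from larvodec.response_models import GroupedTrials

        pool = set(GroupedTrials(ds).background_pool("bg0", set()).astype(int))
        for _ in range(20):
            r = lv.synthesize_response(ds, model, "A", rng)
            assert r["bg0"] in pool

    def test_draws_uniform_over_pool(self, rng):
        """Chi-square goodness of fit of 10^4 draws against the uniform
        distribution over the recorded responses."""
        ds, model = self._setup()
        values = [t.stim_count for t in ds.trials_for("n0", "A")]
        draws = [lv.synthesize_response(ds, model, "A", rng)["n0"] for _ in range(10_000)]
        counts = [sum(d == v for d in draws) for v in set(values)]
        expected = [10_000 * values.count(v) / len(values) for v in set(values)]
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01


class TestIdentify:
    def test_separable_code_decoded_nearly_perfectly(self):
        ds, rs = dataset_and_responding(separable_spec())
        res = lv.identify(ds, rs, n_cycles=200, rng=np.random.default_rng(2))
        assert res.per_odor["accuracy"].min() >= 99.0

    def test_confusion_rows_sum_to_cycles(self):
        ds, rs = dataset_and_responding(separable_spec(n=4))
        res = lv.identify(ds, rs, n_cycles=50, rng=np.random.default_rng(3))
        assert (res.confusion.sum(axis=1) == 50).all()
        assert ((res.per_odor["accuracy"] >= 0) & (res.per_odor["accuracy"] <= 100)).all()

    def test_identical_seed_reproduces_result(self):
        ds, rs = dataset_and_responding(separable_spec(n=3))
        a = lv.identify(ds, rs, n_cycles=40, rng=np.random.default_rng(7))
        b = lv.identify(ds, rs, n_cycles=40, rng=np.random.default_rng(7))
        assert a == b

    def test_uninformative_code_at_chance_over_datasets(self):
        """All odors share one response distribution; averaged over fresh
        datasets the decoder sits at chance (its unconditional accuracy)."""
        accs = []
        for seed in range(12):
            ds, rs = dataset_and_responding(uniform_tuning_spec(3, 6, 8, seed=100 + seed))
            res = lv.identify(ds, rs, n_cycles=25, rng=np.random.default_rng(seed))
            accs.append(res.mean_accuracy)
        n_dec = 12 * 25 * 6
        hw = 258.0 * math.sqrt((1 / 6) * (5 / 6) / n_dec)
        assert abs(np.mean(accs) - 100 / 6) < max(hw, 3.0)

    def test_responding_pair_needs_three_trials(self):
        ds, rs = dataset_and_responding(two_odor_spec(30, 38, trials_per_pair=2, seed=1))
        with pytest.raises(lv.InsufficientDataError):
            lv.identify(ds, rs, n_cycles=5, rng=np.random.default_rng(0))


class TestChanceBand:
    def test_band_above_analytic_chance_and_null_centered(self, recording_like_dataset):
        _, ds, _ = recording_like_dataset
        band = lv.chance_band(
            ds, n_randomizations=25, rng=np.random.default_rng(5), cycles_per_randomization=4
        )
        chance = 100 / len(ds.odor_ids)
        assert band.band >= chance
        assert abs(band.null_mean - chance) < 3.0

    def test_median_band_near_chance(self):
        ds, _ = dataset_and_responding(uniform_tuning_spec(2, 5, 8, seed=21))
        band = lv.chance_band(
            ds,
            n_randomizations=30,
            alpha=0.5,
            rng=np.random.default_rng(6),
            cycles_per_randomization=6,
        )
        assert abs(band.band - 100 / 5) < 6.0

    def test_label_permutation_preserves_marginals(self, rng):
        ds, _ = dataset_and_responding(uniform_tuning_spec(2, 4, 6, seed=8))
        perm = lv.permute_labels_within_neuron(ds, rng)
        assert len(perm) == len(ds)
        for n in ds.neuron_ids:
            orig = sorted(t.stim_count for t in ds.trials if t.neuron_id == n)
            new = sorted(t.stim_count for t in perm.trials if t.neuron_id == n)
            assert orig == new
        for n, o in ds.pairs():
            assert len(perm.trials_for(n, o)) == len(ds.trials_for(n, o))


class TestAblate:
    def test_curve_spans_full_set_down_to_one(self):
        ds, rs = dataset_and_responding(separable_spec(n=4))
        curve = lv.ablate(ds, rs, n_cycles=20, rng=np.random.default_rng(4))
        counts = [s.n_neurons for s in curve.steps]
        assert len(curve.steps) == 4
        assert counts == [4, 3, 2, 1]
        assert curve.steps[0].removed is None

    def test_redundant_neuron_removed_before_unique_one(self):
        """A neuron duplicating another's tuning goes before the only
        neuron carrying a third odor."""
        neurons = tuple(lv.NeuronSpec(n, 3.0) for n in ("dup1", "dup2", "uniq"))
        odors = ("oA", "oB")
        tuning = {
            ("dup1", "oA"): lv.Tuning(1.0, 60, 3),
            ("dup2", "oA"): lv.Tuning(1.0, 60, 3),
            ("uniq", "oB"): lv.Tuning(1.0, 60, 3),
        }
        ds, rs = dataset_and_responding(
            lv.GeneratorSpec(neurons, odors, tuning, trials_per_pair=8, seed=13)
        )
        curve = lv.ablate(ds, rs, n_cycles=60, rng=np.random.default_rng(9))
        first_removed = curve.steps[1].removed
        assert first_removed in ("dup1", "dup2")

    def test_pure_noise_neuron_removal_costs_nothing(self):
        ds, rs = dataset_and_responding(
            two_odor_spec(20, 28, trials_per_pair=20, seed=14, n_extra_neurons=1)
        )
        with_noise = lv.identify(ds, rs, n_cycles=300, rng=np.random.default_rng(10))
        sub = ds.subset(neurons=["n0"])
        without = lv.identify(sub, rs, n_cycles=300, rng=np.random.default_rng(10))
        se = math.hypot(with_noise.mean_se, without.mean_se)
        assert abs(with_noise.mean_accuracy - without.mean_accuracy) < 3 * se


class TestDiscriminatePairs:
    def test_separable_pair_near_perfect(self):
        ds, rs = dataset_and_responding(two_odor_spec(10, 80, sigma=3, trials_per_pair=30, seed=15))
        m = lv.discriminate_pairs(ds, rs, n_cycles=200, rng=np.random.default_rng(11))
        assert m.cell("A", "B") >= 99.0
        assert m.cell("B", "A") >= 99.0

    def test_informative_pair_beats_chance_both_ways(self):
        ds, rs = dataset_and_responding(two_odor_spec(20, 32, trials_per_pair=40, seed=16))
        m = lv.discriminate_pairs(ds, rs, n_cycles=400, rng=np.random.default_rng(12))
        assert m.cell("A", "B") > 50 and m.cell("B", "A") > 50

    def test_requested_pairs_only(self, recording_like_dataset):
        _, ds, rs = recording_like_dataset
        pairs = [("butanol", "anisole")]
        m = lv.discriminate_pairs(ds, rs, odor_pairs=pairs, n_cycles=20,
                                  rng=np.random.default_rng(13))
        assert not math.isnan(m.cell("butanol", "anisole"))
        assert math.isnan(m.cell("anisole", "butanol"))
        with pytest.raises(ValueError):
            lv.discriminate_pairs(ds, rs, odor_pairs=[("anisole", "anisole")])
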