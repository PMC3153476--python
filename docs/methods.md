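# Methods

## The decoding problem

A *Drosophila* larva carries 21 unique pairs of olfactory sensory neurons
(OSNs), each expressing (essentially) one odorant receptor. Given the
spike count of each OSN class in a 1-s odor stimulation window, how well
can odor identity be read out at the periphery? `larvodec` implements a
naive-Bayes population decoder over per-(neuron, odor) spike-count
models, together with the statistics needed to interpret it: chance
levels under label randomization, robustness under greedy neuron
ablation, pairwise discriminability, and the behavioral response-index
tests used to compare decoder predictions with whole-animal behavior.

All windows are 1 s, so spike counts and rates in Hz are numerically
interchangeable throughout.

## Response criterion and reliability

A trial counts as a significant response when the stimulation rate
changes by at least 5 Hz (configurable) relative to the *extremes* of
the spontaneous activity recorded in the ten 1-s bins before the
stimulus: excitation when `stim >= max(spont) + 5`, inhibition when
`stim <= min(spont) - 5`, boundaries inclusive. The 5 Hz operating point
corresponds to a 0.05 type-1 error calibration established for this
preparation; we implement the operational rule and do not re-derive the
calibration. Reliability of a (neuron, odor) pair is the fraction of its
trials above criterion; a pair enters the decoder's *responding set*
when at least one trial is above criterion (cutoff configurable).
Summary tables report spontaneous activity from the final pre-stimulus
bin (the second immediately before stimulation); the criterion uses the
extremes over all ten bins. Both views are exposed.

## Spike-count models

Counts of a responding pair are modelled as a Gaussian truncated at
zero,

    f(r | mu, sigma) = phi((r - mu)/sigma) / (sigma * Phi(mu/sigma)),  r >= 0,

fitted by maximum likelihood. Counts are treated as continuous at the
likelihood stage (density evaluated at the integer count); a
discretized-mass variant (`discrete=True`) is available for sensitivity
analysis. The family is exponential in (r, r^2), so fits depend on the
data only through (n, sum r, sum r^2); we minimize the negative
log-likelihood over (mu, log sigma) with L-BFGS-B and an analytic
gradient, starting from the sample moments, with box bounds that keep
the line search numerically safe. The fit falls back to the moment
initializer in the (rare) case the optimizer returns something worse.
Fitted sigma is floored at 0.5 spikes (configurable) to prevent
degenerate zero-width distributions; samples with zero variance return
the floor with a warning.

For boundary-hugging samples (mean near zero, large variance — e.g.
low-reliability mixtures) the truncated-normal likelihood has a ridge:
mu -> -inf with growing sigma leaves the density on [0, inf) nearly
unchanged. Raw (mu, sigma) are then not individually identified, but the
fitted *density* — and hence decoding — is stable; tests compare
distribution means, not raw parameters, in this regime.

Each neuron also gets a pooled *background* distribution, fitted to the
final pre-stimulus bin of all its trials plus its stimulation counts
under non-ligand odors. Inhibitory responses need no special casing:
they fit naturally as low-mu distributions pressed against the zero
bound.

## Decoder

For a population response r = (r_1 ... r_J) the posterior over odors is

    P(o_i | r)  propto  P(o_i) * prod_j P(r_j | o_i)

(product of marginals; the OSN classes were recorded one at a time, so
no joint structure is available). Neuron j contributes its response
distribution to odor i when j is in the responding set of i, and its
background distribution otherwise. Likelihoods accumulate in log space
with densities floored at 1e-300; the predicted odor is the posterior
argmax, exact ties broken uniformly at random from the seeded stream
(tie counts are logged and reported). Priors are uniform by default and
renormalized if supplied.

## Cross-validation and synthesis

Accuracy is estimated by leave-one-out cross-validation. Enumerating all
leave-one-out combinations is infeasible (8^J for 8 trials per pair), so
each of `n_cycles` cycles independently draws one held-out trial per
(neuron, odor) pair, refits every distribution on the remainder, then
for each target odor synthesizes a test response: responding neurons
contribute their held-out stimulation count; all other neurons
contribute one draw from their background pool (the same pool the
background fit used, minus the cycle's held-out items). Per-odor
accuracy is percent correct over cycles with a binomial standard error;
the headline number is the unweighted mean over target odors. Responding
pairs need at least 3 trials so the training split keeps >= 2.

A subtlety worth knowing when validating against analytic oracles:
*conditional on one finite dataset*, LOO accuracy of even a completely
uninformative code deviates from chance, because finite per-pair samples
carry idiosyncratic cluster structure that is genuinely present in both
training and test trials. The unconditional expectation (over data
generation) is exactly chance — the held-out test point is independent
of every fitted distribution, making the target's score exchangeable
with the non-targets'. Chance-level and Bayes-error checks therefore
average over independently generated dataset replicates.

## Chance band

Null decoding accuracy is obtained by permuting, within each neuron,
which odor is credited with each trial (stimulation count and
spontaneous bins move together, preserving every neuron's marginal
response distribution and every pair's trial count), re-deriving the
responding set with the criterion, and re-running the identical LOO
pipeline. The *chance band* is the upper (1 - alpha) quantile (default
alpha = 0.01) of mean accuracy over randomizations. The responding set
is recomputed per permutation because the null model's partition into
"responding" and "background" is itself data-derived; pairs left with
fewer than 3 trials are dropped from the permuted responding set.

## Ablation and pairwise discrimination

Greedy backward elimination: at each stage every leave-one-neuron-out
subset is scored with `identify` and the neuron whose removal costs
least accuracy is eliminated (ties broken by lexicographic label,
logged), from the full set down to one neuron.

Pairwise discrimination restricts the dataset to an odor pair {A, B},
fits a 2-odor model with priors 0.5/0.5, and records in cell (A, B) the
percent of cycles target A was decoded as A. Both orderings come from
the same cross-validation run, so the matrix need not be symmetric;
chance is 50%.

## Behavioral statistics

The locomotor assay's response index is `100 * (n_att - n_rep) / n_tot`
in [-100, 100]. Indices are compared against zero with a one-sample
t-test (df = n - 1, two-sided). Masking comparisons use Welch's
two-sample t-test (the variance assumption is not defensible for
plate-level indices); `direction` reports a significant reduction or
increase at the chosen alpha.

## Synthetic-data generator

The generator emulates the statistical structure of the recordings. Per
neuron, spontaneous counts are drawn from a truncated, rounded Gaussian
with sigma defaulting to max(1, mean/2) — chosen to reproduce the large
per-trial spontaneous ranges (means 0.7–7.9 Hz with per-trial range
0–27 Hz) since the recordings constrain means/SEs/ranges but not the
noise family; a Poisson alternative sits behind `spont_family`. A tuned
pair responds on each trial with probability `reliability`; responding
trials draw from the pair's truncated Gaussian (rounded to integer
counts), others from the spontaneous model. Inhibitory pairs use
mu = max(0, spont_mean - 5 Hz).

The `recording_like_spec` preset is a 15-neuron x 18-odor configuration: the
Table-1-style neuron labels with their mean spontaneous rates, ~1/6 of
pairs responding, reliabilities uniform on [0.1, 1], excitatory
magnitudes 8–90 Hz above background (sigma = max(2, 0.2 * delta)),
exactly three inhibitory pairs, one odor exciting seven classes, one
broadly tuned class covering 13 odors, and 8 trials per pair. What the
preset does *not* emulate: correlated trial-to-trial drift across odors,
animal-level effects, adaptation, and any temporal structure inside the
1-s window — so passing tests validate the decoding machinery and its
calibration, not biological conclusions about real recordings.

## Default problem sizes

Study sizes used by the test suite and `scripts/acceptance.py` are
scaled for a desk run while keeping Monte-Carlo error well inside each
check's tolerance: identification 400 cycles, chance band 60
randomizations x 5 cycles, ablation 10 cycles per subset, pairwise
discrimination 60–400 cycles, Bayes-error oracle 4000 cycles pooled over
20 dataset replicates of 400 trials/pair, parameter recovery 200
replicates of n = 50. All randomness flows from explicit seeds; the same
seed reproduces results bit-for-bit, including the generated datasets.

## Known limitations

- The per-trial spike-count noise family of real recordings is unknown
  from summary statistics; the generator exposes it as a switch rather
  than asserting one.
- Truncated-normal parameters are weakly identified for boundary-hugging
  samples (ridge); downstream quantities are stable, but archived raw
  parameters for such pairs should not be interpreted individually.
- The LOO scheme samples hold-out combinations rather than enumerating
  them; with few cycles the per-odor SEs understate between-cycle
  correlation of the shared refit.
- The chance band's quantile resolution is limited by cycles per
  randomization; with 5 cycles x 18 targets the null accuracy grid is
  ~1.1% wide.
- Generated spike counts are integers, so the two-choice oracle's
  realizable optimum sits a few tenths of a percent below the continuous
  Phi(1) value (rounding adds 1/12 of a count of variance and coarsens
  the decision boundary); the oracle check's Monte-Carlo tolerance
  absorbs this.
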