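# Methods

## Model and assumptions

`bnpower` studies a stylised exposure-response system as a categorical
Bayesian network with eight nodes (see README for the node list). The key
assumptions baked into the structure are:

- Exposure and response are three-level classifications; there is no
  continuous dose metric.
- The strength of relationship `R` acts only through the conditional
  distribution of true response given true exposure.
- Measurement error is non-differential: the exposure instrument's error
  depends only on (`AcEM`, `TE`) and the response instrument's only on
  (`AcRM`, `TR`), with one shared error table for both instruments.
- Cases (subjects) are exchangeable and independent given the latent truth
  `(R, AcEM, AcRM)`.
- The analyst knows the instrument accuracies: updating always clamps `AcEM`
  and `AcRM` to the scenario's true values, so the posterior concerns `R`
  alone. Joint inference over unknown accuracies is out of scope.

## Default parameterisation

The published account of this model prints only a handful of numbers (the
prior percentages and a single misclassification entry); its full conditional
probability tables are not available in machine-readable form. The defaults
shipped here are therefore this package's own parameterisation, fixed once by
the constraints the source text does state:

- P(ME = high | AcEM = low, TE = low) = 0.2 (the anchor entry);
- *perfect* accuracy is the identity matrix;
- under R = *none* the response row is uniform (independence);
- under R = *strong* the aligned response has probability ≥ 0.9;
- the error table is symmetric under swapping the *low* and *high* classes,
  and identical for the exposure and response instruments.

Measurement table P(measured | accuracy, truth), rows = truth:

| accuracy | low | medium | high |
|---|---|---|---|
| low | .50 .30 .20 | .25 .50 .25 | .20 .30 .50 |
| high | .80 .15 .05 | .10 .80 .10 | .05 .15 .80 |
| perfect | 1 0 0 | 0 1 0 | 0 0 1 |

Response table P(TR | R, TE), rows = TE:

| R | low | medium | high |
|---|---|---|---|
| none | ⅓ ⅓ ⅓ | ⅓ ⅓ ⅓ | ⅓ ⅓ ⅓ |
| medium | .60 .30 .10 | .20 .60 .20 | .10 .30 .60 |
| strong | .90 .08 .02 | .05 .90 .05 | .02 .08 .90 |

Because these tables are a reconstruction, the package's required-sample-size
table is validated against the *qualitative* structure expected of the system
(accuracy monotonicity, the difficulty ordering medium ≥ none/strong, censored
low-accuracy row, inflated trial-to-trial variance under low accuracy), not
against any externally printed cell values. Users holding the original tables
can reproduce them exactly through a network definition file: every CPT is
overridable via `bnpower.io.load_network`, and
`src/bnpower/data/exposure_response.yaml` documents the format (it reproduces
the code defaults bit-exactly and is asserted to in the tests).

Two modelling ambiguities were resolved as follows. The true-response node has
**three** states; a four-category response would be incompatible with the
nine-state measured-pair outcome and would require redefining `ERMatch`. A
*medium* measurement-accuracy level exists nowhere in the scenario grid
(low/high/perfect); the CPT schema nevertheless accepts arbitrary accuracy
levels through the definition file.

## Inference

All posteriors come from exact enumeration: the joint table (3⁷ × 9 = 19 683
cells for the default network) is materialised as a dense array and
conditioned by indexing and summation. At this size exactness costs
milliseconds and removes approximate-inference error as a confounder in the
power results; junction-tree or importance-sampling algorithms would add
machinery without benefit. Probabilities are handled in linear space inside
the joint table; CPT rows must be normalised within 1e-12 at load, inferred
distributions within 1e-9, and evidence whose total probability falls below
1e-300 raises an inconsistency error rather than returning NaNs.

## Simulation

A scenario clamps `(R, AcEM, AcRM)`; all other nodes are sampled ancestrally
(topological order, inverse-CDF over the declared state order). Sampling
consumes exactly one PCG64 uniform per unclamped node per case, case-major, so
datasets are byte-reproducible from `(network, scenario, n, seed)` across
platforms. True exposure is resampled from its uniform prior for every
subject by default — this exercises the full error table and mimics an
observational study population; a `fix_te` option instead clamps the whole
study at one exposure level (a designed-exposure experiment). Neither mode is
claimed to match any particular historical analysis.

The sampler is validated distributionally: for every scenario, the empirical
nine-outcome frequencies at n = 10⁵ are compared with the exactly inferred
outcome distribution by a chi-square goodness-of-fit test (p > 0.001, fixed
seeds).

## Sequential updating and the two modes

Given the clamped accuracies, cases are conditionally independent given `R`,
so the posterior after k cases is prior × product of per-outcome likelihoods.
The default `exact` mode applies precisely this, accumulating log-likelihoods
(trajectories of 10⁴ cases remain normalised; no underflow). A separate batch
code path computes the same posterior from outcome *counts* in one shot and
serves as an order-free oracle: sequential and batch agree within 1e-9 on
random datasets over all scenarios, and the final posterior is invariant to
permuting the cases.

The `fixed-bf` mode implements the posterior-odds bookkeeping often used with
Bayes factors: BF(o, r) = P(o | r) / P(o | not-r), with "not-r" a mixture of
the remaining states weighted by their share of the prior, and posterior odds
= BF × prior odds per state, renormalised. With only two hypotheses this is
Bayes' rule exactly. With three strength states the complement weights shift
as data accrue, so *freezing* the factors at the initial prior (which is what
makes the shortcut attractive — compute 27 numbers once, reuse forever) is an
approximation: it matches `exact` on the first update to machine precision
and then drifts. On a fixed seeded study (medium truth, high accuracy,
n = 200) the largest pointwise divergence along the trajectory is ≈ 0.279 and
the final-posterior divergence ≈ 0.062; a regression test pins both. `exact`
is the default because it is correct for any number of hypotheses; `fixed-bf`
is provided for comparability with the odds-update convention.

## Power analysis

Each scenario runs 10 replicate trials of up to n_max = 1000 cases (defaults;
both overridable). Trial t uses seed `base_seed + t` with
`base_seed = 20190322` — an arbitrary but fixed constant recorded, together
with every derived seed, in the run record. The required sample size is the
**first** crossing of the across-trial mean posterior of the true strength
above the threshold (0.9 default). First crossing, not sustained crossing, is
a deliberate choice: the mean trajectories are near-monotone where they cross
at all, and a sustained-crossing rule would need an arbitrary window length.
Censored cells are serialised as the string `">1000"` so the CSV stays
round-trippable. Alongside the full trajectories, a summary grid reports the
mean posterior at N = 20, 50, 100 and 1000.

The `misleading_trial_fraction` diagnostic reports the share of replicate
trials whose posterior on the true strength at a given study size is at or
below a bound (0.1 default) — studies that would deliver confident, wrong
conclusions. Under the default parameterisation and seeds this fraction is
positive for the strong-truth/low-accuracy scenario at N = 100, while at
N = 1000 the low-accuracy trials are spread between correct and inconclusive
rather than confidently wrong; with error tables harsher than the defaults
the effect strengthens.

## What the generator does and does not emulate

The simulator produces exactly the world the network describes: categorical
truth, non-differential misclassification, known accuracies, i.i.d. subjects.
Passing tests therefore demonstrate internal coherence (sampler matches exact
inference; updater recovers clamped truth with enough data) and the
qualitative design trade-offs, not performance on real studies, where
confounding, differential misclassification, unknown accuracies, continuous
dose and correlated subjects all exist and are all out of scope here.

## Problem sizes and numerics

The shipped validation uses the full default run (9 scenarios × 10 trials ×
1000 cases), 10⁵-case sampler checks per scenario, and a 10⁴-case underflow
check; the whole suite runs in well under a minute on one CPU. CSV output is
UTF-8, LF-terminated, probabilities at six decimals with each printed row's
rounding residual folded into its largest entry so rows sum to exactly
1.000000; reruns with the same configuration are byte-identical.

## Known limitations

- The default CPTs are a constrained reconstruction (see above); absolute
  required-N values depend on them and should be read as properties of this
  parameterisation, not of any published study.
- The Bayes-factor table's `fixed-bf` mode is intentionally approximate for
  three hypotheses; use `exact` for inference.
- Confounders, multiple exposure metrics, multi-study evidence synthesis and
  unequal exposure priors (beyond the `fix_te` clamp) are not modelled.
- Exact enumeration scales exponentially in the number of nodes; the
  implementation is intended for networks up to ~10⁶ joint states.
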