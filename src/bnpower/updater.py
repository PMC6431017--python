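"""Case-by-case posterior updating of the strength of relationship.

The analyst observes only the per-subject outcome (the nine-state measured
exposure/response pair) and knows the measurement accuracies of the study
design.  Because cases are independent given the strength ``R`` and the
clamped accuracies, the posterior over ``R`` after each case follows from the
outcome likelihoods P(outcome | R, accuracies), obtained once by exact
inference.

Two update modes are provided:

``exact``
    Multiply the prior by the per-state likelihood of the observed outcome and
    renormalise — Bayes' rule applied per case, the default.

``fixed-bf``
    The posterior-odds formulation: for each state, posterior odds = Bayes
    factor × prior odds, with the Bayes factors *frozen* at the complement
    weights of the initial prior, then renormalised.  For two hypotheses this
    coincides with ``exact``; with three strength states the complement
    mixture shifts as data accrue, so the frozen-BF recursion is an
    approximation that increasingly diverges from Bayes' rule.  It is kept as
    an explicit, inspectable alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .bn import Distribution, NetworkSpec, infer_marginal
from .simulate import Dataset, OutcomeCounts

MODES = ("exact", "fixed-bf")


class InconsistentOutcomeError(ValueError):
    """An observed outcome has zero likelihood under every strength state."""


@dataclass(eq=False)
class LikelihoodTable:
    """P(outcome | R state, clamped accuracies) for all 9 × 3 combinations."""

    r_states: tuple[str, ...]
    outcomes: tuple[str, ...]
    acem: str
    acrm: str
    probs: np.ndarray  # shape (len(r_states), len(outcomes)); rows sum to 1

    def prob(self, outcome: str, r_state: str) -> float:
        return float(
            self.probs[self.r_states.index(r_state), self.outcomes.index(outcome)]
        )


@dataclass(eq=False)
class BayesFactorTable:
    """Bayes factors for every (outcome, R state), at fixed reference weights."""

    likelihoods: LikelihoodTable
    reference_prior: Distribution
    bf: dict[tuple[str, str], float]


@dataclass(eq=False)
class PosteriorTrajectory:
    """Posterior over ``R`` after each successive case of one study."""

    prior: Distribution
    r_states: tuple[str, ...]
    outcomes: tuple[str, ...]  # observed outcome per case, in study order
    probs: np.ndarray  # shape (n_cases, len(r_states))

    def __len__(self) -> int:
        return len(self.outcomes)

    def posterior_after(self, i: int) -> Distribution:
        """Posterior after case ``i`` (1-based); ``i = 0`` returns the prior."""
        if i == 0:
            return dict(self.prior)
        return {s: float(p) for s, p in zip(self.r_states, self.probs[i - 1])}

    @property
    def final(self) -> Distribution:
        return self.posterior_after(len(self))


def outcome_likelihoods(
    net: NetworkSpec,
    acem: str,
    acrm: str,
    r_node: str = "R",
    match_node: str = "ERMatch",
) -> LikelihoodTable:
    """Exact P(outcome | R state) with the accuracies clamped as evidence."""
    r_states = net.states(r_node)
    outcomes = net.states(match_node)
    probs = np.empty((len(r_states), len(outcomes)))
    for i, r in enumerate(r_states):
        dist = infer_marginal(net, match_node, {r_node: r, "AcEM": acem, "AcRM": acrm})
        probs[i] = [dist[o] for o in outcomes]
    return LikelihoodTable(r_states, outcomes, acem, acrm, probs)


def _prior_vector(prior: Distribution, r_states: tuple[str, ...]) -> np.ndarray:
    vec = np.array([float(prior[r]) for r in r_states])
    if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"prior {prior!r} is not a distribution over {r_states}")
    return vec


def bayes_factor(
    likelihoods: LikelihoodTable,
    outcome: str,
    r_state: str,
    reference_prior: Distribution,
) -> float:
    """Likelihood of the outcome under one state versus the complement mixture.

    The complement likelihood weights the remaining states by their share of
    the reference prior: w_j = P(R_j) / Σ_{k≠i} P(R_k).
    """
    prior = _prior_vector(reference_prior, likelihoods.r_states)
    i = likelihoods.r_states.index(r_state)
    o = likelihoods.outcomes.index(outcome)
    rest = 1.0 - prior[i]
    if rest <= 0.0:
        raise ValueError(
            f"reference prior puts all mass on {r_state!r}; complement undefined"
        )
    numerator = likelihoods.probs[i, o]
    weights = np.delete(prior, i) / rest
    denominator = float(weights @ np.delete(likelihoods.probs[:, o], i))
    if denominator == 0.0:
        raise InconsistentOutcomeError(
            f"outcome {outcome!r} impossible under every state other than {r_state!r}"
        )
    return float(numerator / denominator)


def bayes_factor_table(
    likelihoods: LikelihoodTable, reference_prior: Distribution
) -> BayesFactorTable:
    bf = {
        (o, r): bayes_factor(likelihoods, o, r, reference_prior)
        for o in likelihoods.outcomes
        for r in likelihoods.r_states
    }
    return BayesFactorTable(likelihoods, dict(reference_prior), bf)


def _fixed_bf_step(
    p: np.ndarray, bft: BayesFactorTable, outcome: str, r_states: tuple[str, ...]
) -> np.ndarray:
    factors = np.array([bft.bf[(outcome, r)] for r in r_states])
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = p / (1.0 - p)
        post_odds = factors * odds
        post = post_odds / (1.0 + post_odds)
    post = np.where(np.isinf(post_odds) | (p >= 1.0), 1.0, post)
    post = np.where(p <= 0.0, 0.0, post)
    total = post.sum()
    if total <= 0.0:
        raise InconsistentOutcomeError(f"outcome {outcome!r} annihilated the posterior")
    return post / total


def update_posterior(
    prior: Distribution,
    likelihoods: LikelihoodTable,
    outcome: str,
    mode: str = "exact",
    bf_table: BayesFactorTable | None = None,
) -> Distribution:
    """Posterior over ``R`` after observing one outcome.

    In ``fixed-bf`` mode the Bayes factors default to the ones implied by
    ``prior`` unless a frozen ``bf_table`` is supplied.
    """
    r_states = likelihoods.r_states
    p = _prior_vector(prior, r_states)
    if mode == "exact":
        o = likelihoods.outcomes.index(outcome)
        unnorm = p * likelihoods.probs[:, o]
        total = unnorm.sum()
        if total <= 0.0:
            raise InconsistentOutcomeError(
                f"outcome {outcome!r} has zero likelihood under every non-null state"
            )
        post = unnorm / total
    elif mode == "fixed-bf":
        bft = bf_table if bf_table is not None else bayes_factor_table(likelihoods, prior)
        post = _fixed_bf_step(p, bft, outcome, r_states)
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return {r: float(v) for r, v in zip(r_states, post)}


def run_trajectory(
    net: NetworkSpec,
    dataset: Dataset,
    prior: Distribution | None = None,
    mode: str = "exact",
) -> PosteriorTrajectory:
    """Fold the per-case update over a study, recording each posterior.

    The accuracies are clamped to the scenario truth throughout (the analyst
    knows the study's measurement quality).  Exact mode accumulates
    log-likelihoods (underflow-safe for arbitrarily long studies); fixed-bf
    mode iterates the posterior-odds recursion with Bayes factors frozen at
    the initial prior.
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    sc = dataset.scenario
    lik = outcome_likelihoods(net, sc.acem, sc.acrm)
    if prior is None:
        prior = infer_marginal(net, "R")
    p0 = _prior_vector(prior, lik.r_states)
    outcomes = tuple(case.match for case in dataset.cases)
    codes = np.array([lik.outcomes.index(o) for o in outcomes])
    if mode == "exact":
        with np.errstate(divide="ignore"):
            log_lik = np.log(lik.probs.T)[codes]  # (n, r)
            log_post = np.cumsum(log_lik, axis=0) + np.log(p0)
        norm = logsumexp(log_post, axis=1)
        if not np.all(np.isfinite(norm)):
            first = int(np.argmin(np.isfinite(norm)))
            raise InconsistentOutcomeError(
                f"outcome {outcomes[first]!r} at case {first + 1} annihilated the posterior"
            )
        probs = np.exp(log_post - norm[:, None])
    else:
        bft = bayes_factor_table(lik, prior)
        probs = np.empty((dataset.n, len(lik.r_states)))
        p = p0
        for i, o in enumerate(outcomes):
            p = _fixed_bf_step(p, bft, o, lik.r_states)
            probs[i] = p
    return PosteriorTrajectory(dict(prior), lik.r_states, outcomes, probs)


def batch_posterior(
    net: NetworkSpec,
    counts: OutcomeCounts,
    prior: Distribution | None = None,
    *,
    acem: str,
    acrm: str,
) -> Distribution:
    """Posterior from outcome counts in one shot, accumulated in log space.

    Serves as the order-free oracle for the sequential exact mode: both answer
    posterior(r) ∝ prior(r) · Π_o P(o | r)^count(o).
    """
    lik = outcome_likelihoods(net, acem, acrm)
    if prior is None:
        prior = infer_marginal(net, "R")
    p0 = _prior_vector(prior, lik.r_states)
    count_vec = np.array([float(counts.get(o, 0)) for o in lik.outcomes])
    with np.errstate(divide="ignore", invalid="ignore"):
        log_post = np.log(p0) + np.where(
            count_vec > 0, count_vec * np.log(lik.probs), 0.0
        ).sum(axis=1)
    total = logsumexp(log_post)
    if not np.isfinite(total):
        raise InconsistentOutcomeError("counts have zero likelihood under every state")
    post = np.exp(log_post - total)
    return {r: float(v) for r, v in zip(lik.r_states, post)}
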