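"""Replicate-trial simulation and required-sample-size (power) analysis.

For each scenario, a fixed number of replicate studies (trials) is simulated
and updated case by case; the ensemble of posterior trajectories shows both
the mean learning curve and the trial-to-trial spread.  The required sample
size is the first study size at which the *mean* posterior probability of the
scenario's true strength reaches a threshold (0.9 by default); a scenario
whose mean never crosses within ``n_max`` cases is reported censored as
``">n_max"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn import NetworkSpec
from .model import ACCURACY_STATES, R_STATES, ScenarioSpec, scenario_catalog
from .simulate import DEFAULT_BASE_SEED, generate_dataset
from .updater import PosteriorTrajectory, run_trajectory

#: study sizes highlighted in summary output alongside the full trajectories
REPORT_GRID = (20, 50, 100, 1000)

DEFAULT_THRESHOLD = 0.9
DEFAULT_N_TRIALS = 10
DEFAULT_N_MAX = 1000


@dataclass(eq=False)
class TrialEnsemble:
    """All replicate trajectories of one scenario, with their seeds."""

    scenario: ScenarioSpec
    n_trials: int
    n_max: int
    mode: str
    seeds: tuple[int, ...]
    trajectories: tuple[PosteriorTrajectory, ...]

    @property
    def r_states(self) -> tuple[str, ...]:
        return self.trajectories[0].r_states

    def posterior_matrix(self) -> np.ndarray:
        """Posteriors stacked as an (n_trials, n_max, n_states) array."""
        return np.stack([t.probs for t in self.trajectories])


@dataclass(eq=False)
class PowerTable:
    """Required N per (accuracy level, true strength); censored cells are strings."""

    cells: dict[tuple[str, str], int | str]
    n_max: int
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [[self.cells[(acc, r)] for r in R_STATES] for acc in ACCURACY_STATES],
            index=pd.Index(ACCURACY_STATES, name="accuracy"),
            columns=list(R_STATES),
        )
        return frame


def run_trials(
    net: NetworkSpec,
    scenario: ScenarioSpec,
    n_max: int = DEFAULT_N_MAX,
    n_trials: int = DEFAULT_N_TRIALS,
    base_seed: int = DEFAULT_BASE_SEED,
    mode: str = "exact",
    fix_te: str | None = None,
) -> TrialEnsemble:
    """Simulate and update ``n_trials`` independent studies of ``n_max`` cases.

    Trial ``t`` (1-based) uses seed ``base_seed + t``, recorded in the
    ensemble for exact reproduction.
    """
    if n_trials < 1 or n_max < 1:
        raise ValueError("n_trials and n_max must be at least 1")
    seeds = tuple(base_seed + t for t in range(1, n_trials + 1))
    trajectories = []
    for seed in seeds:
        dataset = generate_dataset(net, scenario, n_max, seed, fix_te=fix_te)
        trajectories.append(run_trajectory(net, dataset, mode=mode))
    return TrialEnsemble(scenario, n_trials, n_max, mode, seeds, tuple(trajectories))


def mean_trajectory(ensemble: TrialEnsemble) -> np.ndarray:
    """Across-trial mean posterior at each study size, renormalised.

    The mean of normalised distributions is already normalised; the explicit
    renormalisation only sweeps up float rounding.
    """
    mean = ensemble.posterior_matrix().mean(axis=0)
    return mean / mean.sum(axis=1, keepdims=True)


def required_sample_size(
    ensemble: TrialEnsemble, threshold: float = DEFAULT_THRESHOLD
) -> int | str:
    """Smallest N at which the mean posterior of the true strength reaches
    ``threshold`` (first crossing); ``">n_max"`` if it never does."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    true_idx = ensemble.r_states.index(ensemble.scenario.r_true)
    curve = mean_trajectory(ensemble)[:, true_idx]
    hits = np.nonzero(curve >= threshold)[0]
    if hits.size == 0:
        return f">{ensemble.n_max}"
    return int(hits[0]) + 1


def misleading_trial_fraction(
    ensemble: TrialEnsemble, n: int, bound: float = 0.1
) -> float:
    """Fraction of trials whose posterior on the true strength at study size
    ``n`` is at most ``bound`` — studies that would confidently mislead."""
    if not 1 <= n <= ensemble.n_max:
        raise ValueError(f"n must be within 1..{ensemble.n_max}, got {n}")
    true_idx = ensemble.r_states.index(ensemble.scenario.r_true)
    at_n = ensemble.posterior_matrix()[:, n - 1, true_idx]
    return float(np.mean(at_n <= bound))


def ensemble_power_table(
    ensembles: dict[int, TrialEnsemble], threshold: float = DEFAULT_THRESHOLD
) -> PowerTable:
    """Assemble the 3×3 required-N table from per-scenario ensembles."""
    cells: dict[tuple[str, str], int | str] = {}
    n_max = None
    for ens in ensembles.values():
        sc = ens.scenario
        cells[(sc.acem, sc.r_true)] = required_sample_size(ens, threshold)
        n_max = ens.n_max
    missing = {
        (acc, r) for acc in ACCURACY_STATES for r in R_STATES
    } - set(cells)
    if missing:
        raise ValueError(f"ensembles do not cover the full grid; missing {sorted(missing)}")
    return PowerTable(cells, int(n_max), threshold)


def power_table(
    net: NetworkSpec,
    base_seed: int = DEFAULT_BASE_SEED,
    mode: str = "exact",
    n_max: int = DEFAULT_N_MAX,
    n_trials: int = DEFAULT_N_TRIALS,
    threshold: float = DEFAULT_THRESHOLD,
) -> PowerTable:
    """Run all nine scenarios and assemble the required-sample-size table."""
    ensembles = {
        sc.id: run_trials(net, sc, n_max=n_max, n_trials=n_trials,
                          base_seed=base_seed, mode=mode)
        for sc in scenario_catalog()
    }
    return ensemble_power_table(ensembles, threshold)
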