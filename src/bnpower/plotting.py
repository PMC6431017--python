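"""Optional trajectory plots: one 3×3 panel per accuracy level.

Rows are the true strength used to simulate, columns the strength state whose
posterior probability is drawn; the ten replicate trials appear in gray with
their mean in black.  Requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

from pathlib import Path

from .model import R_STATES
from .power import TrialEnsemble, mean_trajectory


def plot_accuracy_panel(
    ensembles: dict[int, TrialEnsemble], accuracy: str, path: str | Path
) -> None:
    """Write the panel for one accuracy level from the scenario ensembles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_truth = {
        ens.scenario.r_true: ens
        for ens in ensembles.values()
        if ens.scenario.acem == accuracy
    }
    missing = set(R_STATES) - set(by_truth)
    if missing:
        raise ValueError(f"no ensemble at accuracy {accuracy!r} for truth {sorted(missing)}")

    fig, axes = plt.subplots(3, 3, figsize=(9, 8), sharex=True, sharey=True)
    for i, truth in enumerate(R_STATES):
        ens = by_truth[truth]
        mean = mean_trajectory(ens)
        x = range(1, ens.n_max + 1)
        for j, predicted in enumerate(R_STATES):
            ax = axes[i][j]
            k = ens.r_states.index(predicted)
            for traj in ens.trajectories:
                ax.plot(x, traj.probs[:, k], color="0.7", lw=0.6)
            ax.plot(x, mean[:, k], color="black", lw=1.5)
            ax.set_ylim(0, 1)
            if i == 0:
                ax.set_title(f"P(R = {predicted})")
            if j == 0:
                ax.set_ylabel(f"true R = {truth}")
            if i == 2:
                ax.set_xlabel("sample size N")
    fig.suptitle(f"Posterior trajectories, accuracy = {accuracy}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
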