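"""File formats: network definition YAML, dataset/trajectory/power CSV, run records.

All CSV output is UTF-8, comma-separated, LF-terminated, with probabilities
printed to six decimal places — fixed so that reruns with the same
configuration are byte-identical across platforms.
"""

from __future__ import annotations

import csv
import datetime
import itertools
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import __version__
from .bn import Cpt, NetworkError, NetworkSpec, NodeSpec, validate_network
from .model import ScenarioSpec, scenario_catalog
from .power import PowerTable, TrialEnsemble, mean_trajectory
from .simulate import CaseRecord, Dataset
from .updater import PosteriorTrajectory

PROB_DECIMALS = 6


class DatasetFormatError(ValueError):
    """A dataset CSV (or its metadata) could not be parsed; names the line."""


# ---------------------------------------------------------------------------
# network definition files

def network_to_dict(spec: NetworkSpec) -> dict:
    nodes = []
    for node in spec.nodes:
        cpt = spec.cpts[node.name]
        combos = itertools.product(*(spec.states(p) for p in node.parents))
        nodes.append(
            {
                "name": node.name,
                "states": list(node.states),
                "parents": list(node.parents),
                "cpt": [
                    {"given": list(combo), "p": [float(x) for x in cpt.table[combo]]}
                    for combo in combos
                ],
            }
        )
    return {"name": spec.name, "nodes": nodes}


def save_network(spec: NetworkSpec, path: str | Path) -> None:
    """Write a network definition file (YAML).  Floats round-trip exactly."""
    Path(path).write_text(
        yaml.safe_dump(network_to_dict(spec), sort_keys=False), encoding="utf-8"
    )


def network_from_dict(obj: dict) -> NetworkSpec:
    nodes = []
    cpts = {}
    for block in obj["nodes"]:
        node = NodeSpec(block["name"], tuple(block["states"]), tuple(block["parents"]))
        nodes.append(node)
        table = {
            tuple(row["given"]): tuple(float(p) for p in row["p"])
            for row in block["cpt"]
        }
        cpts[node.name] = Cpt(node.name, node.parents, table)
    spec = NetworkSpec(tuple(nodes), cpts, name=obj.get("name", "network"))
    violations = validate_network(spec)
    if violations:
        raise NetworkError(
            "invalid network definition:\n" + "\n".join(f"- {v}" for v in violations)
        )
    return spec


def load_network(path: str | Path) -> NetworkSpec:
    """Load and validate a network definition file; raises on any violation."""
    with open(path, encoding="utf-8") as fh:
        return network_from_dict(yaml.safe_load(fh))


def default_network_path() -> Path:
    """The canonical shipped definition file of the default network."""
    return Path(resources.files("bnpower").joinpath("data/exposure_response.yaml"))


# ---------------------------------------------------------------------------
# datasets

def write_dataset(dataset: Dataset, csv_path: str | Path,
                  meta_path: str | Path | None = None) -> None:
    """Write a dataset CSV and its companion JSON metadata."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["case_index", "te", "tr", "me", "mr", "match"])
        for i, case in enumerate(dataset.cases, start=1):
            writer.writerow([i, case.te, case.tr, case.me, case.mr, case.match])
    sc = dataset.scenario
    meta = {
        "scenario": {"id": sc.id, "r_true": sc.r_true, "acem": sc.acem, "acrm": sc.acrm},
        "clamps": dataset.clamps,
        "n": dataset.n,
        "seed": dataset.seed,
        "fix_te": dataset.fix_te,
        "package": "bnpower",
        "version": __version__,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def read_dataset(csv_path: str | Path,
                 meta_path: str | Path | None = None) -> Dataset:
    """Read a dataset CSV plus metadata back into a :class:`Dataset`."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    try:
        meta = json.loads(Path(meta_path).read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise DatasetFormatError(f"metadata file {meta_path} not found") from None
    except json.JSONDecodeError as exc:
        raise DatasetFormatError(f"metadata file {meta_path}: {exc}") from None
    sc = meta["scenario"]
    scenario = ScenarioSpec(sc["id"], sc["r_true"], sc["acem"], sc["acrm"])
    cases = []
    with open(csv_path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["case_index", "te", "tr", "me", "mr", "match"]:
            raise DatasetFormatError(f"{csv_path}: line 1: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 6:
                raise DatasetFormatError(
                    f"{csv_path}: line {lineno}: expected 6 fields, got {len(row)}"
                )
            cases.append(CaseRecord(te=row[1], tr=row[2], me=row[3], mr=row[4], match=row[5]))
    return Dataset(scenario=scenario, seed=int(meta["seed"]), cases=tuple(cases),
                   fix_te=meta.get("fix_te"))


# ---------------------------------------------------------------------------
# trajectories / ensembles / power tables

def _prob(x: float) -> str:
    return f"{x:.{PROB_DECIMALS}f}"


def _prob_row(probs) -> list[str]:
    """Format a distribution so the printed values sum to exactly 1.

    Rounding each entry independently can leave the printed row off by up to
    1.5 ulp at the last decimal; the residual is folded into the largest entry.
    """
    quantum = 10 ** -PROB_DECIMALS
    rounded = [round(float(p), PROB_DECIMALS) for p in probs]
    residual = round((1.0 - sum(rounded)) / quantum)
    rounded[rounded.index(max(rounded))] += residual * quantum
    return [_prob(p) for p in rounded]


def write_trajectories(
    items: Iterable[tuple[int, PosteriorTrajectory]], path: str | Path
) -> None:
    """Write (trial, trajectory) pairs as one CSV.

    Columns: trial, case_index, outcome, then one ``p_<state>`` column per
    strength state, probabilities to six decimals.
    """
    items = list(items)
    r_states = items[0][1].r_states
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["trial", "case_index", "outcome"] + [f"p_{r}" for r in r_states])
        for trial, traj in items:
            for i, outcome in enumerate(traj.outcomes, start=1):
                writer.writerow([trial, i, outcome] + _prob_row(traj.probs[i - 1]))


def write_ensemble(ensemble: TrialEnsemble, path: str | Path) -> None:
    write_trajectories(
        zip(range(1, ensemble.n_trials + 1), ensemble.trajectories), path
    )


def write_power_table(table: PowerTable, path: str | Path) -> None:
    """Power table CSV: accuracy rows × strength columns; censored cells as '>n'."""
    frame = table.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["accuracy"] + list(frame.columns))
        for acc, row in frame.iterrows():
            writer.writerow([acc] + [str(v) for v in row])


def write_report_grid(
    ensembles: dict[int, TrialEnsemble], path: str | Path,
    grid: Sequence[int] | None = None,
) -> None:
    """Mean posterior of every scenario at the highlighted study sizes."""
    from .power import REPORT_GRID

    grid = list(grid if grid is not None else REPORT_GRID)
    first = next(iter(ensembles.values()))
    r_states = first.r_states
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["scenario", "r_true", "accuracy", "n"]
                        + [f"p_{r}" for r in r_states])
        for sid in sorted(ensembles):
            ens = ensembles[sid]
            mean = mean_trajectory(ens)
            for n in grid:
                if n > ens.n_max:
                    continue
                writer.writerow(
                    [sid, ens.scenario.r_true, ens.scenario.acem, n]
                    + _prob_row(mean[n - 1])
                )


def write_scenarios(path: str | Path) -> None:
    """Export the scenario catalog as CSV (id, r_true, acem, acrm)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "r_true", "acem", "acrm"])
        for sc in scenario_catalog():
            writer.writerow([sc.id, sc.r_true, sc.acem, sc.acrm])


def write_run_record(
    path: str | Path, config: dict, trial_seeds: dict[int, Sequence[int]] | None = None
) -> None:
    """Record everything needed to regenerate a run's outputs byte-exactly."""
    record = {
        "package": "bnpower",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "trial_seeds": {str(k): list(v) for k, v in (trial_seeds or {}).items()},
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")
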