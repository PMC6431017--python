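"""Seeded synthetic study generation by ancestral (forward) sampling.

A scenario clamps the latent truth (``R`` and the two accuracy nodes); every
other node is sampled in topological order from its CPT row given the sampled
or clamped parents.  Sampling is inverse-CDF over the declared state order and
consumes exactly one PCG64 uniform per unclamped node per case, case-major, so
a dataset is a pure function of (network, clamps, n, seed) across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .bn import Evidence, MalformedAssignmentError, NetworkSpec, cpt_array
from .model import ER_MATCH_STATES, ScenarioSpec

#: default base seed for replicate trials; trial t uses base_seed + t
DEFAULT_BASE_SEED = 20190322

#: ERMatch outcome -> count for one dataset
OutcomeCounts = dict[str, int]


@dataclass(frozen=True)
class CaseRecord:
    """One simulated subject: true and measured classes plus the compiled outcome."""

    te: str
    tr: str
    me: str
    mr: str
    match: str


@dataclass(frozen=True)
class Dataset:
    """An ordered synthetic study of ``n`` cases, reproducible from (scenario, seed)."""

    scenario: ScenarioSpec
    seed: int
    cases: tuple[CaseRecord, ...]
    fix_te: str | None = None

    @property
    def n(self) -> int:
        return len(self.cases)

    @property
    def clamps(self) -> dict[str, str]:
        clamps = self.scenario.clamps
        if self.fix_te is not None:
            clamps["TE"] = self.fix_te
        return clamps

    def permuted(self, order: np.ndarray) -> "Dataset":
        return replace(self, cases=tuple(self.cases[i] for i in order))


def _ancestral_codes(
    net: NetworkSpec, clamps: Mapping[str, str], n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Sample integer state codes for every node of ``n`` cases.

    Clamped nodes consume no randomness; each unclamped node consumes one
    uniform per case.  The uniforms are drawn as one (n, k) block, which is
    identical to drawing them one by one case-major.
    """
    for name in clamps:
        net.state_index(name, clamps[name])  # raises on malformed scenario
    codes: dict[str, np.ndarray] = {}
    free = [node for node in net.nodes if node.name not in clamps]
    u = rng.random((n, len(free)))
    j = 0
    for node in net.nodes:
        if node.name in clamps:
            codes[node.name] = np.full(
                n, net.state_index(node.name, clamps[node.name]), dtype=np.int64
            )
            continue
        cpt = net.cpts[node.name]
        arr = cpt_array(net, node.name)
        if cpt.parent_order:
            rows = arr[tuple(codes[p] for p in cpt.parent_order)]
        else:
            rows = np.broadcast_to(arr, (n, arr.shape[0]))
        cum = np.cumsum(rows, axis=1)
        drawn = (u[:, j, None] >= cum).sum(axis=1)
        codes[node.name] = np.minimum(drawn, len(node.states) - 1)
        j += 1
    return codes


def _to_records(net: NetworkSpec, codes: Mapping[str, np.ndarray]) -> tuple[CaseRecord, ...]:
    labels = {name: net.states(name) for name in ("TE", "TR", "ME", "MR", "ERMatch")}
    n = len(codes["TE"])
    return tuple(
        CaseRecord(
            te=labels["TE"][codes["TE"][i]],
            tr=labels["TR"][codes["TR"][i]],
            me=labels["ME"][codes["ME"][i]],
            mr=labels["MR"][codes["MR"][i]],
            match=labels["ERMatch"][codes["ERMatch"][i]],
        )
        for i in range(n)
    )


def sample_case(
    net: NetworkSpec, clamped: Evidence, rng: np.random.Generator
) -> CaseRecord:
    """Draw a single case given the scenario's clamped nodes."""
    return _to_records(net, _ancestral_codes(net, clamped, 1, rng))[0]


def generate_dataset(
    net: NetworkSpec,
    scenario: ScenarioSpec,
    n: int,
    seed: int,
    fix_te: str | None = None,
) -> Dataset:
    """Simulate a study of ``n`` subjects under a scenario's true conditions.

    ``R``, ``AcEM`` and ``AcRM`` are clamped to the scenario truth; ``TE`` is
    drawn from its uniform prior per subject unless ``fix_te`` pins the whole
    study at one exposure level.
    """
    if n < 1:
        raise ValueError(f"sample size must be at least 1, got {n}")
    clamps = dict(scenario.clamps)
    if fix_te is not None:
        net.state_index("TE", fix_te)
        clamps["TE"] = fix_te
    rng = np.random.default_rng(seed)
    codes = _ancestral_codes(net, clamps, n, rng)
    return Dataset(scenario=scenario, seed=seed, cases=_to_records(net, codes), fix_te=fix_te)


def outcome_frequencies(dataset: Dataset) -> OutcomeCounts:
    """Count each of the nine ERMatch outcomes; counts sum to ``dataset.n``."""
    counts = {state: 0 for state in ER_MATCH_STATES}
    for case in dataset.cases:
        counts[case.match] += 1
    return counts
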