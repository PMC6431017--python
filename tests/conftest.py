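"""Shared fixtures: the default network, a brute-force inference oracle, and
the full default power run (computed once per session)."""

from __future__ import annotations

import itertools

import pytest

import bnpower as bp


@pytest.fixture(scope="session")
def net() -> bp.NetworkSpec:
    return bp.default_network()


@pytest.fixture(scope="session")
def enumerated_joint(net):
    """Independent full-joint table: one chain-rule product per assignment.

    Deliberately avoids the package's array-based joint construction so it can
    serve as an oracle for it.
    """
    names = [n.name for n in net.nodes]
    entries = {}
    for combo in itertools.product(*(n.states for n in net.nodes)):
        assign = dict(zip(names, combo))
        prob = 1.0
        for node in net.nodes:
            cpt = net.cpts[node.name]
            row = cpt.table[tuple(assign[p] for p in cpt.parent_order)]
            prob *= row[node.states.index(assign[node.name])]
        entries[combo] = prob
    return names, entries


@pytest.fixture(scope="session")
def oracle_marginal(net, enumerated_joint):
    """Posterior P(query | evidence) by filtering the enumerated joint.

    Returns None when the evidence has zero total probability.
    """
    names, entries = enumerated_joint
    pos = {name: i for i, name in enumerate(names)}

    def _marginal(query: str, evidence: dict[str, str]) -> dict[str, float] | None:
        fixed = [(pos[k], v) for k, v in evidence.items()]
        qi = pos[query]
        probs = dict.fromkeys(net.states(query), 0.0)
        for combo, p in entries.items():
            if all(combo[i] == v for i, v in fixed):
                probs[combo[qi]] += p
        total = sum(probs.values())
        if total <= 0.0:
            return None
        return {s: v / total for s, v in probs.items()}

    return _marginal


@pytest.fixture(scope="session")
def default_ensembles(net):
    """The full default power run: 9 scenarios x 10 trials x 1000 cases."""
    return {sc.id: bp.run_trials(net, sc) for sc in bp.scenario_catalog()}
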