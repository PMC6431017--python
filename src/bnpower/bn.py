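"""Discrete Bayesian networks: validation, joint evaluation, exact inference.

This module handles small categorical networks — a directed acyclic graph in
which every node carries a conditional probability table (CPT) over its states
given each combination of its parents' states.  The joint distribution is the
chain-rule product of the CPT entries.

Inference here is *exact*: the full joint table is materialised as a dense
array (one axis per node) and conditional marginals are obtained by indexing
and summation.  For the networks this package targets the joint has on the
order of 10^4 cells, so exactness is cheap and no message-passing or sampling
approximation is ever involved in a posterior.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

#: tolerance for each CPT row to sum to one (checked by :func:`validate_network`)
ROW_SUM_TOL = 1e-12

#: evidence whose total probability falls below this is treated as impossible
MIN_EVIDENCE_PROB = 1e-300


class NetworkError(ValueError):
    """Base class for structural problems with a network or a query."""


class MalformedAssignmentError(NetworkError):
    """An assignment or evidence refers to unknown nodes/states or is incomplete."""


class InconsistentEvidenceError(NetworkError):
    """The supplied evidence has (numerically) zero probability under the network."""


#: Evidence maps node name -> observed state label.
Evidence = Mapping[str, str]

#: Distribution maps state label -> probability (sums to one).
Distribution = dict[str, float]


@dataclass(frozen=True)
class NodeSpec:
    """One categorical node: its name, ordered state labels, and parent names.

    The declared state order is canonical: CPT rows, sampled integer codes and
    all serialised output follow it.  Labels are case-sensitive.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table for one node.

    ``table`` maps each full combination of parent states (a tuple ordered as
    ``parent_order``) to a probability row over the child's states.  A root
    node has a single row keyed by the empty tuple.
    """

    child: str
    parent_order: tuple[str, ...]
    table: dict[tuple[str, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_order", tuple(self.parent_order))
        object.__setattr__(
            self,
            "table",
            {tuple(k): tuple(float(p) for p in v) for k, v in self.table.items()},
        )


@dataclass(frozen=True)
class NetworkSpec:
    """A Bayesian network: nodes in topological order plus one CPT per node."""

    nodes: tuple[NodeSpec, ...]
    cpts: dict[str, Cpt]
    name: str = "network"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "_by_name", {n.name: n for n in self.nodes})

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> NodeSpec:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise MalformedAssignmentError(f"unknown node {name!r}") from None

    def states(self, name: str) -> tuple[str, ...]:
        return self.node(name).states

    def state_index(self, name: str, state: str) -> int:
        node = self.node(name)
        try:
            return node.states.index(state)
        except ValueError:
            raise MalformedAssignmentError(
                f"unknown state {state!r} for node {name!r}"
            ) from None

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(n.states) for n in self.nodes)

    def n_assignments(self) -> int:
        return int(np.prod(self.shape))


def validate_network(spec: NetworkSpec) -> list[str]:
    """Check a network for structural defects; return a list of violations.

    An empty list means the network is valid: the graph is acyclic, nodes are
    declared parents-first, every node has a complete CPT and every CPT row is
    normalised within :data:`ROW_SUM_TOL`.  Violations are described, not
    raised, so a caller can report them all at once.
    """
    violations: list[str] = []
    names = [n.name for n in spec.nodes]
    for name in sorted({n for n in names if names.count(n) > 1}):
        violations.append(f"node {name!r} declared more than once")
    known = set(names)

    for node in spec.nodes:
        if len(node.states) < 2:
            violations.append(f"node {node.name!r} has fewer than 2 states")
        if len(set(node.states)) != len(node.states):
            violations.append(f"node {node.name!r} has duplicate state labels")
        for p in node.parents:
            if p not in known:
                violations.append(f"node {node.name!r} references unknown parent {p!r}")

    graph = nx.DiGraph()
    graph.add_nodes_from(known)
    graph.add_edges_from(
        (p, node.name) for node in spec.nodes for p in node.parents if p in known
    )
    if not nx.is_directed_acyclic_graph(graph):
        cycle = " -> ".join(u for u, _ in nx.find_cycle(graph))
        violations.append(f"graph contains a cycle: {cycle}")
    else:
        pos = {name: i for i, name in enumerate(names)}
        for node in spec.nodes:
            for p in node.parents:
                if p in pos and pos[p] > pos[node.name]:
                    violations.append(
                        f"node {node.name!r} is declared before its parent {p!r}"
                        " (nodes must be in topological order)"
                    )

    for name in spec.cpts:
        if name not in known:
            violations.append(f"CPT given for unknown node {name!r}")
    for node in spec.nodes:
        cpt = spec.cpts.get(node.name)
        if cpt is None:
            violations.append(f"node {node.name!r} has no CPT")
            continue
        if cpt.child != node.name:
            violations.append(f"CPT for {node.name!r} names child {cpt.child!r}")
        if cpt.parent_order != node.parents:
            violations.append(
                f"CPT for {node.name!r} conditions on {cpt.parent_order!r},"
                f" node declares parents {node.parents!r}"
            )
            continue
        if any(p not in known for p in node.parents):
            continue  # cannot enumerate combinations of an unknown parent
        expected = set(itertools.product(*(spec.node(p).states for p in node.parents)))
        present = set(cpt.table)
        for combo in sorted(expected - present):
            violations.append(f"CPT for {node.name!r} missing row for parents {combo!r}")
        for combo in sorted(present - expected):
            violations.append(f"CPT for {node.name!r} has spurious row {combo!r}")
        for combo in sorted(present & expected):
            row = cpt.table[combo]
            if len(row) != len(node.states):
                violations.append(
                    f"CPT row {combo!r} of node {node.name!r} has {len(row)} entries,"
                    f" expected {len(node.states)}"
                )
                continue
            if any(p < 0.0 or p > 1.0 for p in row):
                violations.append(
                    f"CPT row {combo!r} of node {node.name!r} has entries outside [0, 1]"
                )
            total = float(sum(row))
            if abs(total - 1.0) > ROW_SUM_TOL:
                violations.append(
                    f"CPT row {combo!r} of node {node.name!r} sums to {total!r}, not 1"
                )
    return violations


def joint_probability(spec: NetworkSpec, assignment: Evidence) -> float:
    """Probability of one full assignment: the chain-rule product of CPT entries.

    ``assignment`` must assign exactly one state to every node of the network.
    """
    given = set(assignment)
    missing = set(spec.node_names) - given
    extra = given - set(spec.node_names)
    if missing or extra:
        raise MalformedAssignmentError(
            f"assignment must cover every node exactly; missing={sorted(missing)},"
            f" unknown={sorted(extra)}"
        )
    prob = 1.0
    for node in spec.nodes:
        cpt = spec.cpts[node.name]
        key = tuple(assignment[p] for p in cpt.parent_order)
        try:
            row = cpt.table[key]
        except KeyError:
            raise MalformedAssignmentError(
                f"no CPT row for node {node.name!r} with parent states {key!r}"
            ) from None
        prob *= row[spec.state_index(node.name, assignment[node.name])]
    return prob


def cpt_array(spec: NetworkSpec, name: str) -> np.ndarray:
    """The CPT of ``name`` as an array with axes (*parents in order*, child)."""
    node = spec.node(name)
    cpt = spec.cpts[name]
    shape = tuple(len(spec.states(p)) for p in cpt.parent_order) + (len(node.states),)
    arr = np.empty(shape)
    for combo, row in cpt.table.items():
        idx = tuple(spec.state_index(p, s) for p, s in zip(cpt.parent_order, combo))
        arr[idx] = row
    return arr


def joint_table(spec: NetworkSpec) -> np.ndarray:
    """The dense joint probability table, one axis per node in declared order."""
    axis = {n.name: i for i, n in enumerate(spec.nodes)}
    shape = spec.shape
    joint = np.ones(shape)
    for node in spec.nodes:
        cpt = spec.cpts[node.name]
        dims = [axis[p] for p in cpt.parent_order] + [axis[node.name]]
        factor = cpt_array(spec, node.name).transpose(np.argsort(dims))
        newshape = [1] * len(shape)
        for d in dims:
            newshape[d] = shape[d]
        joint = joint * factor.reshape(newshape)
    return joint


def _check_evidence(spec: NetworkSpec, evidence: Evidence) -> dict[str, str]:
    checked = {}
    for name, state in dict(evidence).items():
        spec.state_index(name, state)  # raises on unknown node/state
        checked[name] = state
    return checked


def infer_marginal(
    spec: NetworkSpec, query: str, evidence: Evidence | None = None
) -> Distribution:
    """Exact conditional marginal P(query | evidence) by full-joint summation.

    Sums the joint probability over every completion of the evidence, then
    normalises.  Evidence with total probability below
    :data:`MIN_EVIDENCE_PROB` raises :class:`InconsistentEvidenceError` rather
    than returning NaNs.
    """
    qstates = spec.states(query)
    evidence = _check_evidence(spec, evidence or {})
    joint = joint_table(spec)
    index = tuple(
        spec.state_index(n.name, evidence[n.name]) if n.name in evidence else slice(None)
        for n in spec.nodes
    )
    sub = joint[index]
    total = float(sub.sum())
    if total < MIN_EVIDENCE_PROB:
        raise InconsistentEvidenceError(
            f"evidence {evidence!r} has zero probability under the network"
        )
    if query in evidence:
        return {s: (1.0 if s == evidence[query] else 0.0) for s in qstates}
    free = [n.name for n in spec.nodes if n.name not in evidence]
    qaxis = free.index(query)
    marg = sub.sum(axis=tuple(i for i in range(sub.ndim) if i != qaxis)) / total
    return {s: float(p) for s, p in zip(qstates, marg)}
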