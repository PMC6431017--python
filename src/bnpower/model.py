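"""The eight-node exposure-response network and its scenario grid.

The network couples a latent exposure-response system to an imperfect
measurement process:

* ``R`` — strength of the exposure-response relationship (``none`` /
  ``medium`` / ``strong``); the quantity a study tries to learn.
* ``TE``, ``TR`` — true exposure and true response of a subject (``low`` /
  ``medium`` / ``high``).  ``TR`` depends on ``TE`` and ``R``: under ``none``
  the response is independent of exposure, under ``strong`` it almost always
  tracks it.
* ``AcEM``, ``AcRM`` — accuracy of the exposure and response measurement
  instruments (``low`` / ``high`` / ``perfect``).
* ``ME``, ``MR`` — measured exposure and response, noisy readings of ``TE``
  and ``TR`` whose error rate is set by the accuracy nodes; ``perfect``
  accuracy is the identity.
* ``ERMatch`` — the recorded study outcome for one subject: the pair of
  measured classes, nine states ``ll`` … ``hh``, a deterministic function of
  (``ME``, ``MR``).

Default CPTs
------------
The published description of this model pins only a handful of entries, so the
default tables shipped here are this package's own parameterisation, fixed by
the documented constraints: P(ME=high | AcEM=low, TE=low) = 0.2; perfect
accuracy is the identity matrix; no relationship means a uniform response row;
a strong relationship gives ≥ 0.9 mass to the aligned response; the exposure
and response instruments share one error model, symmetric under swapping the
``low`` and ``high`` classes.  Every table can be overridden through a network
definition file (see :mod:`bnpower.io`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .bn import Cpt, MalformedAssignmentError, NetworkSpec, NodeSpec

ACCURACY_STATES = ("low", "high", "perfect")
LEVEL_STATES = ("low", "medium", "high")
R_STATES = ("none", "medium", "strong")
#: measured-exposure class paired with measured-response class, e.g. "lm"
ER_MATCH_STATES = tuple(me[0] + mr[0] for me in LEVEL_STATES for mr in LEVEL_STATES)

#: P(measured | accuracy, truth) — one error model for both instruments
MEASUREMENT_CPT: dict[str, dict[str, tuple[float, float, float]]] = {
    "low": {
        "low": (0.50, 0.30, 0.20),
        "medium": (0.25, 0.50, 0.25),
        "high": (0.20, 0.30, 0.50),
    },
    "high": {
        "low": (0.80, 0.15, 0.05),
        "medium": (0.10, 0.80, 0.10),
        "high": (0.05, 0.15, 0.80),
    },
    "perfect": {
        "low": (1.0, 0.0, 0.0),
        "medium": (0.0, 1.0, 0.0),
        "high": (0.0, 0.0, 1.0),
    },
}

#: P(true response | strength of relationship, true exposure)
RESPONSE_CPT: dict[str, dict[str, tuple[float, float, float]]] = {
    "none": {lvl: (1 / 3, 1 / 3, 1 / 3) for lvl in LEVEL_STATES},
    "medium": {
        "low": (0.60, 0.30, 0.10),
        "medium": (0.20, 0.60, 0.20),
        "high": (0.10, 0.30, 0.60),
    },
    "strong": {
        "low": (0.90, 0.08, 0.02),
        "medium": (0.05, 0.90, 0.05),
        "high": (0.02, 0.08, 0.90),
    },
}

#: prior on the strength of relationship: half the mass on "no relationship",
#: the rest split evenly between medium and strong
R_PRIOR = {"none": 0.50, "medium": 0.25, "strong": 0.25}

UNIFORM3 = (1 / 3, 1 / 3, 1 / 3)


def er_match_state(me: str, mr: str) -> str:
    """Compile a measured (exposure, response) pair into its ERMatch label.

    The label concatenates the first letters of the two classes; the mapping
    is a bijection over the nine pairs.
    """
    if me not in LEVEL_STATES or mr not in LEVEL_STATES:
        raise MalformedAssignmentError(
            f"measured states must be one of {LEVEL_STATES}, got ({me!r}, {mr!r})"
        )
    return me[0] + mr[0]


def default_network() -> NetworkSpec:
    """Build the exposure-response network with the default parameterisation."""
    nodes = (
        NodeSpec("AcEM", ACCURACY_STATES),
        NodeSpec("AcRM", ACCURACY_STATES),
        NodeSpec("TE", LEVEL_STATES),
        NodeSpec("R", R_STATES),
        NodeSpec("TR", LEVEL_STATES, parents=("R", "TE")),
        NodeSpec("ME", LEVEL_STATES, parents=("AcEM", "TE")),
        NodeSpec("MR", LEVEL_STATES, parents=("AcRM", "TR")),
        NodeSpec("ERMatch", ER_MATCH_STATES, parents=("ME", "MR")),
    )
    measurement = {
        (acc, truth): MEASUREMENT_CPT[acc][truth]
        for acc in ACCURACY_STATES
        for truth in LEVEL_STATES
    }
    match_rows = {
        (me, mr): tuple(
            1.0 if s == er_match_state(me, mr) else 0.0 for s in ER_MATCH_STATES
        )
        for me in LEVEL_STATES
        for mr in LEVEL_STATES
    }
    cpts = {
        "AcEM": Cpt("AcEM", (), {(): UNIFORM3}),
        "AcRM": Cpt("AcRM", (), {(): UNIFORM3}),
        "TE": Cpt("TE", (), {(): UNIFORM3}),
        "R": Cpt("R", (), {(): tuple(R_PRIOR[r] for r in R_STATES)}),
        "TR": Cpt(
            "TR",
            ("R", "TE"),
            {
                (r, te): RESPONSE_CPT[r][te]
                for r in R_STATES
                for te in LEVEL_STATES
            },
        ),
        "ME": Cpt("ME", ("AcEM", "TE"), measurement),
        "MR": Cpt("MR", ("AcRM", "TR"), dict(measurement)),
        "ERMatch": Cpt("ERMatch", ("ME", "MR"), match_rows),
    }
    return NetworkSpec(nodes, cpts, name="exposure_response")


@dataclass(frozen=True)
class ScenarioSpec:
    """One study-design scenario: a true strength × a measurement accuracy.

    The exposure and response accuracies are varied together, so the grid of
    (true R, accuracy) pairs has nine cells.
    """

    id: int
    r_true: str
    acem: str
    acrm: str

    def __post_init__(self) -> None:
        if self.r_true not in R_STATES:
            raise ValueError(f"unknown strength {self.r_true!r}")
        if self.acem not in ACCURACY_STATES or self.acrm not in ACCURACY_STATES:
            raise ValueError(f"unknown accuracy {(self.acem, self.acrm)!r}")

    @property
    def clamps(self) -> dict[str, str]:
        """The nodes held at their true value while simulating this scenario."""
        return {"R": self.r_true, "AcEM": self.acem, "AcRM": self.acrm}

    @property
    def label(self) -> str:
        return f"{self.id}:{self.r_true}/{self.acem}-{self.acrm}"


def scenario_catalog() -> list[ScenarioSpec]:
    """The nine scenarios: strengths (none, medium, strong) × accuracies
    (low, high, perfect), ids 1–9 in that nesting order."""
    return [
        ScenarioSpec(i + 1, r, acc, acc)
        for i, (r, acc) in enumerate(itertools.product(R_STATES, ACCURACY_STATES))
    ]


def scenario_by_id(scenario_id: int) -> ScenarioSpec:
    if not 1 <= scenario_id <= 9:
        raise ValueError(f"scenario id must be between 1 and 9, got {scenario_id}")
    return scenario_catalog()[scenario_id - 1]
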