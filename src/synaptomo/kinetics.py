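"""AMPA receptor kinetic state schemes.

A :class:`KineticScheme` is a labelled continuous-time Markov topology
with two kinds of transitions: glutamate-binding steps (bimolecular,
rates in M^-1 s^-1) and unimolecular steps (s^-1). The shipped default
(``data/ampar_kinetics.yaml``) is a six-state scheme in which receptors
must bind two glutamate molecules before a single open state becomes
reachable, and each bound state can fall into a long-lived desensitized
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = ["Transition", "KineticScheme", "MOLAR_TO_PER_NM3",
           "M_INV_S_TO_NM3_PER_US"]

#: 1 M in molecules / nm^3
MOLAR_TO_PER_NM3 = 6.02214076e23 / 1e24
#: 1 M^-1 s^-1 in nm^3 / us
M_INV_S_TO_NM3_PER_US = 1.0 / MOLAR_TO_PER_NM3 / 1e6

GLU_BINDING = "glutamate-binding"
UNIMOLECULAR = "unimolecular"


@dataclass(frozen=True)
class Transition:
    src: str
    dst: str
    rate: float          # M^-1 s^-1 if binding, s^-1 otherwise
    order: str           # "glutamate-binding" | "unimolecular"


class KineticScheme:
    """Receptor state topology with validated transition structure."""

    def __init__(self, states: list[str], transitions: list[Transition],
                 name: str = "custom"):
        self.states = list(states)
        self.transitions = list(transitions)
        self.name = name
        self.index = {s: i for i, s in enumerate(self.states)}
        self._validate()

    def _validate(self) -> None:
        for t in self.transitions:
            if t.src not in self.index or t.dst not in self.index:
                raise ValueError(f"unknown state in transition {t}")
            if t.rate < 0:
                raise ValueError(f"negative rate in {t}")
            if t.order not in (GLU_BINDING, UNIMOLECULAR):
                raise ValueError(f"unknown order {t.order!r}")
        binding = {(t.src, t.dst) for t in self.transitions
                   if t.order == GLU_BINDING}
        if binding - {("C0", "C1"), ("C1", "C2")}:
            raise ValueError("only C0->C1 and C1->C2 may bind glutamate")
        into_o = {t.src for t in self.transitions if t.dst == "O"}
        if into_o - {"C2"}:
            raise ValueError("the open state is reachable only from C2")
        if {t.src for t in self.transitions if t.dst == "D1"} - {"C1"}:
            raise ValueError("D1 is reachable only from C1")
        if {t.src for t in self.transitions if t.dst == "D2"} - {"C2"}:
            raise ValueError("D2 is reachable only from C2")

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        trans = [Transition(t["from"], t["to"], float(t["rate"]), t["order"])
                 for t in d["transitions"]]
        return cls(d["states"], trans, d.get("name", "custom"))

    @classmethod
    def from_yaml(cls, path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "KineticScheme":
        text = resources.files("synaptomo.data").joinpath(
            "ampar_kinetics.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    # ------------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_index(self) -> int:
        return self.index["O"]

    @property
    def resting_index(self) -> int:
        return self.index["C0"]

    def binding_rate_of(self, state_idx: int) -> float:
        """Glutamate-binding rate (M^-1 s^-1) out of a state, or 0."""
        s = self.states[state_idx]
        for t in self.transitions:
            if t.order == GLU_BINDING and t.src == s:
                return t.rate
        return 0.0

    def binding_destination(self, state_idx: int) -> int:
        s = self.states[state_idx]
        for t in self.transitions:
            if t.order == GLU_BINDING and t.src == s:
                return self.index[t.dst]
        raise ValueError(f"state {s} has no binding transition")

    def unimolecular_rates(self) -> tuple[np.ndarray, list[list[tuple[int, float]]]]:
        """Per-state total unimolecular exit rate (s^-1) and branch lists."""
        total = np.zeros(self.n_states)
        branches: list[list[tuple[int, float]]] = [[] for _ in self.states]
        for t in self.transitions:
            if t.order == UNIMOLECULAR:
                i = self.index[t.src]
                total[i] += t.rate
                branches[i].append((self.index[t.dst], t.rate))
        return total, branches

    def unimolecular_tables(self, dt_s: float):
        """Cached per-dt transition tables for the stochastic stepper.

        Returns ``(p_leave, dsts, cums)``: per-state leave probability
        ``1 - exp(-R dt)``, and per-state destination arrays with
        cumulative branch probabilities.
        """
        cache = getattr(self, "_uni_cache", None)
        if cache is None:
            cache = self._uni_cache = {}
        if dt_s not in cache:
            total, branches = self.unimolecular_rates()
            p_leave = -np.expm1(-total * dt_s)
            dsts, cums = [], []
            for i in range(self.n_states):
                if total[i] > 0:
                    d = np.array([b[0] for b in branches[i]])
                    r = np.array([b[1] for b in branches[i]])
                    c = np.cumsum(r) / total[i]
                    c[-1] = 1.0
                else:
                    d = np.array([i])
                    c = np.array([1.0])
                dsts.append(d)
                cums.append(c)
            cache[dt_s] = (p_leave, dsts, cums)
        return cache[dt_s]

    def generator_matrix(self, glu_conc_M: float) -> np.ndarray:
        """Master-equation generator Q (s^-1) at a fixed concentration.

        ``dp/dt = p @ Q`` for the row-vector of state probabilities.
        Provided for convenience (e.g. steady-state checks); validation
        tests integrate their own ODE from the transition list.
        """
        q = np.zeros((self.n_states, self.n_states))
        for t in self.transitions:
            i, j = self.index[t.src], self.index[t.dst]
            rate = t.rate * glu_conc_M if t.order == GLU_BINDING else t.rate
            q[i, j] += rate
            q[i, i] -= rate
        return q
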