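"""Ionization states of a polyprotic permeant.

A molecule with several titratable sites populates *microstates* (fully
specified site-by-site protonation patterns, i.e. tautomers when the net
charge coincides) grouped into *macrostates* by net charge.  Macrostate
fractions at a given pH follow from the macroscopic acid-dissociation
constants via the sequential Henderson-Hasselbalch relation; resolving the
tautomers inside a macrostate additionally requires microscopic pk values,
which are related to each other through thermodynamic cycles: around any
closed loop of protonation steps the pk values must sum to zero (signed by
direction), which this module validates.

Microstate statistical weights are computed relative to the fully
deprotonated reference: each protonation step multiplies the weight by
10^(pk - pH), so a microstate reached by protonation steps with exponents
pk_1..pk_n has weight 10^(sum pk_i - n*pH).  Path independence is exactly the
cycle-closure condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .profiles import ThermoConditions

__all__ = [
    "Microstate",
    "PkEdge",
    "IonizationModel",
    "MacroscopicPkas",
    "Populations",
    "macrostate_fractions",
    "microstate_log_weight",
    "microstate_weight",
    "microstate_fractions",
    "split_macrostate_by_ratios",
    "validate_cycles",
    "assignment_variants",
]


class IonizationError(ValueError):
    """Invalid ionization model or query."""


@dataclass(frozen=True)
class Microstate:
    """One fully specified protonation pattern.

    ``site_charges`` maps site name to its integer charge in this state;
    ``n_protons`` counts bound titratable protons.
    """

    label: str
    n_protons: int
    site_charges: tuple[tuple[str, int], ...] = ()
    net_charge: int | None = None

    def __post_init__(self) -> None:
        if self.site_charges:
            total = sum(c for _, c in self.site_charges)
            if self.net_charge is None:
                object.__setattr__(self, "net_charge", total)
            elif self.net_charge != total:
                raise IonizationError(
                    f"{self.label}: net_charge {self.net_charge} != sum of "
                    f"site charges {total}"
                )
        elif self.net_charge is None:
            raise IonizationError(f"{self.label}: net_charge or site_charges required")
        if self.n_protons < 0:
            raise IonizationError(f"{self.label}: negative proton count")


@dataclass(frozen=True)
class PkEdge:
    """A single deprotonation step donor -> acceptor with microscopic pk.

    The donor carries exactly one more titratable proton than the acceptor;
    ``pk`` is the negative log of the microscopic acid-dissociation constant.
    """

    donor: str
    acceptor: str
    pk: float


@dataclass
class Populations:
    """Equilibrium fractions at one pH, by net charge and by microstate."""

    by_macrostate: dict[int, float]
    by_microstate: dict[str, float]
    pH: float

    def __post_init__(self) -> None:
        for name, m in (("macrostate", self.by_macrostate),
                        ("microstate", self.by_microstate)):
            if not m:
                continue
            total = sum(m.values())
            if abs(total - 1.0) > 1e-12:
                raise IonizationError(f"{name} fractions sum to {total!r}, not 1")
            if any(f < 0 or f > 1 for f in m.values()):
                raise IonizationError(f"{name} fraction outside [0, 1]")

    def fraction(self, key) -> float:
        """Look up a fraction by microstate label or by integer net charge."""
        if isinstance(key, str) and key in self.by_microstate:
            return self.by_microstate[key]
        return self.by_macrostate[int(key)]


@dataclass(frozen=True)
class MacroscopicPkas:
    """Macroscopic pKa values ordered from the most acidic dissociation.

    ``max_charge`` is the net charge of the fully protonated macrostate; each
    successive dissociation lowers the charge by one.
    """

    values: tuple[float, ...]
    max_charge: int = 0

    def __post_init__(self) -> None:
        if not self.values:
            raise IonizationError("at least one macroscopic pKa is required")
        if not all(np.isfinite(self.values)):
            raise IonizationError("macroscopic pKas must be finite")

    def __len__(self) -> int:
        return len(self.values)


class IonizationModel:
    """Microstates connected by deprotonation edges carrying microscopic pks.

    The deprotonation graph must be connected from the fully deprotonated
    ``reference`` microstate and thermodynamically consistent: every closed
    cycle of edges has a signed pk-sum below ``cycle_tolerance``.
    """

    def __init__(
        self,
        microstates: Iterable[Microstate],
        edges: Iterable[PkEdge],
        reference: str | None = None,
        cycle_tolerance: float = 1e-6,
        validate: bool = True,
    ) -> None:
        self.microstates = {m.label: m for m in microstates}
        self.edges = list(edges)
        self.cycle_tolerance = cycle_tolerance
        for e in self.edges:
            for lbl in (e.donor, e.acceptor):
                if lbl not in self.microstates:
                    raise IonizationError(f"edge references unknown microstate {lbl!r}")
            if (
                self.microstates[e.donor].n_protons
                != self.microstates[e.acceptor].n_protons + 1
            ):
                raise IonizationError(
                    f"edge {e.donor}->{e.acceptor} is not a single deprotonation"
                )
        if reference is None:
            reference = min(
                self.microstates.values(), key=lambda m: m.n_protons
            ).label
        self.reference = reference
        ref_protons = self.microstates[reference].n_protons
        if any(m.n_protons < ref_protons for m in self.microstates.values()):
            raise IonizationError(
                "reference must be the fully deprotonated microstate"
            )
        # undirected view for connectivity/path queries; protonation = acceptor->donor
        g = nx.Graph()
        g.add_nodes_from(self.microstates)
        for e in self.edges:
            g.add_edge(e.donor, e.acceptor, pk=e.pk, donor=e.donor)
        self._graph = g
        if validate:
            unreachable = set(self.microstates) - set(
                nx.node_connected_component(g, reference)
            ) if g.number_of_nodes() else set()
            if unreachable:
                raise IonizationError(
                    f"microstates unreachable from reference: {sorted(unreachable)}"
                )
            bad = [(c, r) for c, r in validate_cycles(self) if abs(r) > cycle_tolerance]
            if bad:
                raise IonizationError(
                    f"thermodynamic cycles violate path independence: {bad}"
                )

    # -- convenience ------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return list(self.microstates)

    def macrostate_of(self, label: str) -> int:
        return int(self.microstates[label].net_charge)

    @classmethod
    def from_dict(cls, spec: Mapping) -> "IonizationModel":
        """Build from a plain mapping (parsed YAML/JSON ionization spec)."""
        micro = [
            Microstate(
                label=m["label"],
                n_protons=int(m["n_protons"]),
                site_charges=tuple((s, int(c)) for s, c in m.get("site_charges", {}).items()),
                net_charge=m.get("net_charge"),
            )
            for m in spec["microstates"]
        ]
        edges = [
            PkEdge(donor=e["donor"], acceptor=e["acceptor"], pk=float(e["pk"]))
            for e in spec["edges"]
        ]
        return cls(
            micro,
            edges,
            reference=spec.get("reference"),
            cycle_tolerance=float(spec.get("cycle_tolerance", 1e-6)),
        )

    @classmethod
    def from_file(cls, path) -> "IonizationModel":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Fractions


def macrostate_fractions(
    pkas: MacroscopicPkas, tc: ThermoConditions
) -> Populations:
    """Macrostate fractions at ``tc.pH`` by sequential Henderson-Hasselbalch.

    For pKas ordered from the most acidic dissociation, the state that has
    lost k protons (relative to the fully protonated one) carries log-weight
    sum_{i<=k} (pH - pKa_i); fractions are the normalized weights.
    """
    pH = tc.pH
    logw = np.concatenate([[0.0], np.cumsum(pH - np.asarray(pkas.values))])
    logw -= logw.max()
    w = 10.0 ** logw
    fr = w / w.sum()
    by_macro = {pkas.max_charge - k: float(fr[k]) for k in range(len(fr))}
    return Populations(by_macrostate=by_macro, by_microstate={}, pH=pH)


def microstate_log_weight(model: IonizationModel, label: str, tc: ThermoConditions) -> float:
    """log10 of the unnormalized weight of ``label`` relative to the reference.

    Any protonation path from the reference gives the same answer once the
    cycle-closure condition holds.
    """
    if label not in model.microstates:
        raise IonizationError(f"unknown microstate {label!r}")
    try:
        path = nx.shortest_path(model._graph, model.reference, label)
    except nx.NetworkXNoPath as exc:
        raise IonizationError(f"{label!r} unreachable from reference") from exc
    log10w = 0.0
    for a, b in zip(path, path[1:]):
        data = model._graph.edges[a, b]
        sign = +1.0 if data["donor"] == b else -1.0  # traversing a->b
        log10w += sign * data["pk"]
    n_extra = model.microstates[label].n_protons - model.microstates[model.reference].n_protons
    return log10w - n_extra * tc.pH


def microstate_weight(model: IonizationModel, label: str, tc: ThermoConditions) -> float:
    """Unnormalized Boltzmann weight 10^(sum pk - n_protons*pH)."""
    return 10.0 ** microstate_log_weight(model, label, tc)


def microstate_fractions(model: IonizationModel, tc: ThermoConditions) -> Populations:
    """Normalized microstate fractions and their macrostate sums at ``tc.pH``."""
    logw = np.array([microstate_log_weight(model, lbl, tc) for lbl in model.labels])
    logw -= logw.max()
    w = 10.0 ** logw
    fr = w / w.sum()
    by_micro = dict(zip(model.labels, map(float, fr)))
    by_macro: dict[int, float] = {}
    for lbl, f in by_micro.items():
        q = model.macrostate_of(lbl)
        by_macro[q] = by_macro.get(q, 0.0) + f
    # renormalize away accumulated rounding so the Populations invariant holds
    s = sum(by_macro.values())
    by_macro = {q: f / s for q, f in by_macro.items()}
    return Populations(by_macrostate=by_macro, by_microstate=by_micro, pH=tc.pH)


def split_macrostate_by_ratios(
    macro: Populations,
    charge: int,
    ratios: Mapping[str, float],
    anchor: str,
) -> Populations:
    """Split one macrostate fraction among tautomers with known ratios.

    ``ratios`` maps tautomer label to its bulk-population ratio to the
    ``anchor`` tautomer (the anchor itself must be present with ratio 1).
    pH-independent tautomer ratios come from microscopic pk differences;
    multiplying them into the macrostate fraction is how experimental
    macroscopic pKas and model-compound microscopic pks combine.
    """
    if anchor not in ratios:
        raise IonizationError(f"ratios must include the anchor {anchor!r}")
    if not np.isclose(ratios[anchor], 1.0):
        raise IonizationError(f"anchor {anchor!r} must have ratio 1")
    if any(r <= 0 for r in ratios.values()):
        raise IonizationError("tautomer ratios must be positive")
    f_macro = macro.by_macrostate[charge]
    total = sum(ratios.values())
    by_micro = dict(macro.by_microstate)
    for lbl, r in ratios.items():
        by_micro[lbl] = f_macro * r / total
    # charged macrostates may legitimately stay lumped, so by_microstate covers
    # only the split macrostate; represent the untouched lumped macrostates as
    # microstates named by their charge so the fractions still sum to one.
    for q, f in macro.by_macrostate.items():
        if q != charge:
            by_micro.setdefault(f"{q:+d}", f)
    return Populations(
        by_macrostate=dict(macro.by_macrostate), by_microstate=by_micro, pH=macro.pH
    )


# ---------------------------------------------------------------------------
# Cycle validation


def validate_cycles(model: IonizationModel) -> list[tuple[list[str], float]]:
    """Signed pk-sum residual around every independent cycle.

    Traversing an edge in the protonation direction counts +pk, in the
    deprotonation direction -pk; thermodynamic consistency (path independence
    of microstate weights) requires each residual to vanish.
    """
    out = []
    for cycle in nx.cycle_basis(model._graph):
        resid = 0.0
        loop = cycle + [cycle[0]]
        for a, b in zip(loop, loop[1:]):
            data = model._graph.edges[a, b]
            resid += data["pk"] if data["donor"] == b else -data["pk"]
        out.append((cycle, resid))
    return out


# ---------------------------------------------------------------------------
# Macroscopic -> microscopic assignment variants


def assignment_variants(
    pkas: MacroscopicPkas,
    scheme: str,
    micro_pks: Mapping[str, float] | None = None,
) -> "IonizationModel":
    """Tetracycline-style 3-site models under different pKa assignments.

    The three zero-net-charge tautomers (zwitterion Z, neutral N, alternative
    zwitterion Z') cannot be resolved by macroscopic pKas alone.  The
    documented variants differ in how the tautomer ratios are obtained:

    - ``leeson``: model-compound microscopic values pk21, pk12, pk13 (with
      pk31 ~ pk21) giving f_N/f_Z = 10^(pk21-pk12), f_Z'/f_Z = 10^(pk21-pk13).
    - ``stephens-like-swap``: as ``leeson`` with the roles of pk12 and pk13
      exchanged (the conflicting literature assignment of the two basic
      groups).
    - ``naive-forward``: treat the macroscopic pKas as per-site microscopic
      ones in order (site A = pKa1, B = pKa2, C = pKa3), so
      f_N/f_Z = 10^(pKa1-pKa2) and f_Z'/f_Z = 10^(pKa1-pKa3).
    - ``naive-reverse``: the same with pKa2 and pKa3 exchanged.

    Returns a cycle-consistent :class:`IonizationModel` whose lumped
    macrostate ladder reproduces ``pkas`` exactly and whose tautomer ratios
    follow the variant.
    """
    if len(pkas) != 3:
        raise IonizationError("assignment variants are defined for 3 macroscopic pKas")
    micro_pks = dict(micro_pks or {"pk21": 5.97, "pk12": 8.8, "pk13": 7.80})
    p21, p12, p13 = micro_pks["pk21"], micro_pks["pk12"], micro_pks["pk13"]
    a1, a2, a3 = pkas.values
    if scheme == "leeson":
        log_rN, log_rZp = p21 - p12, p21 - p13
    elif scheme == "stephens-like-swap":
        log_rN, log_rZp = p21 - p13, p21 - p12
    elif scheme == "naive-forward":
        log_rN, log_rZp = a1 - a2, a1 - a3
    elif scheme == "naive-reverse":
        log_rN, log_rZp = a1 - a3, a1 - a2
    else:
        raise IonizationError(
            f"unknown assignment scheme {scheme!r}; expected leeson | "
            "stephens-like-swap | naive-forward | naive-reverse"
        )
    return build_tautomer_ladder_model(
        pkas, {"Z": 0.0, "N": log_rN, "Z'": log_rZp}, anchor="Z"
    )


def build_tautomer_ladder_model(
    pkas: MacroscopicPkas,
    log_ratios: Mapping[str, float],
    anchor: str = "Z",
    max_charge: int | None = None,
) -> IonizationModel:
    """Assemble a lumped-macrostate model with resolved middle tautomers.

    The charged macrostates are single lumped microstates; the zero-net-charge
    macrostate is split into tautomers whose log10 population ratios to
    ``anchor`` are given.  Edge pks are chosen so that (i) summing tautomer
    fractions reproduces the macroscopic ladder exactly and (ii) the tautomer
    ratios equal the requested values — the same construction used to combine
    titration pKas with model-compound microscopic pks.
    """
    if anchor not in log_ratios or not np.isclose(log_ratios[anchor], 0.0):
        raise IonizationError("log_ratios must include the anchor with value 0")
    if max_charge is None:
        max_charge = pkas.max_charge if pkas.max_charge else 1
    a = list(pkas.values)
    if len(a) != 3:
        raise IonizationError("the ladder builder expects 3 macroscopic pKas")
    log_S = float(np.log10(sum(10.0 ** np.asarray(list(log_ratios.values())))))
    plus, minus, minus2 = "+1", "-1", "-2"
    micro = [
        Microstate(label=plus, n_protons=3, net_charge=max_charge),
        Microstate(label=minus, n_protons=1, net_charge=max_charge - 2),
        Microstate(label=minus2, n_protons=0, net_charge=max_charge - 3),
    ]
    edges = [PkEdge(donor=minus, acceptor=minus2, pk=a[2])]
    # tautomer T: weight(T)/weight(anchor) = 10^log_ratio via its edge to "-1"
    pk_anchor = a[1] - log_S
    for lbl, lr in log_ratios.items():
        micro.append(Microstate(label=lbl, n_protons=2, net_charge=max_charge - 1))
        edges.append(PkEdge(donor=lbl, acceptor=minus, pk=pk_anchor + lr))
        # edge up to the +1 state; closes one cycle per non-anchor tautomer
        edges.append(PkEdge(donor=plus, acceptor=lbl, pk=a[0] + log_S - lr))
    return IonizationModel(micro, edges, reference=minus2, cycle_tolerance=1e-9)
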