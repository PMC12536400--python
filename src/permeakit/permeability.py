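"""Specific and effective membrane permeability.

The inhomogeneous solubility-diffusion (ISD) model expresses the permeability
of a single, fixed ionization state as

    1/P = integral_{z1}^{z2} exp(+beta w(z)) / D(z) dz,

with w(z) the potential of mean force (zeroed in bulk water) and D(z) the
position-dependent diffusivity.  For an ionizable permeant two limiting
protocols combine the state-specific permeabilities into an effective,
pH-dependent one:

- *pH-partitioning* (slow protonation exchange relative to permeation):
  P_eff = sum_s f_s P_s over ionization states s with bulk fractions f_s.
- *BWAP* (fast exchange): the Boltzmann-weighted average potential
  w_m(z) = -kT ln sum_s f_s exp(-beta w_s(z)) and an effective diffusivity
  are fed through the ISD integral once.

States whose profiles were never computed can be carried by a *proxy* (their
specific permeability and PMF approximated by another state's), the standard
treatment when one tautomer dominates transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .ionization import (
    IonizationModel,
    Populations,
    microstate_fractions,
)
from .profiles import (
    ANGSTROM_PER_NS_TO_CM_PER_S,
    Profile1D,
    ProfileError,
    ThermoConditions,
    resample,
)

__all__ = [
    "SpeciesInput",
    "PermeabilityResult",
    "PermeabilityModel",
    "isd_permeability",
    "effective_ph_partitioning",
    "bwap_potential",
    "bwap_effective_diffusivity",
    "effective_bwap",
    "ph_scan",
    "proxy_sensitivity_scan",
]


@dataclass(frozen=True)
class SpeciesInput:
    """One ionization state entering an effective-permeability calculation.

    Provide either both profiles (PMF + diffusivity) or a precomputed
    ``specific_permeability`` in cm/s, or declare the state a proxy of
    another via ``proxy_of`` (its permeability and profiles are then taken
    from the donor state).
    """

    label: str
    pmf: Profile1D | None = None
    diffusivity: Profile1D | None = None
    specific_permeability: float | None = None
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        has_profiles = self.pmf is not None and self.diffusivity is not None
        if not (has_profiles or self.specific_permeability is not None or self.proxy_of):
            raise ValueError(
                f"species {self.label!r} needs (pmf and diffusivity), a "
                "specific_permeability, or a proxy_of declaration"
            )
        if self.specific_permeability is not None and not self.specific_permeability > 0:
            raise ValueError(f"species {self.label!r}: permeability must be positive")

    @property
    def is_proxy(self) -> bool:
        return self.proxy_of is not None


@dataclass
class PermeabilityResult:
    """Effective permeability with per-state breakdown.

    For the pH-partitioning protocol ``contributions`` holds the additive
    terms f_s * P_s (they sum to ``p_eff``); for BWAP it records each state's
    bulk fraction (the mixture weights entering the average potential).
    """

    p_eff: float
    protocol: str
    contributions: dict[str, float]
    p_specific: dict[str, float]
    conditions: ThermoConditions
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.p_eff > 0:
            raise ValueError("effective permeability must be positive")
        if self.protocol == "ph-partitioning":
            total = sum(self.contributions.values())
            if abs(total - self.p_eff) > 1e-12 * max(self.p_eff, total):
                raise ValueError(
                    f"contributions sum to {total!r} but p_eff is {self.p_eff!r}"
                )

    @property
    def dominant_state(self) -> str:
        return max(self.contributions, key=self.contributions.get)

    def summary(self) -> str:
        lines = [
            f"Effective permeability ({self.protocol})",
            f"  pH          : {self.conditions.pH:g}",
            f"  temperature : {self.conditions.temperature:g} K",
            f"  P_eff       : {self.p_eff:.6g} cm/s  (log10 = {np.log10(self.p_eff):.2f})",
            "  state        P_specific (cm/s)   "
            + ("f_s * P_s" if self.protocol == "ph-partitioning" else "bulk fraction"),
        ]
        for lbl in sorted(self.contributions, key=self.contributions.get, reverse=True):
            p = self.p_specific.get(lbl, float("nan"))
            lines.append(f"  {lbl:<12} {p:<18.6g} {self.contributions[lbl]:.6g}")
        for k, v in self.notes.items():
            lines.append(f"  note: {k} = {v}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ISD integral


def _common_grid(pmf: Profile1D, d: Profile1D, bounds=None) -> np.ndarray:
    lo = max(pmf.z[0], d.z[0])
    hi = min(pmf.z[-1], d.z[-1])
    if bounds is not None:
        z1, z2 = sorted(bounds)
        if z1 < lo - 1e-9 or z2 > hi + 1e-9:
            raise ProfileError(
                f"integration bounds ({z1:g}, {z2:g}) outside the profiles' "
                f"common range ({lo:g}, {hi:g})"
            )
        lo, hi = z1, z2
    if hi <= lo:
        raise ProfileError("profiles share no z-range")
    # finer of the two native spacings, with the bounds hit exactly
    h = min(np.diff(pmf.z).min(), np.diff(d.z).min())
    n = max(int(np.ceil((hi - lo) / h)), 2)
    return np.linspace(lo, hi, n + 1)


def isd_permeability(
    pmf: Profile1D,
    d: Profile1D,
    tc: ThermoConditions,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Specific permeability (cm/s) from the ISD integral.

    The resistance integral of exp(+beta w)/D is evaluated by composite
    trapezoid on the common grid (the finer of the two native spacings) in
    log space, so barriers of tens of kcal/mol cannot overflow.
    ``bounds`` restricts the membrane span; default is the full common range.
    """
    if pmf.kind != "pmf" or d.kind != "diffusivity":
        raise ProfileError("isd_permeability expects (pmf, diffusivity) profiles")
    z = _common_grid(pmf, d, bounds)
    w = np.interp(z, pmf.z, pmf.values)
    dv = np.interp(z, d.z, d.values)
    if not (dv > 0).all():
        raise ProfileError("diffusivity must be positive on the integration grid")
    log_integrand = tc.beta * w - np.log(dv)
    # trapezoid weights
    h = np.diff(z)
    wts = np.zeros_like(z)
    wts[:-1] += 0.5 * h
    wts[1:] += 0.5 * h
    log_resistance = logsumexp(log_integrand, b=wts)  # ns/A
    return float(np.exp(-log_resistance) * ANGSTROM_PER_NS_TO_CM_PER_S)


# ---------------------------------------------------------------------------
# Protocols


def _resolve_specific(
    species: Sequence[SpeciesInput],
    tc: ThermoConditions,
    bounds=None,
) -> dict[str, float]:
    """Specific permeability per label, computing ISD and resolving proxies."""
    by_label = {s.label: s for s in species}
    p: dict[str, float] = {}

    def resolve(lbl: str, seen=()) -> float:
        if lbl in p:
            return p[lbl]
        if lbl in seen:
            raise ValueError(f"circular proxy chain at {lbl!r}")
        s = by_label[lbl]
        if s.specific_permeability is not None:
            val = s.specific_permeability
        elif s.pmf is not None and s.diffusivity is not None:
            val = isd_permeability(s.pmf, s.diffusivity, tc, bounds)
        elif s.proxy_of is not None:
            if s.proxy_of not in by_label:
                raise ValueError(
                    f"species {lbl!r} proxies unknown state {s.proxy_of!r}"
                )
            val = resolve(s.proxy_of, (*seen, lbl))
        else:  # pragma: no cover - excluded by SpeciesInput validation
            raise ValueError(f"species {lbl!r} has no permeability source")
        p[lbl] = val
        return val

    for s in species:
        resolve(s.label)
    return p


def _fractions_for(species: Sequence[SpeciesInput], pops: Populations) -> dict[str, float]:
    fr = {}
    for s in species:
        try:
            fr[s.label] = pops.fraction(s.label)
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"populations carry no fraction for species {s.label!r}"
            ) from exc
    missing = [
        lbl for lbl, f in pops.by_microstate.items()
        if lbl not in fr and f > 0
    ]
    if missing:
        raise ValueError(
            f"population states with no species entry (add one or a proxy): {missing}"
        )
    return fr


def effective_ph_partitioning(
    species: Sequence[SpeciesInput],
    pops: Populations,
    tc: ThermoConditions,
    bounds=None,
) -> PermeabilityResult:
    """P_eff = sum_s f_s P_s (slow-exchange limit), with proxy substitution."""
    p_spec = _resolve_specific(species, tc, bounds)
    fr = _fractions_for(species, pops)
    contributions = {lbl: fr[lbl] * p_spec[lbl] for lbl in fr}
    return PermeabilityResult(
        p_eff=float(sum(contributions.values())),
        protocol="ph-partitioning",
        contributions=contributions,
        p_specific=p_spec,
        conditions=tc,
    )


def _profile_species(
    species: Sequence[SpeciesInput], pops: Populations
) -> tuple[list[SpeciesInput], np.ndarray]:
    """Species owning real profiles, with proxy fractions folded onto them."""
    by_label = {s.label: s for s in species}

    def owner(lbl: str) -> str:
        seen = set()
        while by_label[lbl].proxy_of is not None:
            if lbl in seen:
                raise ValueError(f"circular proxy chain at {lbl!r}")
            seen.add(lbl)
            lbl = by_label[lbl].proxy_of
        return lbl

    weights: dict[str, float] = {}
    for s in species:
        host = owner(s.label)
        if by_label[host].pmf is None:
            raise ValueError(
                f"BWAP needs PMFs: state {host!r} (carrying {s.label!r}) has none"
            )
        weights[host] = weights.get(host, 0.0) + pops.fraction(s.label)
    hosts = [by_label[lbl] for lbl in weights]
    if not hosts:
        raise ValueError("no species with PMF profiles")
    return hosts, np.array([weights[s.label] for s in hosts])


def bwap_potential(
    species: Sequence[SpeciesInput],
    pops: Populations,
    tc: ThermoConditions,
) -> Profile1D:
    """Boltzmann-weighted average potential over the contributing states.

    w_m(z) = -kT ln sum_s f_s exp(-beta w_s(z)), evaluated with log-sum-exp;
    proxied states contribute their fraction through the donor's PMF.
    """
    hosts, fr = _profile_species(species, pops)
    grid = hosts[0].pmf.z
    for s in hosts[1:]:
        lo, hi = max(grid[0], s.pmf.z[0]), min(grid[-1], s.pmf.z[-1])
        grid = grid[(grid >= lo) & (grid <= hi)]
    W = np.stack([np.interp(grid, s.pmf.z, s.pmf.values) for s in hosts])
    log_mix = logsumexp(-tc.beta * W, b=fr[:, None] / fr.sum(), axis=0)
    wm = -tc.kT * log_mix
    return Profile1D(z=grid, values=wm, kind="pmf", label="BWAP")


def bwap_effective_diffusivity(
    species: Sequence[SpeciesInput],
    pops: Populations,
    tc: ThermoConditions,
) -> Profile1D:
    """Effective diffusivity for the BWAP protocol.

    D_m(z) = sum_s phi_s(z) D_s(z) where phi_s(z) is the local Boltzmann
    population share f_s exp(-beta w_s(z)) / sum_t f_t exp(-beta w_t(z)).
    The weighting recovers the single-state and local-dominance limits; other
    choices are possible where several states coexist at the same depth.
    """
    hosts, fr = _profile_species(species, pops)
    for s in hosts:
        if s.diffusivity is None:
            raise ValueError(f"state {s.label!r} has no diffusivity profile")
    wm = bwap_potential(species, pops, tc)
    grid = wm.z
    W = np.stack([np.interp(grid, s.pmf.z, s.pmf.values) for s in hosts])
    D = np.stack([np.interp(grid, s.diffusivity.z, s.diffusivity.values) for s in hosts])
    logphi = np.log(fr[:, None] / fr.sum()) - tc.beta * W
    logphi -= logsumexp(logphi, axis=0, keepdims=True)
    dm = np.sum(np.exp(logphi) * D, axis=0)
    return Profile1D(z=grid, values=dm, kind="diffusivity", label="BWAP")


def effective_bwap(
    species: Sequence[SpeciesInput],
    pops: Populations,
    tc: ThermoConditions,
    bounds=None,
) -> PermeabilityResult:
    """P_eff in the fast-exchange limit: ISD integral of (w_m, D_m)."""
    wm = bwap_potential(species, pops, tc)
    dm = bwap_effective_diffusivity(species, pops, tc)
    p_eff = isd_permeability(wm, dm, tc, bounds)
    hosts, fr = _profile_species(species, pops)
    return PermeabilityResult(
        p_eff=p_eff,
        protocol="bwap",
        contributions={s.label: float(f) for s, f in zip(hosts, fr)},
        p_specific=_resolve_specific(species, tc, bounds),
        conditions=tc,
        notes={"effective_diffusivity": "local Boltzmann population weighting"},
    )


# ---------------------------------------------------------------------------
# Scans


def ph_scan(
    species: Sequence[SpeciesInput],
    model: IonizationModel,
    tc_template: ThermoConditions,
    ph_grid: Sequence[float],
    bounds=None,
) -> pd.DataFrame:
    """Effective permeability across a pH grid.

    Populations are recomputed at each pH; the pH-partitioning protocol is
    always evaluated, BWAP only when every contributing state resolves to a
    PMF.  Each row records the dominant contributing state and its share.
    """
    rows = []
    bwap_possible = True
    for ph in np.asarray(ph_grid, dtype=float):
        tc = replace(tc_template, pH=float(ph))
        pops = microstate_fractions(model, tc)
        res = effective_ph_partitioning(species, pops, tc, bounds)
        row = {
            "pH": float(ph),
            "p_eff": res.p_eff,
            "dominant": res.dominant_state,
            "dominant_share": res.contributions[res.dominant_state] / res.p_eff,
        }
        for lbl, c in res.contributions.items():
            row[f"share_{lbl}"] = c / res.p_eff
        if bwap_possible:
            try:
                row["p_eff_bwap"] = effective_bwap(species, pops, tc, bounds).p_eff
            except ValueError:
                bwap_possible = False
        rows.append(row)
    return pd.DataFrame(rows)


def proxy_sensitivity_scan(
    species: Sequence[SpeciesInput],
    pops: Populations,
    tc: ThermoConditions,
    scale_factors: Sequence[float],
    bounds=None,
) -> pd.DataFrame:
    """Sensitivity of P_eff to the proxied states' permeabilities.

    Proxy states stand in for ionization states whose profiles were never
    computed; multiplying their specific permeabilities by each factor (the
    donor state itself is untouched) bounds the error of the proxy treatment.
    Returns (factor, p_eff, relative_change) with the baseline at factor 1.
    """
    base = effective_ph_partitioning(species, pops, tc, bounds)
    p_spec = base.p_specific
    fr = _fractions_for(species, pops)
    proxy_labels = [s.label for s in species if s.is_proxy]
    rows = []
    for factor in scale_factors:
        p_eff = sum(
            fr[lbl] * p_spec[lbl] * (factor if lbl in proxy_labels else 1.0)
            for lbl in fr
        )
        rows.append(
            {
                "factor": float(factor),
                "p_eff": float(p_eff),
                "relative_change": float(p_eff / base.p_eff - 1.0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results front-end


class PermeabilityModel:
    """Effective-permeability calculation bundled as a fittable model.

    Parameters
    ----------
    species
        Ionization states with profiles, direct permeabilities or proxy rules.
    ionization
        Either an :class:`IonizationModel` (populations recomputed from it at
        the requested pH) or precomputed :class:`Populations`.
    conditions
        Temperature and pH.
    bounds
        Optional membrane span (z1, z2) for the ISD integral.

    ``fit(protocol=...)`` evaluates the requested protocol(s) and returns the
    :class:`PermeabilityResult` (or a dict of them for ``"both"``).
    """

    def __init__(
        self,
        species: Sequence[SpeciesInput],
        ionization: IonizationModel | Populations,
        conditions: ThermoConditions,
        bounds: tuple[float, float] | None = None,
    ) -> None:
        self.species = list(species)
        self.ionization = ionization
        self.conditions = conditions
        self.bounds = bounds

    @property
    def populations(self) -> Populations:
        if isinstance(self.ionization, Populations):
            return self.ionization
        return microstate_fractions(self.ionization, self.conditions)

    def fit(self, protocol: str = "ph-partitioning"):
        pops = self.populations
        if protocol == "ph-partitioning":
            return effective_ph_partitioning(
                self.species, pops, self.conditions, self.bounds
            )
        if protocol == "bwap":
            return effective_bwap(self.species, pops, self.conditions, self.bounds)
        if protocol == "both":
            return {
                "ph-partitioning": effective_ph_partitioning(
                    self.species, pops, self.conditions, self.bounds
                ),
                "bwap": effective_bwap(self.species, pops, self.conditions, self.bounds),
            }
        raise ValueError(f"unknown protocol {protocol!r}")
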