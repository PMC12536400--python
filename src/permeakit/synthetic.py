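"""Synthetic ground-truth inputs: profiles, trajectories, ionization models.

Every input the permeability pipeline consumes can be generated here with a
known ground truth:

- W-shaped permeation PMFs (bulk plateaus, mirrored interfacial wells, a
  central barrier) built from Gaussian bumps so derivatives are analytic;
- smooth positive diffusivity profiles with a dip inside the membrane;
- overdamped Langevin (Brownian dynamics) trajectories consistent with a
  given (w, D) pair, using the Ito convention with the explicit dD/dz drift
  term so the stationary density is Boltzmann even for position-dependent D;
- an equilibrium crossing-count permeability estimator, the standard
  independent cross-check of the solubility-diffusion integral;
- random, exactly cycle-consistent ionization models.

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .ionization import IonizationModel, Microstate, PkEdge
from .profiles import (
    ANGSTROM_PER_NS_TO_CM_PER_S,
    Profile1D,
    ThermoConditions,
)

__all__ = [
    "WPmfSpec",
    "LangevinSpec",
    "Trajectory1D",
    "make_w_pmf",
    "make_diffusivity",
    "simulate_langevin",
    "crossing_permeability",
    "CrossingEstimate",
    "make_tautomer_model",
]


@dataclass(frozen=True)
class WPmfSpec:
    """Shape parameters of a synthetic W-shaped permeation PMF.

    ``barrier`` (kcal/mol, >= 0) is the central maximum relative to bulk;
    ``well_depth`` (kcal/mol, <= 0) the depth of the two mirrored interfacial
    wells at ``+-well_position`` (A).  ``interface_width`` sets the Gaussian
    width (std, A) of both features; ``bulk_extent`` the half-width of the
    grid; ``grid_spacing`` its resolution.
    """

    barrier: float = 4.5
    well_depth: float = -4.9
    well_position: float = 14.0
    interface_width: float = 3.0
    bulk_extent: float = 40.0
    grid_spacing: float = 0.2

    def __post_init__(self) -> None:
        if not (self.barrier >= 0 >= self.well_depth):
            raise ValueError("need barrier >= 0 >= well_depth")
        if self.bulk_extent <= self.well_position:
            raise ValueError("bulk_extent must exceed well_position")
        if self.grid_spacing <= 0 or self.interface_width <= 0:
            raise ValueError("grid_spacing and interface_width must be positive")


def make_w_pmf(spec: WPmfSpec, label: str = "") -> Profile1D:
    """Analytic W-shaped PMF: central Gaussian barrier + mirrored wells.

    The three Gaussians overlap slightly, so the barrier and well amplitudes
    are corrected by solving the small 2x2 linear system that makes the
    profile hit exactly ``spec.barrier`` at z = 0 and ``spec.well_depth`` at
    the well positions; the bulk plateau is ~0 by construction.
    """
    s = spec
    n = int(round(2 * s.bulk_extent / s.grid_spacing))
    z = np.linspace(-s.bulk_extent, s.bulk_extent, n + 1)

    def shape(z, a_b, a_w):
        g = np.exp(-0.5 * (np.asarray(z) / s.interface_width) ** 2)
        w = np.exp(-0.5 * ((np.asarray(z) - s.well_position) / s.interface_width) ** 2)
        wm = np.exp(-0.5 * ((np.asarray(z) + s.well_position) / s.interface_width) ** 2)
        return a_b * g + a_w * (w + wm)

    # cross-talk coefficients at the landmarks
    c = np.exp(-0.5 * (s.well_position / s.interface_width) ** 2)
    c2 = np.exp(-0.5 * (2 * s.well_position / s.interface_width) ** 2)
    A = np.array([[1.0, 2.0 * c], [c, 1.0 + c2]])
    a_b, a_w = np.linalg.solve(A, [s.barrier, s.well_depth])
    return Profile1D(z=z, values=shape(z, a_b, a_w), kind="pmf", label=label)


def make_diffusivity(
    bulk_D: float,
    center_D: float,
    width: float,
    grid: Sequence[float],
    label: str = "",
) -> Profile1D:
    """Smooth positive diffusivity interpolating bulk -> center -> bulk.

    A Gaussian dip (or bump) of std ``width`` (A) centred at z = 0 connects
    the bulk level to the membrane-interior level.
    """
    if not (bulk_D > 0 and center_D > 0):
        raise ValueError("diffusivities must be positive")
    z = np.asarray(grid, dtype=float)
    v = bulk_D + (center_D - bulk_D) * np.exp(-0.5 * (z / width) ** 2)
    return Profile1D(z=z, values=v, kind="diffusivity", label=label)


# ---------------------------------------------------------------------------
# Overdamped Langevin simulation


@dataclass
class Trajectory1D:
    """A single-particle 1D trajectory with its generation metadata.

    ``z`` are positions (A) at uniform spacing ``dt`` (ns); ``bias`` is the
    total potential actually applied during generation (may be flat) and
    ``boundaries`` the reflecting limits.
    """

    z: np.ndarray
    dt: float
    bias: Profile1D
    boundaries: tuple[float, float]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        lo, hi = self.boundaries
        if not (self.z >= lo - 1e-9).all() or not (self.z <= hi + 1e-9).all():
            raise ValueError("trajectory leaves the reflecting boundaries")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.z.size) * self.dt

    @property
    def total_time(self) -> float:
        return (self.z.size - 1) * self.dt


@dataclass(frozen=True)
class LangevinSpec:
    """Inputs of one overdamped Langevin run.

    ``potential`` is the *total* potential (PMF plus any applied bias) in
    kcal/mol; ``diffusivity`` in A^2/ns; ``dt`` in ns.  ``seed`` is
    mandatory — reproducibility is part of the contract.
    """

    potential: Profile1D
    diffusivity: Profile1D
    dt: float
    n_steps: int
    seed: int
    boundaries: tuple[float, float] | None = None
    initial_z: float = 0.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.boundaries is None:
            lo = max(self.potential.z[0], self.diffusivity.z[0])
            hi = min(self.potential.z[-1], self.diffusivity.z[-1])
            object.__setattr__(self, "boundaries", (float(lo), float(hi)))
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt must be positive and n_steps >= 1")
        lo, hi = self.boundaries
        if not (lo <= self.initial_z <= hi):
            raise ValueError("initial_z outside boundaries")


@njit(cache=False)
def _interp(x, xp, fp):  # pragma: no cover - numba kernel
    if x <= xp[0]:
        return fp[0]
    if x >= xp[-1]:
        return fp[-1]
    j = np.searchsorted(xp, x) - 1
    t = (x - xp[j]) / (xp[j + 1] - xp[j])
    return fp[j] * (1.0 - t) + fp[j + 1] * t


@njit(cache=False)
def _langevin_kernel(z0, dt, grid, drift, dgrid, dvals, noise, lo, hi):  # pragma: no cover
    n = noise.size
    out = np.empty(n + 1)
    out[0] = z0
    z = z0
    sqrt2dt = np.sqrt(2.0 * dt)
    for i in range(n):
        mu = _interp(z, grid, drift)
        d = _interp(z, dgrid, dvals)
        z = z + mu * dt + sqrt2dt * np.sqrt(d) * noise[i]
        # reflecting walls
        while z < lo or z > hi:
            if z < lo:
                z = 2.0 * lo - z
            else:
                z = 2.0 * hi - z
        out[i + 1] = z
    return out


def simulate_langevin(spec: LangevinSpec, rng: np.random.Generator | None = None) -> Trajectory1D:
    """Overdamped (Brownian) dynamics under a total potential and D(z).

    Ito update  z <- z + [-beta D(z) w'(z) + D'(z)] dt + sqrt(2 D(z) dt) xi,
    with reflecting boundaries.  The D'(z) term makes the stationary density
    exp(-beta w) for position-dependent diffusivity.  A stability check
    refuses dt whose maximum drift step exceeds the potential grid spacing.
    """
    tc = ThermoConditions(temperature=spec.temperature)
    grid = spec.potential.z
    wprime = spec.potential.gradient()
    dz = spec.diffusivity
    d_on_grid = np.interp(grid, dz.z, dz.values)
    dprime = np.gradient(np.interp(grid, dz.z, dz.values), grid)
    drift = -tc.beta * d_on_grid * wprime + dprime
    h = float(np.diff(grid).min())
    max_step = float(np.max(np.abs(drift))) * spec.dt
    if max_step >= h:
        suggested = 0.5 * h / max(np.max(np.abs(drift)), 1e-300)
        raise ValueError(
            f"dt = {spec.dt:g} ns is unstable: max drift step {max_step:.3g} A "
            f"exceeds the grid spacing {h:g} A; try dt <= {suggested:.3g} ns"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.n_steps)
    lo, hi = spec.boundaries
    z = _langevin_kernel(
        float(spec.initial_z),
        float(spec.dt),
        grid,
        drift,
        dz.z,
        dz.values,
        noise,
        float(lo),
        float(hi),
    )
    return Trajectory1D(z=z, dt=spec.dt, bias=spec.potential, boundaries=(lo, hi))


# ---------------------------------------------------------------------------
# Crossing-count permeability


@dataclass(frozen=True)
class CrossingEstimate:
    """Equilibrium flux permeability estimate with bootstrap uncertainty."""

    p: float  # cm/s
    stderr: float  # cm/s
    n_crossings: int
    bulk_concentration: float  # 1/A (time-fraction per unit bulk length)
    upper_bound_only: bool = False


def _count_crossings(z: np.ndarray, z1: float, z2: float) -> int:
    """Complete one-way traversals of [z1, z2] in either direction."""
    side = np.where(z <= z1, -1, np.where(z >= z2, 1, 0))
    side = side[side != 0]
    if side.size == 0:
        return 0
    changes = np.count_nonzero(np.diff(side))
    return int(changes)


def crossing_permeability(
    trajs: Sequence[Trajectory1D],
    membrane: tuple[float, float],
    bulk_regions: Sequence[tuple[float, float]],
    rng: np.random.Generator | None = None,
    n_boot: int = 200,
) -> CrossingEstimate:
    """Permeability from counted membrane traversals at equilibrium.

    For a single particle at equilibrium the one-way crossing rate equals
    P times the bulk linear concentration (time fraction spent in the bulk
    regions divided by their total length); counting traversals in both
    directions and halving gives the one-way rate.  The standard error comes
    from a bootstrap over trajectories.  With zero traversals, an upper
    bound (1 crossing) is returned and flagged.
    """
    z1, z2 = sorted(membrane)
    for lo, hi in bulk_regions:
        if lo < z2 and hi > z1:
            raise ValueError("bulk regions must lie outside the membrane span")
    bulk_len = sum(hi - lo for lo, hi in bulk_regions)

    # per-trajectory sufficient statistics; the bootstrap resamples these
    per_traj = []
    for t in trajs:
        in_bulk = sum(
            int(np.count_nonzero((t.z >= lo) & (t.z <= hi)))
            for lo, hi in bulk_regions
        )
        per_traj.append(
            (_count_crossings(t.z, z1, z2), t.total_time, in_bulk, t.z.size)
        )
    arr = np.array(per_traj, dtype=float)

    def estimate(rows: np.ndarray):
        crossings, total_time, in_bulk, n_frames = rows.sum(axis=0)
        conc = in_bulk / n_frames / bulk_len  # 1/A
        one_way_rate = 0.5 * crossings / total_time  # 1/ns
        return crossings, conc, one_way_rate / conc * ANGSTROM_PER_NS_TO_CM_PER_S

    n_cross, conc, p = estimate(arr)
    n_cross = int(n_cross)
    if n_cross == 0:
        # upper bound from a single hypothetical crossing
        total_time = arr[:, 1].sum()
        p_up = 0.5 / total_time / conc * ANGSTROM_PER_NS_TO_CM_PER_S
        return CrossingEstimate(
            p=p_up, stderr=float("nan"), n_crossings=0,
            bulk_concentration=conc, upper_bound_only=True,
        )
    if rng is None:
        rng = np.random.default_rng(0)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(trajs), size=len(trajs))
        rows = arr[pick]
        if rows[:, 0].sum() == 0:
            continue
        boots.append(estimate(rows)[2])
    stderr = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return CrossingEstimate(
        p=float(p), stderr=stderr, n_crossings=n_cross, bulk_concentration=float(conc)
    )


# ---------------------------------------------------------------------------
# Random ionization models


def make_tautomer_model(
    n_sites: int,
    pk_range: tuple[float, float] = (2.0, 11.0),
    seed: int = 0,
) -> IonizationModel:
    """Random, exactly cycle-consistent ionization model with ``n_sites`` sites.

    Microstates are all 2^n_sites protonation patterns (site protonated = one
    bound proton; a protonated site carries charge +0 and a deprotonated one
    -1, except site 0 which is an amine-like +1/0 pair, mimicking the mix of
    acids and bases in real drugs).  Free energies are assigned by drawing a
    random pk for each site (plus random pairwise couplings), and every edge
    pk is derived from the microstate free energies — so all thermodynamic
    cycles close exactly by construction.
    """
    if not 1 <= n_sites <= 4:
        raise ValueError("n_sites must be between 1 and 4")
    rng = np.random.default_rng(seed)
    site_pk = rng.uniform(*pk_range, size=n_sites)
    coupling = rng.normal(0.0, 0.5, size=(n_sites, n_sites))
    coupling = np.triu(coupling, 1)

    def g(state: tuple[int, ...]) -> float:
        # log10-weight at pH 0 (protons' pH term added separately)
        val = sum(site_pk[i] for i in range(n_sites) if state[i])
        val += sum(
            coupling[i, j]
            for i in range(n_sites)
            for j in range(i + 1, n_sites)
            if state[i] and state[j]
        )
        return val

    def charges(state: tuple[int, ...]) -> tuple[tuple[str, int], ...]:
        out = []
        for i in range(n_sites):
            if i == 0:  # base-like site: +1 protonated, 0 deprotonated
                out.append((f"s{i}", 1 if state[i] else 0))
            else:  # acid-like site: 0 protonated, -1 deprotonated
                out.append((f"s{i}", 0 if state[i] else -1))
        return tuple(out)

    states = [tuple(int(b) for b in np.binary_repr(k, n_sites)) for k in range(2**n_sites)]
    label = lambda st: "".join("H" if b else "-" for b in st)
    micro = [
        Microstate(label=label(st), n_protons=sum(st), site_charges=charges(st))
        for st in states
    ]
    edges = []
    for st in states:
        for i in range(n_sites):
            if st[i]:
                lower = tuple(b if j != i else 0 for j, b in enumerate(st))
                edges.append(
                    PkEdge(donor=label(st), acceptor=label(lower), pk=g(st) - g(lower))
                )
    return IonizationModel(micro, edges, reference=label(states[0]), cycle_tolerance=1e-9)
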