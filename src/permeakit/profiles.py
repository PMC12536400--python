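"""One-dimensional profiles along the membrane normal.

The whole pipeline trades in two kinds of 1D profiles sampled on a z-grid
(angstrom): the potential of mean force w(z) of a permeant's centre of mass
(kcal/mol) and its position-dependent diffusivity D(z) (A^2/ns).  This module
provides the container (:class:`Profile1D`), file I/O, and the standard
transforms applied before a permeability calculation: symmetrization about the
bilayer midplane, uniform free-energy shifts between tautomers, resampling, a
feature report (central barrier, interfacial wells) and a gradient-RMSD
convergence diagnostic for a time series of profiles.

Unit conventions are fixed throughout the package: z in angstrom, free energy
in kcal/mol, diffusivity in A^2/ns, temperature in K.  Permeabilities are
reported in cm/s using 1 A/ns = 10 cm/s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_KCAL",
    "ANGSTROM_PER_NS_TO_CM_PER_S",
    "Profile1D",
    "ThermoConditions",
    "ProfileSeries",
    "FeatureReport",
    "read_profile",
    "write_profile",
    "symmetrize",
    "shift_profile",
    "tautomer_shift_energy",
    "resample",
    "profile_features",
    "gradient_rmsd_convergence",
]

#: Boltzmann constant in kcal/(mol K).
BOLTZMANN_KCAL = 0.0019872041

#: 1 A/ns expressed in cm/s.
ANGSTROM_PER_NS_TO_CM_PER_S = 10.0

_CANONICAL_UNITS = {"pmf": "kcal/mol", "diffusivity": "A^2/ns"}


class ProfileError(ValueError):
    """Malformed or invalid profile input."""


@dataclass(frozen=True)
class ThermoConditions:
    """Thermodynamic state of the calculation.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.  Default 310 K (body temperature, the
        standard condition for membrane permeation assays).
    pH : float
        Bulk-water pH.
    """

    temperature: float = 310.0
    pH: float = 7.0
    boltzmann_constant: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
        return 1.0 / self.kT


@dataclass(frozen=True)
class Profile1D:
    """A scalar quantity sampled on a strictly increasing z-grid.

    ``kind`` is ``"pmf"`` (kcal/mol) or ``"diffusivity"`` (A^2/ns);
    diffusivity profiles must be positive everywhere.
    """

    z: np.ndarray
    values: np.ndarray
    kind: str = "pmf"
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "values", v)
        if self.kind not in ("pmf", "diffusivity"):
            raise ProfileError(f"unknown profile kind {self.kind!r}")
        if z.ndim != 1 or v.ndim != 1 or z.size != v.size:
            raise ProfileError("z and values must be 1D arrays of equal length")
        if z.size < 3:
            raise ProfileError(f"profile needs at least 3 points, got {z.size}")
        if not (np.isfinite(z).all() and np.isfinite(v).all()):
            raise ProfileError("profile contains non-finite entries")
        dz = np.diff(z)
        if not (dz > 0).all():
            bad = int(np.argmin(dz > 0)) + 1
            raise ProfileError(
                f"z-grid not strictly increasing at row {bad} (z={z[bad]:g})"
            )
        if self.kind == "diffusivity" and not (v > 0).all():
            bad = int(np.argmin(v > 0))
            raise ProfileError(
                f"diffusivity must be positive everywhere; value {v[bad]:g} "
                f"at z={z[bad]:g}"
            )
        if not self.units:
            object.__setattr__(self, "units", _CANONICAL_UNITS[self.kind])

    def __len__(self) -> int:
        return self.z.size

    def __call__(self, at: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation at ``at`` (no extrapolation check)."""
        return np.interp(at, self.z, self.values)

    @property
    def spacing(self) -> float:
        """Maximum grid spacing."""
        return float(np.diff(self.z).max())

    def with_values(self, values: np.ndarray, **kw) -> "Profile1D":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def gradient(self) -> np.ndarray:
        """Finite-difference derivative dv/dz on the native grid."""
        return np.gradient(self.values, self.z)

    def plot(self, ax=None, **kw):
        """Plot the profile; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.z, self.values, label=self.label or None, **kw)
        ax.set_xlabel("z (Å)")
        ax.set_ylabel(f"{self.kind} ({self.units})")
        return ax


@dataclass
class ProfileSeries:
    """Ordered snapshots of the same profile at increasing simulation time."""

    snapshots: list[Profile1D]
    time_labels: list[float]

    def __post_init__(self) -> None:
        if len(self.snapshots) < 2:
            raise ProfileError("a profile series needs at least 2 snapshots")
        if len(self.snapshots) != len(self.time_labels):
            raise ProfileError("snapshots and time_labels differ in length")
        kinds = {p.kind for p in self.snapshots}
        if len(kinds) != 1:
            raise ProfileError(f"snapshots mix profile kinds: {sorted(kinds)}")
        ref = self.snapshots[-1].z
        for i, p in enumerate(self.snapshots):
            if p.z.shape != ref.shape or not np.allclose(p.z, ref):
                raise ProfileError(
                    f"snapshot {i} is not on the common grid; resample first"
                )


# ---------------------------------------------------------------------------
# I/O


def read_profile(path, kind: str | None = None) -> Profile1D:
    """Read a two-column whitespace-delimited profile file.

    Lines starting with ``#`` are comments; the optional headers
    ``# kind: pmf|diffusivity``, ``# units: <u>`` and ``# label: <text>``
    are honoured.  ``kind`` passed explicitly overrides the header.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if ":" in body:
                k, _, val = body.partition(":")
                header[k.strip().lower()] = val.strip()
            continue
        parts = s.split()
        if len(parts) < 2:
            raise ProfileError(f"{path}:{lineno}: expected two columns, got {s!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ProfileError(f"{path}:{lineno}: non-numeric entry in {s!r}") from exc
    if not rows:
        raise ProfileError(f"{path}: no data rows")
    z = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    dz = np.diff(z)
    if not (dz > 0).all():
        bad = int(np.argmin(dz > 0)) + 1
        raise ProfileError(
            f"{path}: z-grid not strictly increasing at data row {bad + 1} "
            f"(z={z[bad]:g})"
        )
    kind = kind or header.get("kind", "pmf")
    return Profile1D(
        z=z,
        values=v,
        kind=kind,
        label=header.get("label", path.stem),
        units=header.get("units", ""),
    )


def write_profile(p: Profile1D, path) -> None:
    """Write a profile with headers read_profile understands (full precision)."""
    buf = io.StringIO()
    buf.write(f"# kind: {p.kind}\n# units: {p.units}\n")
    if p.label:
        buf.write(f"# label: {p.label}\n")
    for zi, vi in zip(p.z, p.values):
        buf.write(f"{zi:.17g} {vi:.17g}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Transforms


def _recentre(p: Profile1D) -> Profile1D:
    """Shift the grid so its midpoint sits at z = 0 (bilayer midplane)."""
    mid = 0.5 * (p.z[0] + p.z[-1])
    if abs(mid) < 1e-12:
        return p
    return replace(p, z=p.z - mid)


def _anchor_bulk(p: Profile1D, tail_fraction: float = 0.1) -> Profile1D:
    """Anchor a PMF so the mean over the outermost tails is zero.

    The permeation integral needs a consistent zero in bulk water; the
    outermost ``tail_fraction`` of the grid on each side defines "bulk".
    """
    n = max(1, int(round(tail_fraction * p.z.size)))
    bulk = 0.5 * (p.values[:n].mean() + p.values[-n:].mean())
    return p.with_values(p.values - bulk)


def symmetrize(
    p: Profile1D,
    anchor: bool = True,
    tail_fraction: float = 0.1,
    recentre: bool = True,
) -> tuple[Profile1D, Profile1D]:
    """Average a profile with its mirror image about z = 0.

    Bilayers with identical leaflets give statistically symmetric profiles;
    averaging w(z) with w(-z) removes the residual sampling asymmetry.  The
    returned deviation profile |p - sym| is the conventional error estimate.

    By default the input is recentred so the grid midpoint (the bilayer
    midplane) is z = 0; with ``recentre=False`` a grid covering only one sign
    of z is an error.  PMFs are re-anchored so the bulk tails average to zero
    (``anchor=False`` disables).  Diffusivity profiles are averaged
    arithmetically.
    """
    if recentre:
        p = _recentre(p)
    if p.z[0] >= 0 or p.z[-1] <= 0:
        raise ProfileError("symmetrize needs a grid spanning both signs of z")
    # restrict to the largest reflection-closed interval
    lo, hi = max(p.z[0], -p.z[-1]), min(p.z[-1], -p.z[0])
    mask = (p.z >= lo - 1e-12) & (p.z <= hi + 1e-12)
    z = p.z[mask]
    v = p.values[mask]
    mirror = np.interp(-z, p.z, p.values)
    sym_v = 0.5 * (v + mirror)
    sym = replace(p, z=z, values=sym_v)
    if p.kind == "pmf" and anchor:
        sym = _anchor_bulk(sym, tail_fraction)
    dev = Profile1D(
        z=z,
        values=np.abs(v - 0.5 * (v + mirror)),
        kind=p.kind,
        label=f"{p.label} deviation" if p.label else "deviation",
        units=p.units,
    )
    return sym, dev


def shift_profile(p: Profile1D, dG: float) -> Profile1D:
    """Uniformly shift a PMF by ``dG`` kcal/mol (grid unchanged).

    Used to place tautomer PMFs on a common free-energy scale: a species whose
    bulk fraction is a factor r below the reference tautomer has its PMF raised
    by -kT ln r.
    """
    if p.kind != "pmf":
        raise ProfileError("shift_profile applies to PMFs only")
    return p.with_values(p.values + float(dG))


def tautomer_shift_energy(ratio: float, tc: ThermoConditions) -> float:
    """Free-energy cost -kT ln(ratio) of converting to a minority tautomer.

    ``ratio`` is the bulk population ratio f_minor/f_major (> 0); the returned
    shift in kcal/mol raises the minority species' PMF relative to the major
    one.
    """
    if not ratio > 0:
        raise ValueError(f"population ratio must be positive, got {ratio}")
    return -tc.kT * float(np.log(ratio))


def resample(p: Profile1D, grid: Sequence[float]) -> Profile1D:
    """Linear interpolation onto ``grid``; extrapolation is refused."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < p.z[0] - 1e-12 or grid.max() > p.z[-1] + 1e-12:
        raise ProfileError(
            f"target grid [{grid.min():g}, {grid.max():g}] extends beyond the "
            f"profile range [{p.z[0]:g}, {p.z[-1]:g}]"
        )
    return replace(p, z=grid, values=np.interp(grid, p.z, p.values))


# ---------------------------------------------------------------------------
# Diagnostics


@dataclass(frozen=True)
class FeatureReport:
    """Landmarks of a symmetrized permeation PMF.

    ``barrier`` is the maximum over the central window relative to the bulk
    reference; ``wells`` lists (position, depth) for local minima below bulk.
    """

    barrier: float
    barrier_position: float
    wells: tuple[tuple[float, float], ...]
    bulk_value: float

    @property
    def well_depth(self) -> float | None:
        """Depth of the deepest well (negative), or None if no wells."""
        if not self.wells:
            return None
        return min(d for _, d in self.wells)


def profile_features(
    p: Profile1D,
    barrier_window: float = 5.0,
    tail_fraction: float = 0.1,
    well_tolerance: float = 1e-9,
) -> FeatureReport:
    """Report the central barrier and interfacial wells of a permeation PMF.

    The barrier is measured inside |z| <= ``barrier_window`` (A) relative to
    the bulk plateau (mean of the outermost tails); wells are interior local
    minima more than ``well_tolerance`` below bulk.
    """
    if p.kind != "pmf":
        raise ProfileError("profile_features applies to PMFs")
    v = p.values
    z = p.z
    n = max(1, int(round(tail_fraction * z.size)))
    bulk = 0.5 * (v[:n].mean() + v[-n:].mean())
    win = np.abs(z) <= barrier_window
    if not win.any():
        win = slice(None)
    i = int(np.argmax(np.where(win, v, -np.inf)))
    barrier = float(v[i] - bulk)
    if barrier < 0:
        barrier, i = 0.0, int(np.argmin(np.abs(z)))
    wells = []
    interior = np.arange(1, z.size - 1)
    is_min = (v[interior] <= v[interior - 1]) & (v[interior] <= v[interior + 1])
    below = v[interior] < bulk - well_tolerance
    for j in interior[is_min & below]:
        # skip plateau duplicates
        if wells and np.isclose(wells[-1][1], v[j] - bulk) and z[j] - wells[-1][0] <= 2 * p.spacing:
            continue
        wells.append((float(z[j]), float(v[j] - bulk)))
    return FeatureReport(
        barrier=barrier,
        barrier_position=float(z[i]),
        wells=tuple(wells),
        bulk_value=float(bulk),
    )


def gradient_rmsd_convergence(series: ProfileSeries) -> "pd.DataFrame":
    """RMSD of each snapshot's PMF gradient against the final snapshot's.

    A standard convergence diagnostic for enhanced-sampling free-energy
    calculations: as sampling converges the gradient RMSD decays toward zero
    (the last entry is exactly zero by construction).
    """
    import pandas as pd

    final = series.snapshots[-1].gradient()
    rows = []
    for t, snap in zip(series.time_labels, series.snapshots):
        g = snap.gradient()
        rows.append((t, float(np.sqrt(np.mean((g - final) ** 2)))))
    return pd.DataFrame(rows, columns=["time", "gradient_rmsd"])
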