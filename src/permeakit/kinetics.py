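"""Rate-regime checks for liposomal fluorescence permeability assays.

A pH-sensitive dye trapped in liposomes reports permeation of a weak acid
through the rate k of its fluorescence change, converted to an apparent
permeability by P_app = k d / 6 for vesicles of hydrodynamic diameter d.
The readout is only meaningful if permeation, not protonation chemistry, is
rate-limiting, so the assay rate is compared against order-of-magnitude
estimates of the protonation on-rate k_on = k0 * 10^-pH (treating 10^-pH as
a molar proton concentration, with k0 ~ 1e10 /M/s diffusion-limited) and the
deprotonation off-rate k_off = k0 * 10^-pKa.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RateReport",
    "on_rate",
    "off_rate",
    "intrinsic_rate",
    "papp_from_rate",
    "classify_regime",
]

#: Diffusion-limited protonation rate constant for small molecules (1/M/s).
DEFAULT_K0 = 1e10

#: nm per cm, for converting P_app (cm/s) against a diameter in nm.
NM_PER_CM = 1e7


@dataclass(frozen=True)
class RateReport:
    """Comparison of protonation and permeation rates for one assay."""

    k_on: float
    k_off: float
    k_perm: float
    p_app: float
    diameter: float
    regime: str
    margins: tuple[float, float]  # (k_on/k_perm, k_off/k_perm)

    def summary(self) -> str:
        return "\n".join(
            [
                "Liposomal assay rate check",
                f"  k_on   : {self.k_on:.4g} 1/s",
                f"  k_off  : {self.k_off:.4g} 1/s",
                f"  k_perm : {self.k_perm:.4g} 1/s  (P_app = {self.p_app:.4g} cm/s, "
                f"d = {self.diameter:g} nm)",
                f"  margins: k_on/k = {self.margins[0]:.4g}, "
                f"k_off/k = {self.margins[1]:.4g}",
                f"  regime : {self.regime}",
            ]
        )


def on_rate(pH: float, k0: float = DEFAULT_K0) -> float:
    """Protonation on-rate k0 * 10^-pH in 1/s (order-of-magnitude estimate)."""
    return k0 * 10.0 ** (-pH)


def off_rate(pka: float, k0: float = DEFAULT_K0) -> float:
    """Deprotonation off-rate k0 * 10^-pKa in 1/s."""
    return k0 * 10.0 ** (-pka)


def intrinsic_rate(p_app: float, diameter: float) -> float:
    """Assay rate k = 6 P_app / d (1/s) for P_app in cm/s, d in nm."""
    if not (p_app > 0 and diameter > 0):
        raise ValueError("p_app and diameter must be positive")
    return 6.0 * p_app * NM_PER_CM / diameter


def papp_from_rate(k: float, diameter: float) -> float:
    """Exact inverse of :func:`intrinsic_rate`: P_app = k d / 6 in cm/s."""
    if not (k > 0 and diameter > 0):
        raise ValueError("k and diameter must be positive")
    return k * diameter / (6.0 * NM_PER_CM)


def classify_regime(
    pH: float,
    pka: float,
    p_app: float,
    diameter: float,
    k0: float = DEFAULT_K0,
    threshold: float = 10.0,
) -> RateReport:
    """Decide whether the assay readout reflects permeation dynamics.

    The assay is *permeation-limited* when both protonation rates exceed the
    permeation rate by at least ``threshold`` (default one order of
    magnitude); *protonation-limited* when the permeation rate exceeds both
    by the same margin; *ambiguous* otherwise.
    """
    kon = on_rate(pH, k0)
    koff = off_rate(pka, k0)
    k = intrinsic_rate(p_app, diameter)
    margins = (kon / k, koff / k)
    if min(margins) >= threshold:
        regime = "permeation-limited"
    elif max(margins) <= 1.0 / threshold:
        regime = "protonation-limited"
    else:
        regime = "ambiguous"
    return RateReport(
        k_on=kon,
        k_off=koff,
        k_perm=k,
        p_app=p_app,
        diameter=diameter,
        regime=regime,
        margins=margins,
    )
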