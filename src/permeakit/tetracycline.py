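"""Published tetracycline (TC) constants and ready-made model fixtures.

Tetracycline carries three ionizable groups — the tricarbonyl (A), the
dimethylammonium (B) and the phenolic diketone (C) — giving eight microstates
in four net-charge macrostates (+1, 0, -1, -2).  The zero-net-charge
macrostate splits into three tautomers: the zwitterion TC_Z (A- B+ C0), the
neutral TC_N (A0 B0 C0) and the alternative zwitterion TC_Z' (A0 B+ C-).

Experimental inputs collected here:

- macroscopic pKas 3.33, 7.75, 9.61 (titration);
- microscopic pk values estimated from model compounds, pk21 = 5.97,
  pk12 = 8.8, pk13 = 7.80 with pk31 ~ pk21, which fix the pH-independent
  tautomer ratios f_N/f_Z = 10^(5.97-8.8) = 10^-2.83 and
  f_Z'/f_Z = 10^(5.97-7.8) = 10^-1.83;
- simulation-derived specific permeabilities P_N = 2.22e-2 cm/s and
  P_Z = 1.63e-8 cm/s at 310 K, and the landmark features of the two
  tautomers' W-shaped permeation PMFs (central barriers 4.5 and 13.6
  kcal/mol, interfacial wells -4.9 and -2.1 kcal/mol near |z| = 14 A);
- liposome assay constants: mean vesicle diameter 167.7 nm and measured
  log10 P_app = -5.86.

The microscopic pks come from different model compounds than the titration
pKas and are therefore used only through the tautomer *ratios*; the shipped
graph model stores edge pks rescaled so that the lumped macrostate ladder
reproduces the macroscopic pKas exactly while the tautomer ratios equal the
microscopic differences.
"""

from __future__ import annotations

import numpy as np

from .ionization import (
    IonizationModel,
    MacroscopicPkas,
    build_tautomer_ladder_model,
)

__all__ = [
    "MACRO_PKAS",
    "MICRO_PKS",
    "LOG10_RATIO_N_OVER_Z",
    "LOG10_RATIO_ZP_OVER_Z",
    "P_N",
    "P_Z",
    "TEMPERATURE",
    "BARRIER_N",
    "BARRIER_Z",
    "WELL_N",
    "WELL_Z",
    "WELL_POSITION",
    "LIPOSOME_DIAMETER_NM",
    "LOG10_P_APP",
    "tc_pkas",
    "tc_model",
    "tc_tautomer_ratios",
    "tc_species",
    "tc_like_species",
]

#: Macroscopic pKas (most acidic first); fully protonated macrostate is +1.
MACRO_PKAS = (3.33, 7.75, 9.61)

#: Model-compound microscopic pk estimates.
MICRO_PKS = {"pk21": 5.97, "pk12": 8.8, "pk13": 7.80}

LOG10_RATIO_N_OVER_Z = MICRO_PKS["pk21"] - MICRO_PKS["pk12"]  # -2.83
LOG10_RATIO_ZP_OVER_Z = MICRO_PKS["pk21"] - MICRO_PKS["pk13"]  # -1.83

#: Specific permeabilities of the neutral and zwitterionic tautomers (cm/s).
P_N = 2.22e-2
P_Z = 1.63e-8

#: Simulation temperature (K).
TEMPERATURE = 310.0

#: PMF landmarks (kcal/mol; positions in A).
BARRIER_N = 4.5
BARRIER_Z = 13.6
WELL_N = -4.9
WELL_Z = -2.1
WELL_POSITION = 14.0

#: Liposomal fluorescence assay constants.
LIPOSOME_DIAMETER_NM = 167.7
LOG10_P_APP = -5.86


def tc_pkas() -> MacroscopicPkas:
    """The macroscopic pKa ladder of TC (fully protonated charge +1)."""
    return MacroscopicPkas(values=MACRO_PKAS, max_charge=1)


def tc_tautomer_ratios() -> dict[str, float]:
    """Bulk tautomer-population ratios relative to the zwitterion TC_Z."""
    return {
        "Z": 1.0,
        "N": 10.0 ** LOG10_RATIO_N_OVER_Z,
        "Z'": 10.0 ** LOG10_RATIO_ZP_OVER_Z,
    }


def tc_model() -> IonizationModel:
    """Default TC ionization model (lumped charged macrostates + tautomers)."""
    return build_tautomer_ladder_model(
        tc_pkas(),
        {
            "Z": 0.0,
            "N": LOG10_RATIO_N_OVER_Z,
            "Z'": LOG10_RATIO_ZP_OVER_Z,
        },
        anchor="Z",
    )


def tc_species() -> list:
    """TC species list using the published specific permeabilities directly.

    The neutral and zwitterionic tautomers carry their simulation-derived
    permeabilities; the charged macrostates and TC_Z' are proxied by TC_Z
    (their permeabilities are at most comparable to the zwitterion's).
    """
    from .permeability import SpeciesInput

    return [
        SpeciesInput(label="N", specific_permeability=P_N),
        SpeciesInput(label="Z", specific_permeability=P_Z),
        SpeciesInput(label="Z'", proxy_of="Z"),
        SpeciesInput(label="+1", proxy_of="Z"),
        SpeciesInput(label="-1", proxy_of="Z"),
        SpeciesInput(label="-2", proxy_of="Z"),
    ]


def tc_like_species(grid_spacing: float = 0.2) -> list:
    """Synthetic profile-based TC stand-in calibrated to the published P_N, P_Z.

    Builds W-shaped PMFs with the published landmark features (central
    barriers 4.5 / 13.6 kcal/mol, interfacial wells -4.9 / -2.1 kcal/mol at
    +-14 A) and constant diffusivity profiles whose levels are calibrated by
    1D root-finding so each tautomer's solubility-diffusion permeability
    equals its published value at 310 K.  Proxy states ride on TC_Z as in
    :func:`tc_species`.  The curve shapes between the landmarks are synthetic;
    only the landmarks and the integrated permeabilities are meaningful.
    """
    from scipy.optimize import brentq

    from .permeability import SpeciesInput, isd_permeability
    from .profiles import ThermoConditions
    from .synthetic import WPmfSpec, make_diffusivity, make_w_pmf

    tc = ThermoConditions(temperature=TEMPERATURE)

    def build(label, barrier, well, target_p):
        pmf = make_w_pmf(
            WPmfSpec(
                barrier=barrier,
                well_depth=well,
                well_position=WELL_POSITION,
                grid_spacing=grid_spacing,
            ),
            label=label,
        )

        def mismatch(log10_d):
            d = make_diffusivity(10.0**log10_d, 10.0**log10_d, 5.0, pmf.z)
            return np.log10(isd_permeability(pmf, d, tc)) - np.log10(target_p)

        log10_d = brentq(mismatch, -3.0, 6.0, xtol=1e-12)
        diff = make_diffusivity(10.0**log10_d, 10.0**log10_d, 5.0, pmf.z, label=label)
        return SpeciesInput(label=label, pmf=pmf, diffusivity=diff)

    species = [
        build("N", BARRIER_N, WELL_N, P_N),
        build("Z", BARRIER_Z, WELL_Z, P_Z),
        SpeciesInput(label="Z'", proxy_of="Z"),
        SpeciesInput(label="+1", proxy_of="Z"),
        SpeciesInput(label="-1", proxy_of="Z"),
        SpeciesInput(label="-2", proxy_of="Z"),
    ]
    return species
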