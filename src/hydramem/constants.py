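"""Physical constants, unit conversions and the shared parameter set.

Internal unit system: lengths in nm, energies in kJ/mol, pressures in bar,
temperatures in K, charges in elementary charges.  Diffraction q-vectors use
inverse angstroms, matching the experimental convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, J/K (SI, exact).
K_B_SI = 1.380649e-23
#: Avogadro constant, 1/mol (exact).
N_AVOGADRO = 6.02214076e23
#: Molar gas constant in kJ/(mol K).
R_KJ_PER_MOL_K = K_B_SI * N_AVOGADRO / 1000.0
#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_KJ_NM_E2 = 138.935458

#: 1 kJ mol^-1 nm^-3 expressed in bar.
BAR_PER_KJMOL_NM3 = 1000.0 / N_AVOGADRO / 1e-27 / 1e5
#: 1 bar nm^3 expressed in kJ/mol (inverse of the above).
KJMOL_PER_BAR_NM3 = 1.0 / BAR_PER_KJMOL_NM3


def kt_kjmol(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return R_KJ_PER_MOL_K * temperature


@dataclass(frozen=True)
class Constants:
    """Parameter set shared across the pipeline.

    Attributes
    ----------
    T : float
        Temperature in K.
    v_w0 : float
        Partial molecular volume of bulk water at ambient pressure, nm^3.
    hb_bulk : float
        Hydrogen bonds per water molecule in bulk water; the reference rate
        against which excess water-water bonds are counted.
    r_hb : float
        Donor-acceptor distance cutoff of the geometric hydrogen-bond
        criterion, nm.
    theta_hb : float
        Hydrogen-donor-acceptor angle cutoff, degrees.
    r_lj : float
        Cutoff for Lennard-Jones and (truncated-shifted) Coulomb
        interactions in test-particle insertion, nm.
    """

    T: float = 300.0
    k_B: float = K_B_SI
    v_w0: float = 0.030
    hb_bulk: float = 1.796
    r_hb: float = 0.35
    theta_hb: float = 30.0
    r_lj: float = 0.9

    def __post_init__(self) -> None:
        for name in ("T", "k_B", "v_w0", "hb_bulk", "r_hb", "theta_hb", "r_lj"):
            if not getattr(self, name) > 0:
                raise ValueError(f"Constants.{name} must be positive")

    @property
    def kT(self) -> float:
        """k_B*T in kJ/mol."""
        return kt_kjmol(self.T)


DEFAULT_CONSTANTS = Constants()
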