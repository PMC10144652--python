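"""Physical constants and unit conversions.

The package straddles two unit conventions: quantum-chemistry outputs come
in Hartree atomic units, MD trajectories in nm and elementary charges.
Everything electronic is kept in atomic units internally; coordinates are
kept in nm and converted to bohr only inside Coulomb sums.  Spectra use
wavenumbers (cm^-1) and cgs intensities so that the standard molar
circular-dichroism prefactor applies directly.

CODATA 2018 values throughout.
"""

from __future__ import annotations

# --- lengths ---------------------------------------------------------------
BOHR_NM = 0.052917721090380  # Bohr radius, nm
NM_TO_BOHR = 1.0 / BOHR_NM
ANGSTROM_NM = 0.1

# --- energies / frequencies ------------------------------------------------
HARTREE_EV = 27.211386245988
EV_TO_CM1 = 8065.543937349212  # 1 eV in wavenumbers
HARTREE_CM1 = HARTREE_EV * EV_TO_CM1  # ~219474.63 cm^-1
NM_CM = 1.0e7  # wavelength(nm) = NM_CM / wavenumber(cm^-1)

# --- dipoles, atomic units -> cgs ------------------------------------------
# electric: e*a0 in esu*cm (2.5417 Debye)
EA0_ESU_CM = 2.541746473e-18
# magnetic: e*hbar/(m_e*c) in erg/G (two Bohr magnetons in Gaussian-cgs)
MAG_AU_ERG_G = 1.85480201566e-20
# rotational strength: (e*a0) * (e*hbar/(m_e*c)); the familiar
# 471.44e-40 cgs per atomic unit of R
R_AU_CGS = EA0_ESU_CM * MAG_AU_ERG_G
# dipole strength |mu|^2: (e*a0)^2 in esu^2 cm^2
D_AU_CGS = EA0_ESU_CM**2

# --- molar spectrum prefactors (cgs) ----------------------------------------
# R = CD_PREFACTOR * integral( d_eps / nu ) d_nu  =>  the per-bin band carries
# nu * R / CD_PREFACTOR.  The UV analogue uses the dipole strength D with the
# companion constant 4x larger.
CD_PREFACTOR = 2.296e-39
UV_PREFACTOR = 4.0 * CD_PREFACTOR  # 9.184e-39

# --- thermodynamics ---------------------------------------------------------
KB_KJ_MOL_K = 0.0083145  # Boltzmann constant, kJ/(mol K)


def hartree_to_cm1(e: float) -> float:
    return e * HARTREE_CM1


def cm1_to_nm(nu):
    """Wavenumber (cm^-1) to wavelength (nm)."""
    return NM_CM / nu


def nm_to_cm1(lam):
    """Wavelength (nm) to wavenumber (cm^-1)."""
    return NM_CM / lam
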