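"""Chromophore spectra and Beer–Lambert conversions.

Ships a small compilation of molar extinction coefficients for oxy- and
deoxyhemoglobin (Prahl's tabulation of the Cope / van Assendelft data,
https://omlc.org/spectra/hemoglobin/) and pure-water absorption
(Hale & Querry 1973), sampled at the wavelengths relevant to NIRS.
Values between tabulated wavelengths are obtained by linear interpolation.

Conventions
-----------
* extinction coefficients ``eps`` are base-10 molar extinctions in
  cm^-1 / (mol/L);
* absorption coefficients are in mm^-1;
* hemoglobin concentrations are in micromolar (uM) unless noted.

The conversion from a concentration change to an absorption change is

    d(mu_a) [mm^-1] = ln(10) * eps [cm^-1/M] * dC [M] * 0.1 [cm/mm]

so per micromolar the factor is ``ln(10) * eps * 1e-7`` mm^-1/uM.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "extinction_coefficients",
    "water_absorption",
    "molar_absorption_matrix",
    "concentration_to_absorption",
    "absorption_to_concentration",
]

# wavelength [nm], eps_HbO2, eps_Hb [cm^-1/M] (Prahl compilation)
_HB_TABLE = np.array(
    [
        # lambda   HbO2      Hb
        [650.0, 368.0, 3750.12],
        [690.0, 276.0, 2051.96],
        [700.0, 290.0, 1794.28],
        [750.0, 586.0, 1405.24],
        [800.0, 816.0, 761.72],
        [850.0, 1058.0, 691.32],
        [900.0, 1198.0, 761.84],
        [950.0, 1204.0, 602.24],
    ]
)

# wavelength [nm], mu_a of pure water [cm^-1] (Hale & Querry 1973)
_WATER_TABLE = np.array(
    [
        [650.0, 0.0034],
        [690.0, 0.0051],
        [700.0, 0.0062],
        [750.0, 0.0282],
        [800.0, 0.0206],
        [850.0, 0.0430],
        [900.0, 0.0679],
        [950.0, 0.3878],
    ]
)

LN10 = float(np.log(10.0))


def _interp(table: np.ndarray, wavelength_nm, column: int):
    lam = np.asarray(wavelength_nm, dtype=float)
    lo, hi = table[0, 0], table[-1, 0]
    if np.any(lam < lo) or np.any(lam > hi):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside tabulated range "
            f"[{lo:g}, {hi:g}] nm"
        )
    return np.interp(lam, table[:, 0], table[:, column])


def extinction_coefficients(wavelength_nm):
    """Molar extinction (eps_HbO, eps_HbR) in cm^-1/M at ``wavelength_nm``."""
    return (
        _interp(_HB_TABLE, wavelength_nm, 1),
        _interp(_HB_TABLE, wavelength_nm, 2),
    )


def water_absorption(wavelength_nm):
    """Pure-water absorption coefficient in cm^-1 at ``wavelength_nm``."""
    return _interp(_WATER_TABLE, wavelength_nm, 1)


def molar_absorption_matrix(wavelengths_nm) -> np.ndarray:
    """Matrix kappa mapping (dC_HbO, dC_HbR) in uM to d(mu_a) in mm^-1.

    Returns an (Nw, 2) array with kappa[w, 0] the HbO factor and
    kappa[w, 1] the HbR factor at wavelength ``wavelengths_nm[w]``.
    """
    eps_hbo, eps_hbr = extinction_coefficients(wavelengths_nm)
    kappa = np.stack([np.atleast_1d(eps_hbo), np.atleast_1d(eps_hbr)], axis=-1)
    return LN10 * kappa * 1e-7  # cm^-1/M -> mm^-1/uM


def concentration_to_absorption(c_hbo_um, c_hbr_um, wavelengths_nm) -> np.ndarray:
    """Forward Beer–Lambert: concentration changes (uM) -> d(mu_a) (mm^-1).

    ``c_hbo_um``/``c_hbr_um`` may be scalars or time series; the result has
    shape (Nw,) + shape(c).
    """
    kappa = molar_absorption_matrix(wavelengths_nm)  # (Nw, 2)
    c = np.stack([np.asarray(c_hbo_um, float), np.asarray(c_hbr_um, float)])
    return np.tensordot(kappa, c, axes=(1, 0))


def absorption_to_concentration(dmua_mm, wavelengths_nm) -> tuple[np.ndarray, np.ndarray]:
    """Invert Beer–Lambert at two (or more) wavelengths.

    Parameters
    ----------
    dmua_mm : array (Nw, ...) of absorption changes in mm^-1
    wavelengths_nm : sequence of Nw >= 2 wavelengths

    Returns
    -------
    (dC_HbO, dC_HbR) in uM, least-squares solution if Nw > 2.
    """
    kappa = molar_absorption_matrix(wavelengths_nm)  # (Nw, 2)
    if kappa.shape[0] < 2:
        raise ValueError("need at least two wavelengths to unmix HbO/HbR")
    d = np.asarray(dmua_mm, float)
    flat = d.reshape(d.shape[0], -1)
    cond = np.linalg.cond(kappa)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(
            f"extinction matrix is singular for wavelengths {wavelengths_nm} "
            f"(condition number {cond:.3g})"
        )
    sol, *_ = np.linalg.lstsq(kappa, flat, rcond=None)
    sol = sol.reshape((2,) + d.shape[1:])
    return sol[0], sol[1]
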