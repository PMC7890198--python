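"""Physical constants and unit conversions used across the package.

Internal unit system: lengths in Å, energies in kcal/mol, masses in amu.
A mass-weighted Hessian eigenvalue therefore carries kcal mol⁻¹ Å⁻² amu⁻¹,
and its square root converts to a spectroscopic wavenumber through
``EIGVAL_TO_CM1``.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

#: Boltzmann constant in kcal mol⁻¹ K⁻¹.
KB_KCAL_PER_MOL_K: float = _sc.k * _sc.N_A / _sc.calorie / 1000.0

#: Coulomb prefactor e²/(4πε₀) in kcal mol⁻¹ Å e⁻².
COULOMB_KCAL_A: float = (
    _sc.e**2 / (4.0 * math.pi * _sc.epsilon_0) * _sc.N_A / _sc.calorie / 1000.0 * 1e10
)

# sqrt(kcal mol⁻¹ Å⁻² amu⁻¹) -> angular frequency in rad s⁻¹
_OMEGA_SI = math.sqrt(
    _sc.calorie * 1000.0 / _sc.N_A / (1e-10**2) / _sc.atomic_mass
)

#: Wavenumber (cm⁻¹) of a mode with unit eigenvalue in internal units,
#: ν̃ = sqrt(λ)/(2πc); ≈ 108.59 cm⁻¹ per sqrt(kcal mol⁻¹ Å⁻² amu⁻¹).
EIGVAL_TO_CM1: float = _OMEGA_SI / (2.0 * math.pi * _sc.c * 100.0)
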