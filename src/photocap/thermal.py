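"""Arrhenius temperature normalization of photosynthetic capacity.

Vcmax and Jmax estimated at a leaf temperature ``Tk`` are projected to the
25°C reference with the exponential Arrhenius form

    f(Tk) / k25 = exp(c - dHa / (R * Tk))

where ``c`` is a dimensionless scaling constant chosen so that the ratio is
exactly 1 at 298.15 K, ``dHa`` the activation energy (kJ mol⁻¹) and
``R = 0.008314`` kJ mol⁻¹ K⁻¹ the molar gas constant.  No peaked
(deactivation) term is used: over the cuvette range considered here the
pure Arrhenius form is adequate, and the estimate at 25°C is unchanged by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

GAS_CONSTANT_KJ = 0.008314
"""Molar gas constant, kJ mol⁻¹ K⁻¹."""

T_REF_K = 298.15
"""Reference leaf temperature (25°C), K."""

_TK_MIN, _TK_MAX = 273.0, 323.0


@dataclass(frozen=True)
class ArrheniusParams:
    """Constants of the exponential Arrhenius response for one rate.

    Parameters
    ----------
    c
        Dimensionless scaling constant; ``exp(c - dHa/(R*298.15))`` should be
        1 for a response normalized at 25°C.
    delta_ha
        Activation energy, kJ mol⁻¹ (must be positive).
    """

    c: float
    delta_ha: float

    def __post_init__(self) -> None:
        if self.delta_ha <= 0:
            raise ValueError(f"activation energy must be positive, got {self.delta_ha}")


#: Temperature response of the maximum carboxylation rate Vcmax.
VCMAX_ARRHENIUS = ArrheniusParams(c=26.355, delta_ha=65.33)

#: Temperature response of the maximum electron-transport rate Jmax.
JMAX_ARRHENIUS = ArrheniusParams(c=17.710, delta_ha=43.90)


def arrhenius_factor(tk, params: ArrheniusParams):
    """Ratio f(Tk)/k25 of a rate at leaf temperature ``tk`` to its 25°C value.

    Strictly positive and strictly increasing in ``tk``.  Accepts scalars or
    arrays; temperatures outside [273, 323] K raise ``ValueError``.
    """
    tk_arr = np.asarray(tk, dtype=float)
    if np.any(tk_arr < _TK_MIN) or np.any(tk_arr > _TK_MAX):
        raise ValueError(
            f"leaf temperature must lie in [{_TK_MIN}, {_TK_MAX}] K, got {tk}"
        )
    out = np.exp(params.c - params.delta_ha / (GAS_CONSTANT_KJ * tk_arr))
    return float(out) if np.isscalar(tk) or out.ndim == 0 else out


def normalize_to_25(k_obs, tk, params: ArrheniusParams):
    """Project a rate observed at leaf temperature ``tk`` to 25°C.

    Divides by :func:`arrhenius_factor`; at ``tk = 298.15`` this is the
    identity to within the rounding of the printed constants (≈1e-3
    relative).  ``k_obs`` must be positive.
    """
    k_arr = np.asarray(k_obs, dtype=float)
    if np.any(k_arr <= 0):
        raise ValueError(f"rate must be positive, got {k_obs}")
    out = k_arr / arrhenius_factor(tk, params)
    return float(out) if np.isscalar(k_obs) or out.ndim == 0 else out


def project_from_25(k25, tk, params: ArrheniusParams):
    """Inverse of :func:`normalize_to_25`: value at ``tk`` given the 25°C rate."""
    k_arr = np.asarray(k25, dtype=float)
    if np.any(k_arr <= 0):
        raise ValueError(f"rate must be positive, got {k25}")
    out = k_arr * arrhenius_factor(tk, params)
    return float(out) if np.isscalar(k25) or out.ndim == 0 else out


def reference_consistency(params: ArrheniusParams) -> float:
    """f(298.15)/k25 — equals 1 when ``c`` and ``dHa`` are mutually consistent."""
    return math.exp(params.c - params.delta_ha / (GAS_CONSTANT_KJ * T_REF_K))
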