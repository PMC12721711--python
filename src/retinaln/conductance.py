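"""Excitatory/inhibitory conductance decomposition from voltage clamp.

Currents recorded at the two reversal potentials isolate the opposing
conductance: at the chloride reversal (E_inh, -68.5 mV in the emulated
recordings) the measured current is purely excitatory,
``I = g_exc (E_inh - E_exc)``, and at the cation reversal (E_exc, 0 mV by
the standard assumption) purely inhibitory.  Inverting the two relations
gives the conductance time courses in nS from baseline-subtracted currents
in pA and potentials in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "ConductancePair",
    "decompose_conductances",
    "compose_currents",
    "peak_conductance_ratio",
]

DEFAULT_E_EXC_MV = 0.0
DEFAULT_E_INH_MV = -68.5

#: conductance excursions more negative than this (nS) are counted as sign
#: violations — a diagnostic for wrong reversal-potential settings
SIGN_TOLERANCE_NS = 0.0


@dataclass
class ConductancePair:
    """Excitatory and inhibitory conductance time courses (nS)."""

    g_exc: np.ndarray
    g_inh: np.ndarray
    E_exc_mV: float
    E_inh_mV: float
    dt: float
    n_sign_violations: int = 0

    def __post_init__(self) -> None:
        self.g_exc = np.asarray(self.g_exc, dtype=float)
        self.g_inh = np.asarray(self.g_inh, dtype=float)
        if self.g_exc.size != self.g_inh.size:
            raise ParameterError("conductance traces must have equal length")
        if self.E_exc_mV <= self.E_inh_mV:
            raise ParameterError("E_exc must exceed E_inh")


def decompose_conductances(
    I_at_Einh_pA: np.ndarray,
    I_at_Eexc_pA: np.ndarray,
    E_exc_mV: float = DEFAULT_E_EXC_MV,
    E_inh_mV: float = DEFAULT_E_INH_MV,
    dt: float = 1e-3,
    sign_tolerance_nS: float = SIGN_TOLERANCE_NS,
) -> ConductancePair:
    """Invert two holding-potential current recordings into g_exc/g_inh.

    ``g_exc(t) = I_at_Einh(t) / (E_inh - E_exc)`` and
    ``g_inh(t) = I_at_Eexc(t) / (E_exc - E_inh)``; pA / mV = nS.
    Currents must be baseline-subtracted.  Small negative excursions from
    recording noise are permitted; samples below ``-sign_tolerance_nS`` are
    counted in ``n_sign_violations`` as a wrong-reversal diagnostic.
    """
    i_inh_hold = np.asarray(I_at_Einh_pA, dtype=float)
    i_exc_hold = np.asarray(I_at_Eexc_pA, dtype=float)
    if i_inh_hold.size != i_exc_hold.size:
        raise ParameterError("the two current traces must have equal length")
    if E_exc_mV == E_inh_mV:
        raise ParameterError("reversal potentials must differ")
    if E_exc_mV < E_inh_mV:
        raise ParameterError("E_exc must exceed E_inh")
    dv = E_exc_mV - E_inh_mV
    g_exc = i_inh_hold / (-dv)
    g_inh = i_exc_hold / dv
    n_viol = int(np.sum(g_exc < -sign_tolerance_nS) + np.sum(g_inh < -sign_tolerance_nS))
    return ConductancePair(g_exc, g_inh, E_exc_mV, E_inh_mV, dt, n_viol)


def compose_currents(
    pair: ConductancePair,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model: currents at the two holding potentials from known
    conductances, ``I(V) = g_exc (V - E_exc) + g_inh (V - E_inh)``.

    Returns ``(I_at_Einh, I_at_Eexc)`` in pA — the synthesis inverse of
    :func:`decompose_conductances`.
    """
    i_at_einh = pair.g_exc * (pair.E_inh_mV - pair.E_exc_mV)
    i_at_eexc = pair.g_inh * (pair.E_exc_mV - pair.E_inh_mV)
    return i_at_einh, i_at_eexc


def peak_conductance_ratio(pair: ConductancePair) -> float:
    """Largest excitatory over largest inhibitory conductance (the peaks need
    not be simultaneous)."""
    peak_exc = float(np.max(pair.g_exc))
    peak_inh = float(np.max(pair.g_inh))
    if peak_inh <= 0:
        raise DegenerateInputError("peak inhibitory conductance is zero: ratio undefined")
    return peak_exc / peak_inh
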