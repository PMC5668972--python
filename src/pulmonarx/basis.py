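"""Pressure-dependent elastance basis functions.

Lung elastance during a recruitment manoeuvre is not constant: recruitment
lowers it and distension raises it as airway pressure climbs.  The model
represents elastance as a fixed linear combination of four shapes of airway
pressure P (cmH2O):

    phi_1(P) = 1                                  (constant)
    phi_2(P) = P / 50                             (linear)
    phi_3(P) = exp(-0.04 P)                       (decaying exponential)
    phi_4(P) = 1 / (1 + exp(-0.25 (P - 28)))      (sigmoid, centred 28 cmH2O)

Only the coefficients E_1..E_4 (cmH2O/L) are patient-specific; the shapes
and their constants are frozen.  The combination extrapolates to pressures
outside the identification range by straightforward evaluation - that
extrapolation is what drives peak-pressure prediction at higher PEEP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError

#: number of basis functions in the full nonlinear model
N_BASIS = 4

#: denominator of the linear basis (cmH2O)
LINEAR_SCALE = 50.0
#: decay rate of the exponential basis (1/cmH2O)
EXP_RATE = 0.04
#: slope of the sigmoidal basis (1/cmH2O)
SIGMOID_SLOPE = 0.25
#: centre of the sigmoidal basis (cmH2O)
SIGMOID_CENTRE = 28.0


def eval_basis(pressure):
    """Evaluate the four basis functions at ``pressure``.

    Parameters
    ----------
    pressure : float or array_like
        Airway pressure in cmH2O.  Must be finite.

    Returns
    -------
    numpy.ndarray
        Shape ``(..., 4)``: the values of phi_1..phi_4.
    """
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidInputError("basis functions require finite pressure values")
    out = np.empty(p.shape + (N_BASIS,), dtype=float)
    out[..., 0] = 1.0
    out[..., 1] = p / LINEAR_SCALE
    out[..., 2] = np.exp(-EXP_RATE * p)
    out[..., 3] = expit(SIGMOID_SLOPE * (p - SIGMOID_CENTRE))
    return out


@dataclass
class ElastanceCurve:
    """Elastance as a function of pressure, E(P) = sum_i E_i phi_i(P).

    ``coefficients`` holds E_1..E_4 in cmH2O/L.  Shorter vectors (e.g. a
    single constant term for the first-order model) are zero-padded, so a
    first-order elastance E is represented as ``(E, 0, 0, 0)``.
    """

    coefficients: np.ndarray

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if c.ndim != 1 or c.size > N_BASIS:
            raise InvalidInputError(
                f"elastance curve takes at most {N_BASIS} coefficients"
            )
        if not np.all(np.isfinite(c)):
            raise InvalidInputError("elastance coefficients must be finite")
        if c.size < N_BASIS:
            c = np.pad(c, (0, N_BASIS - c.size))
        self.coefficients = c
        # plain-float copy for the fast scalar path used by root solvers
        self._c = tuple(float(v) for v in c)

    def __call__(self, pressure):
        """Elastance (cmH2O/L) at ``pressure``; vectorises over arrays."""
        if isinstance(pressure, (int, float)):
            return self.scalar(float(pressure))
        return eval_basis(pressure) @ self.coefficients

    def scalar(self, p: float) -> float:
        """Fast scalar evaluation (used in per-sample implicit solves)."""
        c1, c2, c3, c4 = self._c
        return (
            c1
            + c2 * p / LINEAR_SCALE
            + c3 * math.exp(-EXP_RATE * p)
            + c4 / (1.0 + math.exp(-SIGMOID_SLOPE * (p - SIGMOID_CENTRE)))
        )

    @property
    def is_constant(self) -> bool:
        """True when only the constant basis carries weight (first-order model)."""
        return self._c[1] == 0.0 and self._c[2] == 0.0 and self._c[3] == 0.0

    def to_dict(self) -> dict:
        return {f"E{i + 1}": float(v) for i, v in enumerate(self.coefficients)}

    @classmethod
    def from_dict(cls, d: dict) -> "ElastanceCurve":
        return cls(np.array([d[f"E{i + 1}"] for i in range(N_BASIS)], dtype=float))


def elastance(curve: ElastanceCurve, pressure):
    """Functional form of :meth:`ElastanceCurve.__call__`."""
    return curve(pressure)
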