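"""Least-squares identification of lung-mechanics models.

Both the first-order model (FOM)

    P(t) = R Vdot(t) + E V(t) + P0(t)

and the nonlinear autoregressive (NARX) model

    P(t) = sum_{i=1..M} E_i phi_i(P(t)) V(t)
         + sum_{j=0..L} R_j Vdot(t - j) + P0(t)

are linear in their coefficients once the measured pressure is plugged into
the basis functions, so a training window yields a linear system A x = b
with b = P - P0.  The system is solved by SVD pseudoinverse (minimum-norm
least squares): lagged-flow columns are highly collinear and the
minimum-norm behaviour keeps the solution deterministic.

The FOM is the degenerate configuration M = 1 (constant basis only),
L = 0 (a single flow term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .basis import N_BASIS, ElastanceCurve, eval_basis
from .errors import InsufficientDataError, InvalidInputError
from .waveforms import WaveformRecord

#: relative singular-value cutoff for the pseudoinverse
PINV_RCOND = 1e-10

#: relative residual slack used by the "adaptive" truncation rule
ADAPTIVE_SLACK = 0.02

#: default maximum flow lag, in samples at 50 Hz (3.4 s of history)
DEFAULT_N_LAGS = 170


@dataclass(frozen=True)
class NarxConfig:
    """Model structure: number of basis functions and flow lags.

    ``n_lags`` is the maximum lag L; with ``include_lag_zero`` (the
    default) lags run j = 0..L giving L+1 flow terms.  Setting it False
    drops the instantaneous term (lags 1..L), for the alternative reading
    in which L counts the resistive terms.
    """

    n_basis: int = N_BASIS
    n_lags: int = DEFAULT_N_LAGS
    sample_rate: float = 50.0
    include_lag_zero: bool = True

    def __post_init__(self):
        if self.n_basis not in (1, N_BASIS):
            raise InvalidInputError("n_basis must be 1 (FOM) or 4 (NARX)")
        if self.n_lags < 0:
            raise InvalidInputError("n_lags must be non-negative")
        if self.n_flow_terms < 1:
            raise InvalidInputError("model needs at least one flow term")
        if not self.sample_rate > 0:
            raise InvalidInputError("sample_rate must be positive")

    @property
    def n_flow_terms(self) -> int:
        return self.n_lags + 1 if self.include_lag_zero else self.n_lags

    @property
    def n_coefficients(self) -> int:
        return self.n_basis + self.n_flow_terms

    @property
    def lags(self) -> np.ndarray:
        start = 0 if self.include_lag_zero else 1
        return np.arange(start, self.n_lags + 1)

    @classmethod
    def narx(cls, sample_rate: float = 50.0) -> "NarxConfig":
        return cls(n_basis=N_BASIS, n_lags=DEFAULT_N_LAGS, sample_rate=sample_rate)

    @classmethod
    def fom(cls, sample_rate: float = 50.0) -> "NarxConfig":
        return cls(n_basis=1, n_lags=0, sample_rate=sample_rate)


@dataclass
class NarxModel:
    """An identified model: elastance curve plus lagged resistance kernel."""

    config: NarxConfig
    elastance_curve: ElastanceCurve
    resistance: np.ndarray
    training_peeps: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.resistance = np.atleast_1d(np.asarray(self.resistance, dtype=float))
        if self.resistance.size != self.config.n_flow_terms:
            raise InvalidInputError(
                f"expected {self.config.n_flow_terms} resistance terms, "
                f"got {self.resistance.size}"
            )
        if not np.all(np.isfinite(self.resistance)):
            raise InvalidInputError("resistance coefficients must be finite")

    def coefficient_vector(self) -> np.ndarray:
        """Stacked (E_1..E_M, R_j...) vector matching the design matrix."""
        e = self.elastance_curve.coefficients[: self.config.n_basis]
        return np.concatenate([e, self.resistance])

    def resistance_kernel(self) -> np.ndarray:
        """Resistance coefficients indexed by lag 0..L (zero-filled when the
        instantaneous term is excluded)."""
        if self.config.include_lag_zero:
            return self.resistance
        return np.concatenate([[0.0], self.resistance])

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_basis": self.config.n_basis,
                "n_lags": self.config.n_lags,
                "sample_rate": self.config.sample_rate,
                "include_lag_zero": self.config.include_lag_zero,
            },
            "E": [float(v) for v in self.elastance_curve.coefficients],
            "R": [float(v) for v in self.resistance],
            "training_peeps": [float(p) for p in self.training_peeps],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NarxModel":
        cfg = NarxConfig(**d["config"])
        return cls(
            config=cfg,
            elastance_curve=ElastanceCurve(np.asarray(d["E"], dtype=float)),
            resistance=np.asarray(d["R"], dtype=float),
            training_peeps=list(d.get("training_peeps", [])),
        )


@dataclass
class DesignSystem:
    """The linear system for one training window.

    Columns 0..M-1 hold phi_i(P(t)) V(t); the remaining columns hold
    Vdot(t - j) over the configured lags.  ``row_indices`` maps rows back
    to record sample indices (samples whose lag history would cross the
    record start are dropped, not zero-padded).
    """

    A: np.ndarray
    b: np.ndarray
    row_indices: np.ndarray


def build_design_system(
    record: WaveformRecord,
    window,
    p0: np.ndarray,
    config: NarxConfig,
) -> DesignSystem:
    """Assemble A and b = P - P0 for samples in ``window``.

    ``window`` is a ``slice``/``range`` of record sample indices.  Lag
    history may reach before the window start whenever record data exists
    there; rows whose history would cross the record start are dropped.
    """
    if record.volume is None:
        raise InvalidInputError("record needs volume (run integrate_volume first)")
    p0 = np.asarray(p0, dtype=float)
    if p0.size != record.n_samples:
        raise InvalidInputError("p0 must have one value per record sample")
    start = window.start or 0
    stop = record.n_samples if window.stop is None else window.stop
    if not (0 <= start <= stop <= record.n_samples):
        raise InvalidInputError("window outside record")
    t_idx = np.arange(max(start, config.n_lags), stop)
    if t_idx.size == 0:
        raise InsufficientDataError(
            "no usable samples: window empty after lag-history pruning"
        )
    phi = eval_basis(record.pressure[t_idx])[:, : config.n_basis]
    basis_cols = phi * record.volume[t_idx, None]
    if config.n_lags == 0:
        lag_cols = record.flow[t_idx, None]
    else:
        win = np.lib.stride_tricks.sliding_window_view(
            record.flow, config.n_lags + 1
        )
        # row t -> [flow(t), flow(t-1), ..., flow(t-L)]
        lag_cols = win[t_idx - config.n_lags][:, ::-1]
        if not config.include_lag_zero:
            lag_cols = lag_cols[:, 1:]
    A = np.hstack([basis_cols, lag_cols])
    b = record.pressure[t_idx] - p0[t_idx]
    return DesignSystem(A=A, b=b, row_indices=t_idx)


def _as_list(x):
    return x if isinstance(x, (list, tuple)) else [x]


def _adaptive_solve(A: np.ndarray, b: np.ndarray,
                    slack: float = ADAPTIVE_SLACK) -> np.ndarray:
    """Discrepancy-based truncated-SVD least squares.

    Keeps the fewest leading singular directions whose residual norm is
    within ``(1 + slack)`` of the full pseudoinverse solution's.  On clean,
    consistent data every direction contributes to the fit, so nothing is
    truncated and the solution is exact; on noisy data the near-null
    directions (which improve the fit negligibly but carry enormous,
    mutually cancelling coefficients) are dropped.
    """
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    keep = s > s[0] * PINV_RCOND if s.size else s.astype(bool)
    coeffs = np.zeros_like(s)
    proj = u.T @ b
    coeffs[keep] = proj[keep] / s[keep]
    # residual norms for each truncation level, computed incrementally
    total = float(b @ b)
    gains = np.where(keep, proj**2, 0.0)
    resid_sq = np.maximum(total - np.cumsum(gains), 0.0)
    full_resid = np.sqrt(resid_sq[-1]) if s.size else np.sqrt(total)
    target = (1.0 + slack) * full_resid
    k = int(np.argmax(np.sqrt(resid_sq) <= target)) + 1
    x = vt[:k].T @ (coeffs[:k])
    return x


def identify(
    records,
    windows,
    p0,
    config: NarxConfig,
    training_peeps: list[float] | None = None,
    rcond: float | str = PINV_RCOND,
) -> NarxModel:
    """Identify coefficients by minimum-norm least squares.

    ``records``/``windows``/``p0`` may each be a single item or parallel
    lists; the per-window systems are stacked and solved jointly via SVD
    pseudoinverse.  ``rcond`` is the relative singular-value cutoff; the
    default keeps essentially every direction, which is exact on clean
    data.  On noisy recordings the four elastance regressors are nearly
    affinely dependent over a single PEEP step's narrow pressure range, and
    a larger cutoff (see :data:`pulmonarx.prediction.NOISY_DATA_RCOND`)
    suppresses the noise-amplified coefficient directions that otherwise
    ruin extrapolation.
    """
    records = _as_list(records)
    windows = _as_list(windows)
    p0s = _as_list(p0)
    if not (len(records) == len(windows) == len(p0s)):
        raise InvalidInputError("records, windows and p0 must align")
    systems = [
        build_design_system(r, w, p, config)
        for r, w, p in zip(records, windows, p0s)
    ]
    A = np.vstack([s.A for s in systems])
    b = np.concatenate([s.b for s in systems])
    if A.shape[0] < config.n_coefficients:
        warnings.warn(
            f"underdetermined system ({A.shape[0]} rows < "
            f"{config.n_coefficients} coefficients); minimum-norm solution",
            stacklevel=2,
        )
    if not A.any():
        warnings.warn("all-zero design matrix; coefficients set to zero",
                      stacklevel=2)
    if rcond == "adaptive":
        x = _adaptive_solve(A, b)
    else:
        x, *_ = np.linalg.lstsq(A, b, rcond=rcond)
    e = np.zeros(N_BASIS)
    e[: config.n_basis] = x[: config.n_basis]
    return NarxModel(
        config=config,
        elastance_curve=ElastanceCurve(e),
        resistance=x[config.n_basis:],
        training_peeps=list(training_peeps or []),
    )


def fit_residuals(
    model: NarxModel,
    record: WaveformRecord,
    window,
    p0: np.ndarray,
):
    """Residual series P - (A x + P0) over the window's usable rows.

    Returns ``(residuals, rms, row_indices)``.
    """
    system = build_design_system(record, window, p0, model.config)
    residuals = system.b - system.A @ model.coefficient_vector()
    rms = float(np.sqrt(np.mean(residuals**2)))
    return residuals, rms, system.row_indices
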