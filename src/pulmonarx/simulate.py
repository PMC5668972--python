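"""Virtual patients and recruitment-manoeuvre waveform simulation.

Clinical stepped-PEEP recordings are not publicly available, so the
package generates them: a virtual patient is a single-compartment lung
with a known pressure-dependent elastance E(P) and an airway resistance
(scalar, or a short lag kernel emulating viscoelastic behaviour).  The
simulator plays a recruitment manoeuvre through that patient - PEEP rising
in 2 cmH2O steps every ~10 breaths at ~18 breaths/min, sampled at 50 Hz -
in either ventilation mode:

* volume-controlled (VC): square inspiratory flow, passive exponential
  expiration; pressure follows from P = E(P) V + R Vdot + PEEP solved
  implicitly per sample;
* pressure-controlled (PC): square pressure target above PEEP; flow
  follows by integrating Vdot = (P - E(P) V - PEEP) / R.

Ground truth (noiseless per-step PIP and the above/below-40 cmH2O label)
is recorded alongside, so identification, prediction and classification
can be scored without clinical data.

Real ventilator waveforms are never exactly periodic; small per-breath
tidal-volume and timing jitter are simulated by default.  Beyond realism
this matters mathematically: on exactly periodic flow the lagged-flow
regressors span all breath-phase signals and the elastance regressors
become collinear with them within a single PEEP step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

from .basis import ElastanceCurve
from .errors import InvalidInputError, InvalidPatientError
from .prediction import solve_pressure_sample
from .waveforms import BreathSegment, WaveformRecord, write_waveform_csv


@dataclass
class RecruitmentElastance:
    """Sigmoid-plus-quadratic elastance: recruitment then distension.

    E(P) = base + rise / (1 + exp(-slope (P - centre))) + quad (P/50)^2.

    Deliberately outside the span of the four identification basis
    functions, so model-vs-truth comparisons are honest.
    """

    base: float
    rise: float
    centre: float
    slope: float
    quad: float = 0.0

    def __call__(self, pressure):
        p = np.asarray(pressure, dtype=float)
        return (
            self.base
            + self.rise * expit(self.slope * (p - self.centre))
            + self.quad * (p / 50.0) ** 2
        )

    def scalar(self, p: float) -> float:
        return (
            self.base
            + self.rise / (1.0 + math.exp(-self.slope * (p - self.centre)))
            + self.quad * (p / 50.0) ** 2
        )


ElastanceLike = Union[ElastanceCurve, RecruitmentElastance, Callable]


@dataclass
class VirtualPatient:
    """Ground-truth lung mechanics for simulation.

    ``elastance`` is either an :class:`ElastanceCurve` (in-class truth) or
    any monotone pressure->elastance callable (out-of-class truth).
    ``resistance`` is a scalar (cmH2O s/L) or a short lag kernel at the
    protocol sample rate.
    """

    elastance: ElastanceLike
    resistance: Union[float, np.ndarray]
    name: str = ""

    def resistance_kernel(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.resistance, dtype=float))
        if not np.all(np.isfinite(r)):
            raise InvalidPatientError("resistance kernel must be finite")
        return r

    def total_resistance(self) -> float:
        return float(self.resistance_kernel().sum())

    def elastance_at(self, pressure):
        return self.elastance(pressure)


@dataclass
class RmProtocol:
    """Recruitment-manoeuvre ventilation schedule.

    Defaults follow the clinical protocol being emulated: PEEP staircase in
    2 cmH2O steps, ~10 breaths per step, ~18 breaths/min, 50 Hz sampling,
    Gaussian pressure noise of 0.5 cmH2O.  ``tidal_volume`` applies in VC
    mode, ``driving_pressure`` in PC mode.
    """

    peep_start: float = 10.0
    step_size: float = 2.0
    n_steps: int = 7
    breaths_per_step: int = 10
    respiratory_rate: float = 18.0
    mode: str = "VC"
    tidal_volume: float = 0.5
    driving_pressure: float = 14.0
    sample_rate: float = 50.0
    noise_sd: float = 0.5
    #: flow-sensor noise sd on the *recorded* flow (L/s); the lung is
    #: driven by the clean flow
    flow_noise_sd: float = 0.005
    seed: int = 0
    #: per-breath tidal-volume (VC) / driving-pressure (PC) jitter, fractional sd
    amplitude_jitter: float = 0.03
    #: per-breath timing jitter, seconds (uniform +-)
    timing_jitter_s: float = 0.08

    def __post_init__(self):
        if self.step_size <= 0:
            raise InvalidInputError("step_size must be positive")
        if self.n_steps < 2:
            raise InvalidInputError("n_steps must be at least 2")
        if self.breaths_per_step < 1:
            raise InvalidInputError("breaths_per_step must be at least 1")
        if self.sample_rate <= 0 or self.respiratory_rate <= 0:
            raise InvalidInputError("rates must be positive")
        if self.mode not in ("VC", "PC"):
            raise InvalidInputError("mode must be 'VC' or 'PC'")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")

    @property
    def peeps(self) -> np.ndarray:
        return self.peep_start + self.step_size * np.arange(self.n_steps)


@dataclass
class StepTruth:
    peep: float
    true_pip: float
    exceeds_threshold: bool


@dataclass
class SimulatedRm:
    """A simulated manoeuvre: noisy record plus ground truth."""

    record: WaveformRecord
    clean_pressure: np.ndarray
    breaths: list[BreathSegment]
    truth: list[StepTruth]
    patient: VirtualPatient
    protocol: RmProtocol

    def true_pips(self) -> np.ndarray:
        return np.array([t.true_pip for t in self.truth])

    def truth_sidecar(self) -> dict:
        el = self.patient.elastance
        return {
            "seed": self.protocol.seed,
            "mode": self.protocol.mode,
            "peeps": [float(t.peep) for t in self.truth],
            "true_pip": [float(t.true_pip) for t in self.truth],
            "exceeds_threshold": [bool(t.exceeds_threshold) for t in self.truth],
            "resistance": [float(v) for v in self.patient.resistance_kernel()],
            "elastance": (
                el.to_dict()
                if isinstance(el, ElastanceCurve)
                else {
                    k: float(v)
                    for k, v in vars(el).items()
                    if isinstance(v, (int, float))
                }
            ),
        }


def _breath_layout(protocol: RmProtocol, rng: np.random.Generator):
    """Per-breath (n_samples, n_insp, amplitude_scale) with seeded jitter."""
    fs = protocol.sample_rate
    n_nominal = int(round(fs * 60.0 / protocol.respiratory_rate))
    jitter_samples = int(round(protocol.timing_jitter_s * fs))
    total = protocol.n_steps * protocol.breaths_per_step
    layout = []
    for _ in range(total):
        dj = (
            int(rng.integers(-jitter_samples, jitter_samples + 1))
            if jitter_samples > 0
            else 0
        )
        n_b = max(n_nominal + dj, 10)
        n_insp = int(round(n_b / 3))
        scale = 1.0 + protocol.amplitude_jitter * float(rng.standard_normal())
        layout.append((n_b, n_insp, max(scale, 0.2)))
    return layout


def _vc_breath_flow(
    n_b: int, n_insp: int, amp: float, tau: float, dt: float
) -> np.ndarray:
    """One VC breath: samples 0..n_insp at ``amp`` (so volume reaches
    amp * n_insp * dt exactly under trapezoidal integration), then an
    exponential expiratory limb scaled for an exactly zero within-breath
    trapezoidal integral (volume returns to zero every breath)."""
    flow = np.zeros(n_b)
    flow[: n_insp + 1] = amp
    n_exp = n_b - (n_insp + 1)
    if n_exp <= 0:
        return flow
    shape = -np.exp(-np.arange(n_exp) * dt / tau)
    # trapezoid weights inside the breath: 1/2 at the ends, 1 elsewhere
    w = np.ones(n_b)
    w[0] = w[-1] = 0.5
    base = flow.copy()
    expshape = np.zeros(n_b)
    expshape[n_insp + 1:] = shape
    i_base = float(np.dot(w, base))
    i_shape = float(np.dot(w, expshape))
    a = -i_base / i_shape
    flow[n_insp + 1:] = a * shape
    return flow


def _drift_free_volume(flow: np.ndarray, bounds: list[tuple[int, int]], dt: float):
    """Trapezoidal volume re-zeroed at each breath's first/last sample
    (same scheme as waveforms.integrate_volume)."""
    raw = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    vol = np.zeros_like(raw)
    for s, e in bounds:
        seg = raw[s:e] - raw[s]
        vol[s:e] = seg - np.linspace(0.0, seg[-1], e - s)
    return vol


def _check_elastance_positive(patient: VirtualPatient, p_lo: float, p_hi: float):
    grid = np.linspace(p_lo, p_hi, 200)
    if np.any(np.asarray(patient.elastance_at(grid)) <= 0):
        raise InvalidPatientError(
            "elastance must be positive over the simulated pressure range"
        )


def simulate_rm(patient: VirtualPatient, protocol: RmProtocol) -> SimulatedRm:
    """Simulate a full staircase-PEEP recruitment manoeuvre."""
    rng = np.random.default_rng(protocol.seed)
    dt = 1.0 / protocol.sample_rate
    layout = _breath_layout(protocol, rng)
    _check_elastance_positive(patient, 0.0, 150.0)

    bounds = []
    pos = 0
    for n_b, _, _ in layout:
        bounds.append((pos, pos + n_b))
        pos += n_b
    n_total = pos
    peep = np.empty(n_total)
    for k, (s, e) in enumerate(bounds):
        peep[s:e] = protocol.peeps[k // protocol.breaths_per_step]

    if protocol.mode == "VC":
        flow = np.empty(n_total)
        # expiratory time constant R*C, capped so exhalation completes
        # (~e^-8) before the next breath: residual end-expiratory flow
        # would otherwise bias the measurable PEEP baseline by R*Vdot
        n_nominal = int(round(protocol.sample_rate * 60.0 / protocol.respiratory_rate))
        t_exp = (n_nominal - int(round(n_nominal / 3)) - 1) * dt
        tau = float(
            np.clip(
                patient.total_resistance()
                / float(patient.elastance_at(protocol.peep_start)),
                0.12,
                t_exp / 8.0,
            )
        )
        for (s, e), (n_b, n_insp, scale) in zip(bounds, layout):
            vt = protocol.tidal_volume * scale
            amp = vt / (n_insp * dt) if n_insp > 0 else 0.0
            flow[s:e] = _vc_breath_flow(n_b, n_insp, amp, tau, dt)
        volume = _drift_free_volume(flow, bounds, dt)
        kernel = patient.resistance_kernel()
        resistive = np.convolve(flow, kernel)[:n_total]
        clean = np.empty(n_total)
        prev = float(peep[0])
        for t in range(n_total):
            prev = solve_pressure_sample(
                patient.elastance, volume[t], resistive[t] + peep[t], prev
            )
            clean[t] = prev
    else:  # PC
        kernel = patient.resistance_kernel()
        if kernel.size != 1:
            raise InvalidInputError(
                "PC simulation supports scalar resistance only"
            )
        r = float(kernel[0])
        clean = np.empty(n_total)
        rise_n = 3  # short linear pressure ramp at inspiration onset
        for (s, e), ((n_b, n_insp, scale), peep_k) in zip(
            bounds, [(l, peep[b[0]]) for l, b in zip(layout, bounds)]
        ):
            dp = protocol.driving_pressure * scale
            seg = np.full(n_b, peep_k)
            seg[:n_insp] = peep_k + dp
            seg[: min(rise_n, n_insp)] = peep_k + dp * (
                np.arange(1, min(rise_n, n_insp) + 1) / rise_n
            )
            clean[s:e] = seg
        # integrate Vdot = (P - E(P) V - PEEP) / R  (midpoint rule)
        volume = np.zeros(n_total)
        flow = np.zeros(n_total)
        breath_starts = {s for s, _ in bounds}
        v = 0.0
        for t in range(n_total):
            if t in breath_starts:
                v = 0.0  # fresh breath starts from end-expiratory volume
            f1 = (clean[t] - float(patient.elastance_at(clean[t])) * v - peep[t]) / r
            v_mid = v + 0.5 * dt * f1
            f2 = (
                clean[t] - float(patient.elastance_at(clean[t])) * v_mid - peep[t]
            ) / r
            v = v + dt * f2
            volume[t] = v
            flow[t] = f2

    noisy = clean + (
        rng.normal(0.0, protocol.noise_sd, n_total) if protocol.noise_sd > 0 else 0.0
    )
    measured_flow = flow + (
        rng.normal(0.0, protocol.flow_noise_sd, n_total)
        if protocol.flow_noise_sd > 0
        else 0.0
    )
    time = np.arange(n_total) * dt
    record = WaveformRecord(
        time=time,
        pressure=noisy,
        flow=measured_flow,
        volume=None,
        sample_rate=protocol.sample_rate,
    )

    breaths = []
    for (s, e), (_, n_insp, _) in zip(bounds, layout):
        breaths.append(
            BreathSegment(
                start_index=s,
                insp_end_index=min(s + n_insp + 1, e),
                end_index=e,
                peak_pressure=float(np.max(noisy[s:e])),
                baseline_pressure=float(np.median(noisy[max(s, e - 17):e])),
            )
        )
    truth = []
    for k in range(protocol.n_steps):
        bs = bounds[
            k * protocol.breaths_per_step:(k + 1) * protocol.breaths_per_step
        ]
        peaks = [float(np.max(clean[s:e])) for s, e in bs]
        pip = float(np.median(peaks))
        truth.append(
            StepTruth(
                peep=float(protocol.peeps[k]),
                true_pip=pip,
                exceeds_threshold=pip > 40.0,
            )
        )
    return SimulatedRm(
        record=record,
        clean_pressure=clean,
        breaths=breaths,
        truth=truth,
        patient=patient,
        protocol=protocol,
    )


def generate_cohort(
    n_patients: int,
    seed: int = 0,
    protocol_family: RmProtocol | None = None,
    out_of_class: bool = True,
) -> list[SimulatedRm]:
    """Generate a reproducible cohort of simulated manoeuvres.

    Patient parameters are drawn from physiologically plausible ranges
    (baseline elastance 10-22 cmH2O/L rising by 15-45 cmH2O/L through a
    distension sigmoid centred at 32-46 cmH2O; resistance 5-20 cmH2O s/L)
    so that PIP crosses 40 cmH2O in roughly half the datasets.  If one
    outcome class is entirely absent, the last patients are redrawn with
    shifted elastance until both classes appear.
    """
    if n_patients < 1:
        raise InvalidInputError("n_patients must be at least 1")
    rng = np.random.default_rng(seed)
    base_proto = protocol_family or RmProtocol()

    def draw(k: int, shift: float = 0.0) -> SimulatedRm:
        # distension steepness max dE/dP = rise * slope / 4 is drawn
        # directly and kept below ~1.3 (cmH2O/L per cmH2O): with tidal
        # volumes ~0.5 L a steeper E(P) would make the quasi-static
        # pressure balance P = E(P) V + ... lose its root (the
        # pressure-parameterised elastance formulation breaks down)
        rise = float(rng.uniform(15.0, 45.0))
        steepness = float(rng.uniform(0.4, 1.3))
        elast = RecruitmentElastance(
            base=float(rng.uniform(10.0, 22.0)) + shift,
            rise=rise,
            centre=float(rng.uniform(32.0, 46.0)),
            slope=4.0 * steepness / rise,
            quad=float(rng.uniform(0.0, 6.0)),
        )
        if not out_of_class:
            # project onto the identification basis span: constant + linear
            # + sigmoid-like mixture with non-negative weights
            elast = ElastanceCurve(
                np.array(
                    [
                        float(rng.uniform(12.0, 25.0)),
                        float(rng.uniform(0.0, 15.0)),
                        float(rng.uniform(0.0, 8.0)),
                        float(rng.uniform(5.0, 30.0)),
                    ]
                )
            )
        patient = VirtualPatient(
            elastance=elast,
            resistance=float(rng.uniform(5.0, 20.0)),
            name=f"virtual-{k:03d}",
        )
        mode = "PC" if rng.random() < 0.6 else "VC"
        proto = replace(
            base_proto,
            mode=mode,
            peep_start=float(rng.choice([8.0, 10.0, 12.0, 14.0, 16.0])),
            n_steps=int(rng.integers(5, 10)),
            tidal_volume=float(rng.uniform(0.35, 0.55)),
            driving_pressure=float(rng.uniform(10.0, 18.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        return simulate_rm(patient, proto)

    cohort = [draw(k) for k in range(n_patients)]
    if n_patients >= 2:
        labels = [any(t.exceeds_threshold for t in s.truth) for s in cohort]
        attempts = 0
        while len(set(labels)) < 2 and attempts < 20:
            shift = -8.0 if all(labels) else +12.0
            cohort[-1] = draw(n_patients - 1, shift=shift)
            labels[-1] = any(t.exceeds_threshold for t in cohort[-1].truth)
            attempts += 1
    return cohort


def write_dataset(sim: SimulatedRm, csv_path, sidecar_path) -> None:
    """Write the waveform CSV plus a ground-truth JSON sidecar."""
    write_waveform_csv(sim.record, csv_path)
    with open(sidecar_path, "w") as fh:
        json.dump(sim.truth_sidecar(), fh, indent=2)
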