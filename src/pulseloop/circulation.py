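"""Closed-loop lumped-parameter systemic circulation.

Four storage compartments -- left atrium, left ventricle, aorta (arterial),
veins -- exchange blood through four resistive segments; the aortic and
mitral valves are ideal diodes (flow clamped to zero against the
gradient).  The LA is a time-varying-elastance chamber interpolating
between a linear end-systolic and an exponential end-diastolic
pressure-volume relation; the veins are a linear compliance; LV and
aortic pressures come from the finite-element chambers (or any callable
pressure-volume law, e.g. the linear-elastance surrogates used for
verification).

Time marching is explicit: volumes are updated from the previous step's
flows, pressures from the new volumes, flows from the new pressures.
Total blood volume is conserved identically because the flows telescope
around the loop.

Units: Pa, ml, ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

__all__ = [
    "CirculationParams",
    "CirculationState",
    "la_elastance",
    "la_pressure",
    "venous_pressure",
    "segment_flows",
    "advance_circulation",
    "total_volume",
    "ElastanceChamber",
]

MMHG = 133.322  # Pa per mmHg


@dataclass
class CirculationParams:
    """Resistances, compliances and left-atrium elastance constants."""

    R_ao: float = 2000.0        # aortic valve resistance, Pa ms/ml
    R_per: float = 125_000.0    # peripheral resistance, Pa ms/ml
    R_ven: float = 2000.0       # venous resistance, Pa ms/ml
    R_mv: float = 2000.0        # mitral valve resistance, Pa ms/ml
    C_ven: float = 0.3          # venous compliance, ml/Pa
    V_ven0: float = 3200.0      # venous resting volume, ml
    E_es_LA: float = 60.0       # LA end-systolic elastance, Pa/ml
    V0_LA: float = 10.0         # LA volume-axis intercept, ml
    A_LA: float = 58.67         # LA EDPVR scale, Pa
    B_LA: float = 0.049         # LA EDPVR exponent, 1/ml
    t_max: float = 200.0        # time to LA end-systole, ms
    tau: float = 35.0           # LA relaxation time constant, ms
    cycle: float = 800.0        # cardiac cycle length, ms
    # LA activation onset within the ventricular cycle (ms).  The atrial
    # clock e(t) starts here, so peak atrial elastance (at onset + t_max)
    # falls just before the next ventricular activation at t = 0.
    la_onset: float = 560.0

    def __post_init__(self) -> None:
        if min(self.R_ao, self.R_per, self.R_ven, self.R_mv) <= 0:
            raise ValueError("resistances must be positive")
        if self.C_ven <= 0:
            raise ValueError("venous compliance must be positive")
        if not 0 < self.t_max < self.cycle:
            raise ValueError("t_max must lie within the cycle")


@dataclass
class CirculationState:
    """Volumes, pressures and segmental flows at one time point."""

    t: float = 0.0
    V_LA: float = 0.0
    V_LV: float = 0.0
    V_art: float = 0.0
    V_ven: float = 0.0
    P_LA: float = 0.0
    P_LV: float = 0.0
    P_art: float = 0.0
    P_ven: float = 0.0
    q_ven: float = 0.0
    q_mv: float = 0.0
    q_ao: float = 0.0
    q_per: float = 0.0

    def copy(self) -> "CirculationState":
        return replace(self)


def total_volume(state: CirculationState) -> float:
    return state.V_LA + state.V_LV + state.V_art + state.V_ven


def la_elastance(t: float, params: CirculationParams) -> float:
    """Normalized LA driving function e(t) in [0, 1].

    ``t`` is measured from atrial activation onset.  Sinusoidal rise and
    fall to t = 3/2 t_max, exponential relaxation (time constant tau)
    after; the two branches join continuously at e = 1/2.
    """
    tm = params.t_max
    t = float(t)
    if t <= 0.0:
        return 0.0
    if t <= 1.5 * tm:
        return 0.5 * (np.sin(np.pi * t / tm - 0.5 * np.pi) + 1.0)
    return 0.5 * np.exp(-(t - 1.5 * tm) / params.tau)


def la_pressure(V_LA: float, t: float, params: CirculationParams) -> float:
    """LA pressure (Pa): elastance-weighted mix of ESPVR and EDPVR.

    ``t`` is measured from atrial activation onset (use
    ``(t - la_onset) % cycle`` for the ventricular clock)."""
    if V_LA <= 0:
        raise ValueError("LA volume must be positive")
    e = la_elastance(t, params)
    dv = V_LA - params.V0_LA
    p_es = params.E_es_LA * dv
    p_ed = params.A_LA * np.expm1(params.B_LA * dv)
    return e * p_es + (1.0 - e) * p_ed


def venous_pressure(V_ven: float, params: CirculationParams) -> float:
    """Linear venous compliance: (V - V0)/C."""
    return (V_ven - params.V_ven0) / params.C_ven


def segment_flows(P_LA: float, P_LV: float, P_art: float, P_ven: float,
                  params: CirculationParams):
    """Resistive flows (ml/ms); aortic and mitral segments are diodes."""
    q_ao = max(P_LV - P_art, 0.0) / params.R_ao
    q_per = (P_art - P_ven) / params.R_per
    q_ven = (P_ven - P_LA) / params.R_ven
    q_mv = max(P_LA - P_LV, 0.0) / params.R_mv
    return q_ven, q_mv, q_ao, q_per


def advance_circulation(state: CirculationState, dt: float,
                        chamber_pressures, params: CirculationParams
                        ) -> CirculationState:
    """One explicit step: volumes from old flows, then pressures, then
    flows.

    ``chamber_pressures(V_LV, V_art, t)`` must return the LV and aortic
    cavity pressures in Pa (the finite-element pressure-volume relations,
    or surrogates).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = state.t + dt
    V_LA = state.V_LA + dt * (state.q_ven - state.q_mv)
    V_LV = state.V_LV + dt * (state.q_mv - state.q_ao)
    V_art = state.V_art + dt * (state.q_ao - state.q_per)
    V_ven = state.V_ven + dt * (state.q_per - state.q_ven)
    if min(V_LA, V_LV, V_art, V_ven) <= 0.0:
        raise RuntimeError(
            f"negative compartment volume at t={t:.1f} ms: "
            f"LA={V_LA:.1f} LV={V_LV:.1f} art={V_art:.1f} ven={V_ven:.1f}")
    t_la = (t - params.la_onset) % params.cycle
    P_LA = la_pressure(V_LA, t_la, params)
    P_ven = venous_pressure(V_ven, params)
    P_LV, P_art = chamber_pressures(V_LV, V_art, t % params.cycle)
    q_ven, q_mv, q_ao, q_per = segment_flows(P_LA, P_LV, P_art, P_ven, params)
    return CirculationState(
        t=t, V_LA=V_LA, V_LV=V_LV, V_art=V_art, V_ven=V_ven,
        P_LA=P_LA, P_LV=P_LV, P_art=P_art, P_ven=P_ven,
        q_ven=q_ven, q_mv=q_mv, q_ao=q_ao, q_per=q_per,
    )


@dataclass
class ElastanceChamber:
    """Linear time-varying-elastance surrogate for a pressurized chamber.

    P(V, t) = [e(t) E_es + (1 - e(t)) E_ed] (V - V0), with the same
    normalized driving function as the LA (peak at t_peak).  With
    ``E_es == E_ed`` this is a fixed linear compliance (arterial
    surrogate).  Used to verify the circulation loop independently of the
    finite-element chambers.
    """

    E_es: float             # Pa/ml
    E_ed: float             # Pa/ml
    V0: float               # ml
    t_peak: float = 250.0   # ms
    tau: float = 60.0       # ms

    def __call__(self, V: float, t: float) -> float:
        prm = CirculationParams(t_max=self.t_peak, tau=self.tau)
        e = la_elastance(t, prm)
        E = e * self.E_es + (1.0 - e) * self.E_ed
        return E * (V - self.V0)
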