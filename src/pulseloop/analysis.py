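"""Derived hemodynamic metrics and the ex-vivo aortic inflation test.

Metrics follow the conventions of invasive hemodynamics: EDV/ESV are the
extremes of the LV volume trace, systolic/diastolic aortic pressures the
extremes of the aortic pressure trace, mean aortic pressure its time
average over the beat, and the aortic "peak stress" is the maximum over
the beat and over the wall of the Frobenius norm of the Cauchy stress
(square root of the sum of squares of all nine components).

Aortic diameters are inner, area-equivalent: 2 sqrt(A/pi) from the
deformed inner cross-section at a reporting station in the (constant
diameter) ascending segment.  End-diastole is the instant of mitral valve
closure and end-systole the instant of aortic valve closure, both read
from the diode flows.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .circulation import MMHG
from .geometry import AortaGeometry, ChamberMesh, cap_area
from .fe import ChamberProblem, ChamberSolveError, FEState

__all__ = [
    "MetricsRecord",
    "compute_metrics",
    "measure_inner_diameter",
    "frobenius_peak",
    "ex_vivo_inflation",
    "ed_es_indices",
]


@dataclass
class MetricsRecord:
    """Per-case summary of one steady-state beat."""

    case: str
    EF: float                   # percent
    EDV: float                  # ml
    ESV: float                  # ml
    SV: float                   # ml
    P_sys: float                # mmHg
    P_dia: float                # mmHg
    pulse: float                # mmHg
    P_mean: float               # mmHg
    D_ED: float                 # mm
    D_ES: float                 # mm
    peak_stress: float          # kPa
    P_LV_peak: float            # mmHg
    reliable: bool = True

    def as_dict(self) -> dict:
        return {
            "case": self.case,
            "EF_percent": self.EF,
            "EDV_ml": self.EDV,
            "ESV_ml": self.ESV,
            "SV_ml": self.SV,
            "P_sys_mmHg": self.P_sys,
            "P_dia_mmHg": self.P_dia,
            "pulse_mmHg": self.pulse,
            "P_mean_mmHg": self.P_mean,
            "D_ED_mm": self.D_ED,
            "D_ES_mm": self.D_ES,
            "peak_aorta_stress_kPa": self.peak_stress,
            "P_LV_peak_mmHg": self.P_LV_peak,
            "reliable": self.reliable,
        }


def ascending_station(mesh: ChamberMesh) -> int:
    """Fine axial index of the reporting station: middle of the ascending
    (constant-diameter) segment."""
    geom: AortaGeometry = mesh.geom
    n_fine = mesh.index_map.shape[1] - 1
    if geom.arch_radius is None:
        v_station = 0.5
    else:
        v_station = 0.5 * geom.length_asc / geom.length
    return int(round(v_station * n_fine))


def measure_inner_diameter(state: FEState | np.ndarray, mesh: ChamberMesh,
                           station: int | None = None) -> float:
    """Area-equivalent deformed inner diameter (mm) at an axial station
    (fine-grid axial index; default: mid-ascending segment)."""
    u = state.u if isinstance(state, FEState) else np.asarray(state)
    if station is None:
        station = ascending_station(mesh)
    n_fine = mesh.index_map.shape[1] - 1
    if not 0 <= station <= n_fine:
        raise ValueError(f"station {station} outside axial range 0..{n_fine}")
    ring = mesh.index_map[:, station, 0]
    xy = mesh.nodes + u
    segs = np.array(
        [
            (ring[2 * i], ring[(2 * i + 2) % len(ring)], ring[2 * i + 1])
            for i in range(len(ring) // 2)
        ],
        dtype=int,
    )

    class _Ring:
        segments = segs

    A = abs(cap_area(xy, _Ring))
    return 20.0 * np.sqrt(A / np.pi)    # cm -> mm


def frobenius_peak(sigma: np.ndarray) -> float:
    """Peak Frobenius norm of a Cauchy stress field.

    For a quadrature-point field (n_elements, n_qp, 3, 3) the stress is
    first cell-averaged (the piecewise-constant projection, the natural
    resolution of the discretization) and the maximum of the Frobenius
    norm over cells is returned; a plain (..., 3, 3) field is reduced
    pointwise."""
    sigma = np.asarray(sigma)
    if sigma.ndim == 4:
        sigma = sigma.mean(axis=1)
    return float(np.sqrt((sigma**2).sum(axis=(-2, -1))).max())


def ed_es_indices(beat) -> tuple[int, int]:
    """Indices of end-diastole (mitral closure) and end-systole (aortic
    closure) within a beat record; falls back to the LV volume extremes if
    a valve never opened."""
    q_mv = np.asarray(beat.q_mv)
    q_ao = np.asarray(beat.q_ao)
    V = np.asarray(beat.V_LV)
    open_mv = np.nonzero(q_mv > 0)[0]
    open_ao = np.nonzero(q_ao > 0)[0]
    # mitral closure: first step after which q_mv stays 0 until ejection
    if len(open_ao) and len(open_mv):
        before_ej = open_mv[open_mv < open_ao[0]]
        i_ed = before_ej[-1] if len(before_ej) else int(np.argmax(V))
        i_es = open_ao[-1]
    else:
        i_ed = int(np.argmax(V))
        i_es = int(np.argmin(V))
    return int(i_ed), int(i_es)


def compute_metrics(beat, case: str = "baseline") -> MetricsRecord:
    """Summarize one (steady-state) beat record into a MetricsRecord.

    ``beat`` is a CycleTimeSeries: arrays V_LV, P_art, P_LV, q_mv, q_ao,
    D_aorta (mm) and aorta_peak_stress (kPa per step), plus a
    ``converged`` flag.
    """
    V = np.asarray(beat.V_LV)
    P_art = np.asarray(beat.P_art) / MMHG
    EDV, ESV = float(V.max()), float(V.min())
    SV = EDV - ESV
    EF = 100.0 * SV / EDV
    i_ed, i_es = ed_es_indices(beat)
    D = np.asarray(beat.D_aorta)
    rec = MetricsRecord(
        case=case,
        EF=EF,
        EDV=EDV,
        ESV=ESV,
        SV=SV,
        P_sys=float(P_art.max()),
        P_dia=float(P_art.min()),
        pulse=float(P_art.max() - P_art.min()),
        P_mean=float(P_art.mean()),
        D_ED=float(D[i_ed]),
        D_ES=float(D[i_es]),
        peak_stress=float(np.asarray(beat.aorta_peak_stress).max()),
        P_LV_peak=float(np.asarray(beat.P_LV).max() / MMHG),
        reliable=bool(getattr(beat, "converged", True)),
    )
    return rec


def ex_vivo_inflation(
    problem: ChamberProblem,
    pressures_mmHg=None,
    station: int | None = None,
):
    """Static pressure-diameter curve of the isolated aorta.

    Solves the pressure-driven chamber problem over a grid of luminal
    pressures and reports the inner diameter at the reporting station.
    The sweep terminates gracefully at a limit point (solver failure);
    the curve returned covers the pressures reached.

    Returns (pressures_mmHg, diameters_mm) arrays.
    """
    if pressures_mmHg is None:
        pressures_mmHg = np.arange(0.0, 161.0, 5.0)
    pressures_mmHg = np.asarray(pressures_mmHg, dtype=float)
    state = None
    Ps, Ds = [], []
    for p_mm in pressures_mmHg:
        try:
            state = problem.solve(P_target=p_mm * MMHG / 1000.0, state=state)
        except ChamberSolveError:
            break
        Ps.append(p_mm)
        Ds.append(measure_inner_diameter(state, problem.mesh, station))
    return np.asarray(Ps), np.asarray(Ds)
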