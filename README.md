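# pulseloop

Closed-loop ventricular–arterial coupling with finite-element chambers.

`pulseloop` is for cardiovascular-mechanics researchers who want to study
how the left ventricle (LV) and the aorta shape each other's behavior —
how aortic wall thickening or collagen accumulation raises pulse pressure
and ventricular afterload, and how ventricular contractility or passive
stiffness changes propagate into aortic distension and wall stress.
Lumped circulation models cannot separate geometry, microstructure and
material behavior; two full nonlinear finite-element chambers inside a
closed loop can.

## The model

Four compartments (left atrium, LV, aorta, veins) exchange blood through
resistive segments, with ideal-diode mitral and aortic valves:

    dV_LA/dt = q_ven - q_mv        q_mv = max(P_LA - P_LV, 0)/R_mv
    dV_LV/dt = q_mv  - q_ao        q_ao = max(P_LV - P_art, 0)/R_ao
    dV_art/dt = q_ao - q_per       q_per = (P_art - P_ven)/R_per
    dV_ven/dt = q_per - q_ven      q_ven = (P_ven - P_LA)/R_ven

The veins are a linear compliance and the atrium a time-varying-elastance
chamber, `P_LA = e(t) P_es(V) + (1 - e(t)) P_ed(V)`.  The LV and aortic
pressures have no closed form: at every timestep each chamber's
incompressible finite-elasticity problem is solved at the prescribed
cavity volume,

    L(u, p, P_cav, c) = ∫ W(u) dV − ∫ p (J − 1) dV
                        − P_cav (V_cav(u) − V) − c·(C u),

and the cavity-volume multiplier P_cav *is* the chamber pressure
(P_LV = f_LV(V_LV), P_art = f_art(V_art)).  The LV wall is a Fung-type
transversely isotropic material with a length- and time-dependent active
fiber tension (helix angle +60°→−60° across the wall); the aortic wall
is an elastin/collagen/smooth-muscle mixture with four collagen fiber
families at 0°/90°/±45° and an active smooth-muscle tone.  Model
equations, parameters and the calibrated geometry are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the calibrated baseline at the reduced (coarse) problem size from
Python:

```python
from dataclasses import replace
from pulseloop import SimulationConfig, CoupledSimulation, compute_metrics

cfg = replace(SimulationConfig().coarse(), max_beats=8)
sim = CoupledSimulation(cfg, verbose=True)
sim.initialize()
sim.run_to_steady_state()
print(compute_metrics(sim.beats[-1]).as_dict())
```

which prints the per-beat convergence and the steady-state metrics
(abridged):

```
beat 0: EDV 140.2 ESV 64.3 EF 54.1% MAP 93.5 mmHg
beat 1: EDV 141.3 ESV 65.3 EF 53.8% MAP 94.1 mmHg
beat 2: EDV 141.1 ESV 65.7 EF 53.4% MAP 94.9 mmHg
beat 3: EDV 141.1 ESV 65.9 EF 53.3% MAP 95.2 mmHg
{'EF_percent': 53.3, 'EDV_ml': 141.08, 'ESV_ml': 65.89,
 'P_sys_mmHg': 130.32, 'P_dia_mmHg': 80.23, 'pulse_mmHg': 50.09,
 'P_mean_mmHg': 95.21, 'D_ED_mm': 25.77, 'D_ES_mm': 28.0,
 'peak_aorta_stress_kPa': 203.31, ...}
```

Reading: the LV ejects 53% of its 141 ml end-diastolic volume each beat;
aortic pressure swings 80–130 mmHg (pulse 50 mmHg) around a mean of
95 mmHg; the ascending aorta distends from 25.8 mm at end-diastole to
28.0 mm at end-systole; and the peak Frobenius-norm Cauchy stress in the
aortic wall over the beat is ≈ 203 kPa — all in the healthy human range.

The same run from the shell, plus the parameter studies and the ex-vivo
inflation experiment:

    pulseloop run --coarse --case baseline --out-dir out
    pulseloop battery --coarse --cases baseline,T3,C2,M1,M2
    pulseloop inflate --coarse --case M1
    pulseloop material-point --tissue lv --stretch 1.1

Cases: `T1,T2,T3` scale aortic wall thickness up to 3×; `M1`/`M2` shift
the wall composition toward collagen/elastin; `C1,C2` reduce LV
contractility (C2 halves T_max); `P1,P2` raise LV passive stiffness;
`without_active` removes smooth-muscle tone.  Thicker or collagen-rich
aortas raise pulse pressure and lower EF; weaker or stiffer ventricles
lower aortic pressures, diameters and wall stress.

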