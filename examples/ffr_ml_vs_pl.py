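"""Reproduce the headline comparison: FFR of a 75% coronary stenosis with a
porous microcirculation outlet load (ML) versus a constant-pressure outlet
(PL).

Runs two full 3-cycle pulsatile simulations (~5 minutes total on one CPU)
and prints a Table-style summary.  The microcirculation load raises FFR and
widens the pressure fluctuation ranges.
"""

import pandas as pd

from stenoflow import (CarreauParams, FluidParams, PorousParams,
                       SimulationConfig, StenosisGeometry, build_waveform,
                       make_report, run_simulation)

rows = []
for mode in ("ML", "PL"):
    geom = StenosisGeometry(L_porous=0.2e-3 if mode == "ML" else 0.0)
    cfg = SimulationConfig(outlet_mode=mode)
    porous = PorousParams() if mode == "ML" else None
    print(f"running {mode} (3 cycles, {cfg.steps_per_cycle} steps/cycle)...")
    history = run_simulation(geom, CarreauParams(), FluidParams(), porous,
                             build_waveform(), cfg)
    rep = make_report(history)
    rows.append(rep.to_frame())
    print(f"  {mode}: mean Pa = {rep.p_a_avg:.0f} Pa, mean Pd = "
          f"{rep.p_d_avg:.0f} Pa, FFR = {rep.ffr:.3f}")

print()
print(pd.concat(rows, ignore_index=True).to_string(index=False))
print("\nFFR = cycle-mean distal / proximal pressure (venous pressure 0)."
      "\nThe ML row should show the higher FFR and the wider fluctuation"
      "\nranges: the porous bed's Darcy impedance raises the whole pressure"
      "\nlevel and passes the inlet pulsatility into the pressure field.")
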