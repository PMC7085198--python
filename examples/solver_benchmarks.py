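"""Run the analytic solver benchmarks: Carreau limits, Hagen-Poiseuille tube
flow and the porous-slug seepage gradient.  Takes ~10 s."""

from stenoflow.validate import run_all

for result in run_all():
    print(result)
print("\nEach line compares the finite-volume solution against a closed-form"
      "\noracle; relative errors should sit well inside the stated tolerance.")
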