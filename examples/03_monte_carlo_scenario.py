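"""Monte Carlo angular-error study (a desk-scale Simulation I).

Runs the x-fiber cell of the standard single-fiber scenario — b=3000 s/mm2,
60 directions, Rician noise at SNR 30, coil deviation diag(-13%,-14%,-5%) —
with 1000 shared-noise replicates and prints median angular deviations per
method and condition.  Increase ``reps`` to 10_000 for the full design.
"""

from gnlsd import run_scenario, scenario, summarize

config = scenario("I", reps=1000, seed=42)
result = run_scenario(config, cells=["fiber-x"])
table = summarize(result)
print(table.to_string(index=False))

print("\nno_dev rows are the noise-only floor; the deviation raises the")
print("uniform fits above it while the corrected variants move back toward")
print("the floor.  Medians carry Monte Carlo error of a few hundredths of a")
print("degree at this replicate count.")
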