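"""Run the entire four-prediction analysis from one config and print the report.

Equivalent to the CLI ``reefcontests run --scenario field``; everything
is derived from the single master seed and recorded in the machine report.
"""

from reefcontests import pipeline

config = pipeline.RunConfig(
    scenario="field",
    seed=1,
    n_permutations=10_000,
    n_bootstrap=1000,
    mslr_n_sim=2000,
)
report = pipeline.run_all(config)
print(pipeline.render_report_text(report))
print("Each block mirrors one prediction: proximity rank tests, bootstrap")
print("signalling contrasts, chase-CV equality, and the comparative models.")
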