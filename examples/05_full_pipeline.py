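"""The whole workflow in one call: cohort in, statistics report out.

Equivalent to the CLI's `thetanet all`; here driven from Python with a
small cohort so it finishes in under a minute.
"""

from thetanet.pipeline import PipelineConfig, render_report, run_analysis
from thetanet.simulate import SimulationConfig, generate_cohort

cohort = generate_cohort(
    SimulationConfig(n_per_group=5, n_channels=16, rest_duration=20.0,
                     n_trials=20, seed=9)
)
bundle = run_analysis(cohort, PipelineConfig(mvar_order=2))

t = bundle.subject_table
print(t[["subject", "analysis_group", "mean_rt_ms", "acc", "z_rt",
         "prominent_band", "dtf_g", "dtf_out", "dtf_in"]]
      .round(4).to_string(index=False))

print("\ngroup means of the connectivity aggregates:")
print(t.groupby("analysis_group")[["dtf_g", "dtf_out", "dtf_in"]]
      .mean().round(4).to_string())

key = bundle.statistics_frame()
key = key[(key["test"] == "one-way ANOVA")
          & key["measure"].isin(["dtf_g", "dtf_out", "dtf_in"])]
print("\nomnibus ANOVAs over the three analysis groups:")
print(key[["measure", "statistic", "df", "p_value"]].round(4)
      .to_string(index=False))
# report = render_report(bundle)  # full markdown report, ready to save
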