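"""Normality-routed group comparisons on synthetic kinetics.

Generates fluorescence-like kinetics for the four conditions (plateaus
encode the 20-fold thrombin/fibrin synergy), pools donors x repetitions
per condition at 450 s, and compares the combined long/high condition
against each other condition with Jarque-Bera routing (t test vs
rank-sum) and Bonferroni adjustment.
"""

from clotflow import SampleSet, compare_conditions, generate_kinetics

df = generate_kinetics(seed=2)
at450 = df[(df["time_s"] == 450.0) & (df["analyte"] == "thrombin")]
samples = {c: SampleSet(c, g["value"].to_numpy())
           for c, g in at450.groupby("condition")}
for name, s in samples.items():
    print(f"{name:11s} n={s.n:2d} mean={s.values.mean():8.3f} a.u.")

report = compare_conditions(samples, reference="long_high")
print("\nlong_high vs ...   test      raw p      adjusted p  significant")
for cond, r in report.items():
    print(f"  {cond:11s}   {r['test_used']:7s} {r['p_raw']:10.2e} "
          f"{r['p_adjusted']:10.2e}  {r['significant']}")
print("\nThe combined condition differs from every other condition after")
print("Bonferroni adjustment, mirroring the measured significance pattern.")
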