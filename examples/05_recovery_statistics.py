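"""Design risk ratios on a planted-native synthetic benchmark.

Runs the end-to-end recovery study twice -- once with a 5 kT
interface reward for the ground-truth native cluster, once on a flat
landscape -- and prints the design risk ratio with its 95% CI.
"""

from cdrdesign.studies import planted_recovery_study

for bonus in (5.0, 0.0):
    study = planted_recovery_study(bonus=bonus, seed=3, n_antibodies=4,
                                   n_runs=5, n_outer=15)
    rr = study.risk_ratio
    c = study.counts
    print(f"native-cluster bonus {bonus:.0f} kT: "
          f"%Recovered={c.pct_recovered:.0f}% %Sampled={c.pct_sampled:.0f}% "
          f"DRR={rr.estimate:.2f} 95%CI=[{rr.ci_low:.2f}, {rr.ci_high:.2f}]")
# With the bonus, the native cluster is recovered far more often than
# it is sampled (DRR well above 1, CI excluding 1): the Monte Carlo
# machinery finds and keeps the energetically preferred conformation.
# On the flat landscape the DRR is statistically indistinguishable
# from 1 -- recovery is pure sampling.
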