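"""Weighted histoscore, observer concordance and survival on a TMA cohort.

Simulates a 356-patient tissue microarray with a doubled hazard in the
high-NRF2 group, computes weighted histoscores (0-300) for both observers,
checks inter-observer agreement (ICC, Bland-Altman, discordance > 50), then
splits at the median score and compares survival (Kaplan-Meier + log-rank).
"""

from nrf2screen import (TmaSpec, concordance, dichotomize, generate_tma_cohort,
                        kaplan_meier, score_table)

tma, _ = generate_tma_cohort(TmaSpec(n_patients=356, hazard_ratio=2.0,
                                     censor_rate=0.3, seed=3))
scored = score_table(tma)
obs1 = scored[scored.observer == 1].set_index("patient")
obs2 = scored[scored.observer == 2].set_index("patient")

rep = concordance(obs1["histoscore"], obs2["histoscore"])
print(f"ICC = {rep.icc:.3f} (acceptable > 0.8: {rep.acceptable}); "
      f"Bland-Altman bias = {rep.bland_altman_bias:.2f} "
      f"[{rep.bland_altman_limits[0]:.1f}, {rep.bland_altman_limits[1]:.1f}]; "
      f"{len(rep.discordant_patients)} discordant patients")

groups, cutoff = dichotomize(obs1["histoscore"], "median")
fit = kaplan_meier(obs1["time_months"], obs1["event"], groups)
print(f"median-split cutoff: histoscore {cutoff:.0f}")
print(f"log-rank chi2 = {fit.logrank_statistic:.2f}, p = {fit.p_value:.2e}")
print(f"restricted mean survival: high {fit.rmst['high']:.1f} vs "
      f"low {fit.rmst['low']:.1f} months "
      f"(difference {fit.rmst_difference('low', 'high'):.1f} months, "
      f"horizon {fit.rmst_horizon:.0f} months)")
print()
print("A small log-rank p with a shorter restricted mean survival in the "
      "high group reproduces the qualitative finding: high nuclear NRF2 "
      "goes with worse cancer-specific survival.")
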