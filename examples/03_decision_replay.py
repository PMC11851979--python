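"""Replay the MSSR decision rules on the published summary columns and
rerun the meta-analysis on the published results table.

Pure decision logic — no network fitting — so it runs in seconds.
"""

from mssr import (
    count_attainable,
    load_published_table1_selection,
    load_published_table2,
    pearson_factor_analysis,
    replay_decisions,
    spearman_factor_analysis,
)

t1 = load_published_table1_selection()
print("replayed decisions for the five published example conditions:")
print(replay_decisions(t1).to_string(index=False), "\n")

t2 = load_published_table2()
print("attainable conditions (of 108):",
      f"stability={count_attainable(t2, 'stability')},",
      f"outperformance={count_attainable(t2, 'outperform')}\n")

print("factor correlations with the stability-criterion MSSR (95 conditions):")
print(f"{'factor':12s} {'spearman':>9s} {'pearson':>9s}")
spear = {fc.factor: fc for fc in spearman_factor_analysis(t2, "stability")}
pear = {fc.factor: fc for fc in pearson_factor_analysis(t2, "stability")}
for factor in spear:
    print(f"{factor:12s} {spear[factor].rho:+9.4f} {pear[factor].rho:+9.4f}")

# 'X' decisions mark cells where no ladder size up to 50,000 meets a
# criterion.  The required sample size rises with the noise level and
# falls steeply with Rt²: cells where little variance is explainable
# need enormous samples for stable, linear-beating networks.  The
# Pearson column is what the published analysis actually reports.
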