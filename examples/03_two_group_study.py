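"""Canonical-like vs noncanonical-like group comparison with known truth.

The default two-group study plants a C-end degron prevalence of 8.4% vs
16.8% (true odds ratio ~2.20) and a +0.15 tail-hydropathy shift in the
noncanonical-like group.  The pipeline should recover both.
"""

from degdet.degrons import degron_set_from_pairs
from degdet.pipeline import compare, profile
from degdet.synthetic_data import generate_two_group_study

cp, ncp, _, _, expected = generate_two_group_study(seed=1, n=5000)
c_set = degron_set_from_pairs([("GG", -0.5)], "C")

prof_ncp = profile(ncp, c_degrons=c_set, determinants=("ctth", "degrons"))
prof_cp = profile(cp, c_degrons=c_set, determinants=("ctth", "degrons"))
report = compare(prof_ncp, prof_cp).set_index("determinant")

row = report.loc["c_degron_present"]
print(f"true odds ratio      {expected['true_c_degron_or']:.3f}")
print(f"estimated odds ratio {row['effect_value']:.3f} "
      f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}, "
      f"Fisher p = {row['p_raw']:.1e})")
print()
row = report.loc["ctth"]
print(f"planted CTTH shift   +{expected['true_ctth_diff']:.2f}")
print(f"rank-biserial r      {row['effect_value']:+.3f} "
      f"(rank-sum p = {row['p_raw']:.1e})")
print("An |r| around 0.1-0.15 is a small but real effect: the tail-"
      "hydropathy regime where group differences are meaningful yet far "
      "from separable.")
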