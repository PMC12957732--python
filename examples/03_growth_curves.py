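"""Von Bertalanffy growth: per-zone fits and bootstrap comparison.

Ages come from otolith annulus counts (integers). The growth model is
L(t) = L_inf (1 - exp(-K (t - t0))) with t0 pinned at -2.0 yr; zones are
compared by overlap of percentile 95% bootstrap CIs.
"""

import reefdiet as rd
from reefdiet.growth import bootstrap_vbgf

data = rd.simulate_dataset(rd.default_config(seed=1))
fish = data.fish[data.fish["species"] == "H_puella"]

boots, pairwise = bootstrap_vbgf(fish, B=400, seed=1)

print("per-zone growth parameters (point estimate and bootstrap 95% CI):")
for zone, b in boots.items():
    lo, hi = b.ci["linf"]
    klo, khi = b.ci["k"]
    print(f"  {zone}: L_inf={b.point.linf:7.2f} mm [{lo:6.2f}, {hi:6.2f}], "
          f"K={b.point.k:.3f} /yr [{klo:.3f}, {khi:.3f}]")

print("\nzone pairs whose CIs are disjoint (evidence of different growth):")
print(pairwise[pairwise["differs"]][["zone_a", "zone_b", "parameter"]]
      .to_string(index=False))
# The generating truth gives the disturbed zone a high K and low L_inf
# (fast early growth, small asymptote), so K contrasts with the inner bay
# are expected to separate at these sample sizes.
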