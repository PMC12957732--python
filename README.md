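# reefdiet

Quantitative analysis of dietary resilience in coral-reef fishes across a
habitat-degradation gradient. The package links three lines of evidence for
two benthic-feeding species — a browsing corallivore and an active
invertebrate predator — sampled from reefs grouped into habitat zones of
high, intermediate and near-zero live coral cover:

1. **Body condition.** The length–weight relationship is fit as
   `ln W = ln a + b ln L` and each fish's Le Cren relative condition factor
   `K_n = W / (a L^b)` measures its plumpness relative to the
   length-specific population mean (`K_n = 1` is average). Zone effects on
   the condition–length relationship are modelled as `K_n ~ logL * zone`
   (Type I ANOVA, partial η², Tukey-adjusted marginal-slope contrasts), and
   condition *variability* between zones is contrasted with bias-corrected
   log variance ratios `lnVR = ln(SD₁/SD₂) + 1/(2(n₁−1)) − 1/(2(n₂−1))` on
   the interaction-model residuals, with percentile bootstrap CIs.
2. **Growth.** Otolith ages and lengths are fit to the von Bertalanffy
   growth function `L(t) = L∞(1 − e^(−K(t−t0)))` per zone by nonlinear least
   squares (t0 fixed at −2.0 yr by default), and zones are compared by
   overlap of bootstrap 95% CIs on `L∞` and `K`.
3. **Diet.** Gut-content metabarcoding OTU tables are analysed with
   Bray–Curtis dissimilarity, PCoA/NMDS ordination, one-way PERMANOVA with
   Bonferroni-corrected pairwise contrasts, sample-based rarefaction, the
   Amundsen–Costello feeding-strategy diagram (frequency of occurrence vs.
   prey-specific abundance `P_i = Σ S_i / Σ S_ti × 100`), and
   negative-binomial mixed models of prey read abundance against coral
   cover or age with zone / nested zone-reef random intercepts and
   likelihood-ratio tests.

A seed-reproducible synthetic-data generator (`reefdiet.simulate`) emulates
the study design — 2 species × 3 zones × 3 reefs × 20 fish, zone-specific
Dirichlet-multinomial diet profiles, lognormal sequencing depths, benthic
photo-quadrat point counts around zone coral-cover targets of
33.46 / 12.06 / 0.34 % — so the entire pipeline is testable without any
field data.

## Worked example

```python
import reefdiet as rd
from reefdiet.community import bray_curtis, permanova

data = rd.simulate_dataset(rd.default_config(seed=1))
fish = data.fish[data.fish["species"] == "C_capistratus"]

fit = rd.fit_length_weight(fish)
print(f"W = {fit.a:.3e} * L^{fit.b:.4f}")
# W = 3.489e-05 * L^2.9997

kn = rd.compute_kn(fish, fit)
inter = rd.fit_condition_interaction(kn)
for c in rd.lnvr_pairwise(kn.assign(resid=inter.residuals), B=1000, seed=1):
    print(c.zone_a, "vs", c.zone_b, round(c.lnvr, 3), c.significant)
# outer_bay vs inner_bay 0.419 True
# outer_bay vs inner_bay_disturbed -0.539 True
# inner_bay vs inner_bay_disturbed -0.957 True

dm = bray_curtis(data.otu.loc[fish["id"]])
zones = fish.set_index("id").loc[list(dm.ids), "zone"].to_numpy()
res = permanova(dm, zones, n_perm=9999, seed=1)
print(f"pseudo-F={res.pseudo_f:.2f}, R2={res.r2:.3f}, p={res.p_value:.4f}")
# pseudo-F=183.45, R2=0.675, p=0.0001
```

The negative `lnVR` values against the disturbed zone say condition is more
variable there (`exp(0.957) ≈ 2.6`-fold variance); the PERMANOVA p at the
permutation floor says no relabelling of zones reached the observed
between-zone separation in diet composition.

The `examples/` directory holds one short narrative script per capability
(simulation, condition/lnVR, growth, community analysis, feeding strategy
and mixed models); each prints the numbers it computes with a line on what
they mean. A thin CLI mirrors the stages:

```bash
reefdiet simulate --out data --seed 1
reefdiet condition --fish data/fish.csv --species C_capistratus --boot 1000
reefdiet growth --fish data/fish.csv --species H_puella --t0 fixed:-2
reefdiet permanova --otu data/otu.tsv --meta data/fish.csv --group zone
reefdiet run --out results --seed 1     # full pipeline + manifest
```

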