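"""OTU-table processing, rarefaction, Amundsen feeding strategy and the
negative-binomial mixed model of prey abundance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from reefdiet.diet import (
    aggregate_taxa,
    amundsen,
    fit_prey_glmm,
    presence_absence,
    rarefaction_curve,
    relative_abundance,
)


def toy_tables():
    otu = pd.DataFrame(
        [[3, 7, 0], [1, 0, 5], [2, 2, 2]],
        index=["f1", "f2", "f3"], columns=["OTU_1", "OTU_2", "OTU_3"])
    tax = pd.DataFrame({
        "phylum": ["A", "B", "B"],
        "class": ["a1", "b1", "b2"],
        "order": ["o", "o", "o"],
        "family": ["x", "y", "z"],
        "genus": ["g1", "g2", "g3"],
    }, index=["OTU_1", "OTU_2", "OTU_3"])
    return otu, tax


class TestAggregation:
    def test_phylum_sums(self):
        otu, tax = toy_tables()
        agg = aggregate_taxa(otu, tax, "phylum")
        assert list(agg.columns) == ["A", "B"]
        assert agg.loc["f1"].tolist() == [3, 7]
        assert agg.loc["f2"].tolist() == [1, 5]

    def test_reads_conserved_at_every_rank(self):
        otu, tax = toy_tables()
        for rank in ("phylum", "class", "family", "genus"):
            assert aggregate_taxa(otu, tax, rank).sum().sum() == otu.sum().sum()

    def test_unassigned_pooled(self):
        otu, tax = toy_tables()
        tax.loc["OTU_2", "genus"] = np.nan
        agg = aggregate_taxa(otu, tax, "genus")
        assert "unassigned" in agg.columns
        assert agg["unassigned"].tolist() == [7, 0, 2]

    def test_unknown_rank_rejected(self):
        otu, tax = toy_tables()
        with pytest.raises(ValueError):
            aggregate_taxa(otu, tax, "kingdom")


class TestRelativeAndBinary:
    def test_proportions(self):
        t = pd.DataFrame([[2, 2]], index=["s"], columns=["a", "b"])
        np.testing.assert_allclose(relative_abundance(t).to_numpy(), [[0.5, 0.5]])

    def test_round_trip(self):
        otu, _ = toy_tables()
        rel = relative_abundance(otu)
        back = rel.mul(otu.sum(axis=1), axis=0)
        np.testing.assert_allclose(back.to_numpy(), otu.to_numpy(), atol=1e-12)

    def test_min_reads_threshold(self):
        t = pd.DataFrame([[9, 10]], index=["s"], columns=["a", "b"])
        pa = presence_absence(t, min_reads=10)
        assert pa.loc["s"].tolist() == [0, 1]

    def test_all_zero_sample_rejected(self):
        t = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            relative_abundance(t)


class TestRarefaction:
    def test_endpoints(self):
        otu, _ = toy_tables()
        out = rarefaction_curve(otu, n_draws=100, seed=0)
        full = out[out["n_samples"] == 3].iloc[0]
        assert full["mean_richness"] == 3  # total observed richness
        assert full["sd_richness"] == 0
        single = out[out["n_samples"] == 1].iloc[0]
        per_sample = [(otu.loc[i] > 0).sum() for i in otu.index]
        assert abs(single["mean_richness"] - np.mean(per_sample)) < 0.15

    def test_pair_expectation_matches_exhaustive_enumeration(self):
        otu, _ = toy_tables()
        exact = np.mean([
            np.count_nonzero((otu.loc[list(pair)] > 0).any(axis=0))
            for pair in combinations(otu.index, 2)
        ])
        out = rarefaction_curve(otu, n_draws=4000, seed=1)
        got = out.loc[out["n_samples"] == 2, "mean_richness"].iloc[0]
        assert got == pytest.approx(exact, abs=0.05)

    def test_monotone_in_sample_count(self, default_dataset):
        fish = default_dataset.fish
        browser = fish[fish["species"] == "C_capistratus"].iloc[:12]
        sub = default_dataset.otu.loc[browser["id"]]
        out = rarefaction_curve(sub, n_draws=200, seed=2)
        means = out.sort_values("n_samples")["mean_richness"].to_numpy()
        assert (np.diff(means) >= -0.2).all()  # Monte-Carlo wiggle tolerance
        assert means[-1] >= means[0]


class TestAmundsen:
    def test_sole_prey_everywhere(self):
        t = pd.DataFrame([[10], [5]], index=["f1", "f2"], columns=["p"])
        pts, _ = amundsen(t)
        assert pts[0].fo == 100 and pts[0].pi == 100
        assert pts[0].quadrant == "dominant-specialized"

    def test_worked_fo_pi(self):
        # prey 'x' only in fish1 at 50% of its reads -> FO 25, P_i 50
        t = pd.DataFrame(
            [[5, 5], [0, 8], [0, 3], [0, 9]],
            index=[f"f{i}" for i in range(4)], columns=["x", "y"])
        pts, _ = amundsen(t)
        x = next(p for p in pts if p.prey == "x")
        assert x.fo == pytest.approx(25.0)
        assert x.pi == pytest.approx(50.0)

    def test_fo_depth_invariant_and_pi_mean_identity(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(1, 50, (6, 4)),
                         index=[f"f{i}" for i in range(6)])
        pts1, _ = amundsen(t)
        t2 = t.copy(); t2.iloc[0] *= 13
        pts2, _ = amundsen(t2)
        for a, b in zip(pts1, pts2):
            assert a.fo == b.fo
        # all prey present in every fish: P_i = mean relative abundance * 100
        rel = relative_abundance(t)
        for p in pts1:
            assert p.pi == pytest.approx(100 * rel[int(p.prey)].mean(), rel=1e-9)

    def test_absent_prey_excluded_and_empty_rejected(self):
        t = pd.DataFrame([[3, 0], [2, 0]], index=["f1", "f2"], columns=["a", "b"])
        pts, summary = amundsen(t)
        assert [p.prey for p in pts] == ["a"]
        assert summary["n_prey"].sum() == 1
        with pytest.raises(ValueError):
            amundsen(t.iloc[:0])


def _glmm_design(n_per_reef=20, seed=0, slope=0.0, sigma_reef=0.3, sigma_zone=0.2):
    rng = np.random.default_rng(seed)
    zones = np.repeat(["z1", "z2", "z3"], 3 * n_per_reef)
    reefs = np.repeat([f"r{i}" for i in range(9)], n_per_reef)
    cover = {"z1": 33.0, "z2": 12.0, "z3": 0.5}
    x = np.array([cover[z] for z in zones]) + np.repeat(rng.normal(0, 2, 9), n_per_reef)
    u_z = np.repeat(rng.normal(0, sigma_zone, 3), 3 * n_per_reef)
    u_r = np.repeat(rng.normal(0, sigma_reef, 9), n_per_reef)
    depth = np.round(rng.lognormal(np.log(8000), 0.4, zones.size))
    mu = depth * np.exp(-4.0 + slope * (x - x.mean()) + u_z + u_r)
    theta = 5.0
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return y, x, zones, reefs, depth


class TestPreyGlmm:
    def test_lrt_nonnegative_and_strong_effect_detected(self):
        # small random-intercept SDs so the cover effect is not absorbed by
        # the zone intercepts (power by construction)
        y, x, zones, reefs, depth = _glmm_design(
            seed=1, slope=0.05, sigma_reef=0.05, sigma_zone=0.02)
        res = fit_prey_glmm(y, x, zones, reefs, mode="offset", depth=depth,
                            n_nodes=11, compute_se=False)
        assert res.chi2 >= 0
        assert res.p_value < 0.001
        assert res.coefficient > 0

    def test_slope_recovered_within_two_se(self):
        y, x, zones, reefs, depth = _glmm_design(seed=2, slope=0.05)
        res = fit_prey_glmm(y, x, zones, reefs, mode="offset", depth=depth,
                            n_nodes=11, compute_se=True)
        assert res.se is not None
        assert abs(res.coefficient - 0.05) < 2 * res.se + 0.01

    def test_mimic_mode_transforms(self):
        y, x, zones, reefs, _ = _glmm_design(seed=3, slope=0.08)
        res = fit_prey_glmm(y, x, zones, reefs, mode="mimic",
                            transformation="fourth_root", n_nodes=7,
                            compute_se=False)
        assert res.transformation == "fourth_root"
        assert np.isfinite(res.chi2)

    def test_constant_predictor_rejected(self):
        y, x, zones, reefs, depth = _glmm_design(seed=4)
        with pytest.raises(ValueError):
            fit_prey_glmm(y, np.ones_like(x), zones, reefs, mode="offset",
                          depth=depth)

    def test_matches_glmmtmb_oracle(self, tmp_path):
        # independent R fit of the same model on the same data
        import subprocess, shutil
        rng = np.random.default_rng(7)
        n = 120
        zones = np.repeat(["z1", "z2", "z3"], 40)
        reefs = np.repeat([f"r{i}" for i in range(6)], 20)
        x = rng.normal(size=n)
        u_r = np.repeat(rng.normal(0, 0.4, 6), 20)
        theta = 4.0
        mu = np.exp(2.0 + 0.5 * x + u_r)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        df = pd.DataFrame(dict(y=y, x=x, zone=zones, reef=reefs))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(glmmTMB))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- glmmTMB(y ~ x + (1|zone/reef), family=nbinom2, data=d)\n'
            'co <- summary(m)$coefficients$cond\n'
            'cat(co["x","Estimate"], co["x","Std. Error"], logLik(m), sep="\\n")\n'
        )
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript not on PATH"
        out = subprocess.run([rscript, str(script)], capture_output=True,
                             text=True, check=True)
        slope_r, se_r, ll_r = map(float, out.stdout.strip().split("\n")[-3:])

        from reefdiet.glmm import fit_nb_mixed
        X = np.column_stack([np.ones(n), x])
        f = fit_nb_mixed(y, X, zones, reefs, n_nodes=11, compute_se=False)
        assert f.beta[1] == pytest.approx(slope_r, abs=3e-3)
        assert f.loglik >= ll_r - 0.05  # our ML at least as good
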