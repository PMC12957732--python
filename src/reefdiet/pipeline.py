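"""End-to-end pipeline driver.

Runs the full analysis sequence on a dataset (synthetic or loaded from
disk): survey summaries, condition (length-weight fit, K_n, interaction
model, lnVR), growth (per-zone VBGF with bootstrap CI comparison) and diet
(aggregation, ordination, PERMANOVA, Amundsen, prey-abundance mixed models),
writing one CSV/TSV per result plus a JSON run manifest with the config
hash, per-file checksums and per-stage wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import condition as cond_mod
from . import community, diet, growth, univariate
from .io import write_table, write_otu_table
from .simulate import SyntheticDataset, DEFAULT_HABITS

logger = logging.getLogger("reefdiet")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    species: tuple[str, ...] = ()          # empty = all species present
    run_surveys: bool = True
    run_condition: bool = True
    run_growth: bool = True
    run_diet: bool = True
    boot: int = 1000
    n_perm: int = 10_000
    glmm_mode: str = "offset"

    def config_hash(self) -> str:
        # identifies the analysis settings; the output location is excluded so
        # re-running the same analysis elsewhere reproduces identical artifacts
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    warnings: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(data: SyntheticDataset, config: PipelineConfig) -> RunManifest:
    """Execute every enabled stage in order; any stage error aborts with the
    stage name while a partial manifest survives at out_dir/manifest.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = f"reefdiet config={config.config_hash()} seed={config.seed}"
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)

    def emit(df: pd.DataFrame, name: str, index: bool = False):
        path = out / name
        if name.endswith(".tsv") and index:
            write_otu_table(df, path, provenance=prov)
        else:
            write_table(df, path, provenance=prov, index=index)
        manifest.outputs[name] = _checksum(path)

    species = list(config.species) or list(dict.fromkeys(data.fish["species"]))

    def stage(name: str, fn, enabled: bool):
        if not enabled:
            manifest.skipped.append(name)
            logger.info("stage %s skipped", name)
            return
        logger.info("stage %s start", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:
            manifest.stages[name] = {"status": "error", "error": str(e)}
            manifest.save(out / "manifest.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest.stages[name] = {
            "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s done", name)

    def do_surveys():
        emit(univariate.benthic_summary(data.benthic), "benthic_summary.csv")
        kw_groups = {
            z: sub["coral_cover_pct"].to_numpy()
            for z, sub in univariate.benthic_summary(data.benthic).groupby("zone")
        }
        # quadrat-level KW on coral cover across zones
        cat_cols = [c for c in data.benthic.columns
                    if c not in ("zone", "reef", "transect", "quadrat")]
        coral_cols = [c for c in cat_cols if c.startswith("coral_")]
        q = data.benthic.copy()
        q["coral_pct"] = 100 * q[coral_cols].sum(axis=1) / q[cat_cols].sum(axis=1)
        kw = univariate.kruskal_wallis(
            {z: s["coral_pct"].to_numpy() for z, s in q.groupby("zone")})
        dunn = univariate.dunn_posthoc(
            {z: s["coral_pct"].to_numpy() for z, s in q.groupby("zone")})
        emit(pd.DataFrame([{
            "test": "kruskal_coral_cover", "statistic": kw.statistic,
            "df": kw.df, "p": kw.p_value, "epsilon_sq": kw.effect_size,
        }]), "survey_tests.csv")
        emit(dunn, "survey_dunn.csv")
        emit(univariate.densities(data.fish_transects), "fish_densities.csv")
        emit(univariate.densities(data.invertebrates), "invert_densities.csv")

    def do_condition():
        frames_kn, frames_anova, frames_lnvr = [], [], []
        for sp in species:
            fish = data.fish[data.fish["species"] == sp]
            fit = cond_mod.fit_length_weight(fish)
            kn = cond_mod.compute_kn(fish, fit)
            inter = cond_mod.fit_condition_interaction(kn)
            resid = kn.assign(resid=inter.residuals)
            comps = cond_mod.lnvr_pairwise(resid, B=config.boot, seed=config.seed)
            kn["species"] = sp
            frames_kn.append(kn)
            a = inter.anova.reset_index().rename(columns={"index": "term"})
            a["species"] = sp
            frames_anova.append(a)
            lv = pd.DataFrame([asdict(c) for c in comps])
            lv["species"] = sp
            frames_lnvr.append(lv)
        emit(pd.concat(frames_kn), "condition_kn.csv")
        emit(pd.concat(frames_anova), "condition_anova.csv")
        emit(pd.concat(frames_lnvr), "condition_lnvr.csv")

    def do_growth():
        rows, ci_rows = [], []
        for sp in species:
            fish = data.fish[data.fish["species"] == sp].dropna(subset=["age_yr"])
            boots, pairwise = growth.bootstrap_vbgf(
                fish, B=max(100, config.boot // 5), seed=config.seed)
            for zone, b in boots.items():
                rows.append({"species": sp, "zone": zone, "linf": b.point.linf,
                             "k": b.point.k, "t0": b.point.t0})
                for p, (lo, hi) in b.ci.items():
                    ci_rows.append({"species": sp, "zone": zone, "parameter": p,
                                    "ci_low": lo, "ci_high": hi, "B": b.B})
        emit(pd.DataFrame(rows), "growth_params.csv")
        emit(pd.DataFrame(ci_rows), "growth_ci.csv")

    def do_diet():
        perm_rows, pair_frames, amundsen_frames = [], [], []
        for sp in species:
            fish = data.fish[data.fish["species"] == sp]
            otu = data.otu.loc[fish["id"]]
            otu = otu.loc[:, otu.sum(axis=0) > 0]
            dm = community.bray_curtis(otu, mode="relative")
            zones = fish.set_index("id").loc[list(dm.ids), "zone"].to_numpy()
            res = community.permanova(dm, zones, n_perm=config.n_perm,
                                      seed=config.seed, grouping="zone")
            perm_rows.append({"species": sp, "pseudo_f": res.pseudo_f, "r2": res.r2,
                              "p": res.p_value, "permutations": res.permutations})
            pw = community.pairwise_permanova(dm, zones, n_perm=config.n_perm,
                                              seed=config.seed)
            pw["species"] = sp
            pair_frames.append(pw)
            ord_res = community.nmds(dm, k=2, n_starts=5, seed=config.seed)
            coords = ord_res.coordinates.copy()
            coords["species"] = sp
            coords["zone"] = zones
            emit(coords, f"nmds_{sp}.csv", index=True)
            for zone in dict.fromkeys(zones):
                sub = otu.loc[fish.loc[fish["zone"] == zone, "id"]]
                sub = sub.loc[:, sub.sum(axis=0) > 0]
                pts, _ = diet.amundsen(sub)
                ad = pd.DataFrame([asdict(p) for p in pts])
                ad["species"], ad["zone"] = sp, zone
                amundsen_frames.append(ad)
        emit(pd.DataFrame(perm_rows), "diet_permanova.csv")
        emit(pd.concat(pair_frames), "diet_permanova_pairwise.csv")
        emit(pd.concat(amundsen_frames), "diet_amundsen.csv")
        # prey-abundance model: coral cover vs focal prey groups
        cover = univariate.benthic_summary(data.benthic).set_index("reef")["coral_cover_pct"]
        glmm_rows = []
        focal = [
            (species[0], "phylum", "Annelida", "zone/reef"),
            (species[0], "order", "Scleractinia", "zone"),
        ]
        if len(species) > 1:
            focal += [(species[1], "habit", "benthic", "zone/reef"),
                      (species[1], "habit", "planktonic", "zone/reef")]
        for sp, rank, label, rand in focal:
            fish = data.fish[data.fish["species"] == sp]
            otu = data.otu.loc[fish["id"]]
            if rank == "habit":
                y = diet.habit_group_counts(otu, data.taxonomy, DEFAULT_HABITS, label)
            else:
                y = diet.prey_group_counts(otu, data.taxonomy, rank, label)
            x = fish["reef"].map(cover).to_numpy()
            res = diet.fit_prey_glmm(
                y.to_numpy(), x, fish["zone"].to_numpy(), fish["reef"].to_numpy(),
                random=rand, mode=config.glmm_mode,
                depth=otu.sum(axis=1).to_numpy(), compute_se=False, n_nodes=11,
            )
            glmm_rows.append({
                "species": sp, "response": label, "predictor": "coral_cover",
                "random": rand, "mode": res.mode, "coefficient": res.coefficient,
                "chi2": res.chi2, "p": res.p_value,
            })
        emit(pd.DataFrame(glmm_rows), "diet_glmm.csv")

    stage("surveys", do_surveys, config.run_surveys)
    stage("condition", do_condition, config.run_condition)
    stage("growth", do_growth, config.run_growth)
    stage("diet", do_diet, config.run_diet)
    manifest.save(out / "manifest.json")
    return manifest
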