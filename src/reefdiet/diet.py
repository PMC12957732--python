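"""Dietary-metabarcoding profile analysis.

OTU-table processing (taxonomic aggregation, relative abundance, presence-
absence), sample-based rarefaction, the Amundsen-Costello graphical feeding-
strategy analysis and negative-binomial mixed models of prey read abundance
against coral cover or age.

Amundsen's plot places each prey taxon at (frequency of occurrence,
prey-specific abundance): FO_i is the percentage of fish containing prey i;
P_i is prey i's percentage of the diet computed only over the fish that
contain it. Prey in the upper right are population-level dominants; the
lower left holds rare, occasional items; the off-diagonal corners read as the
between- (BPC) and within-phenotype (WPC) contributions to niche width.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .glmm import fit_nb_mixed, lrt, NBMixedFit

__all__ = [
    "RANKS",
    "aggregate_taxa",
    "relative_abundance",
    "presence_absence",
    "rarefaction_curve",
    "AmundsenPoint",
    "amundsen",
    "GlmmResult",
    "fit_prey_glmm",
]

RANKS = ("phylum", "class", "order", "family", "genus", "species")


def aggregate_taxa(otu: pd.DataFrame, taxonomy: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum reads per sample across OTUs sharing a taxon label at ``rank``.

    OTUs unassigned at the rank (missing, NaN or "unassigned") are pooled
    into an explicit ``unassigned`` column. Total reads are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if rank not in taxonomy.columns:
        raise ValueError(f"taxonomy table lacks a {rank!r} column")
    labels = taxonomy[rank].reindex(otu.columns)
    labels = labels.where(labels.notna() & (labels != ""), "unassigned")
    out = otu.T.groupby(labels.to_numpy()).sum().T
    out.index = otu.index
    return out


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions (rows sum to 1)."""
    totals = table.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return table.div(totals, axis=0)


def presence_absence(table: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Binary table: 1 where the count is >= ``min_reads``."""
    totals = table.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return (table >= min_reads).astype(int)


def rarefaction_curve(
    table: pd.DataFrame,
    grouping=None,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-based rarefaction: expected OTU richness versus number of
    samples drawn without replacement, per group.

    Returns a long table (group, n_samples, mean_richness, sd_richness).
    At s = group size the mean equals total observed richness with SD 0.
    """
    rng = np.random.default_rng(seed)
    if grouping is None:
        grouping = pd.Series("all", index=table.index)
    else:
        grouping = pd.Series(np.asarray(grouping), index=table.index)
    rows = []
    for gname, idx in grouping.groupby(grouping).groups.items():
        sub = (table.loc[idx].to_numpy() > 0)
        n = sub.shape[0]
        if n < 2:
            raise ValueError(f"group {gname}: need >= 2 samples")
        for s in range(1, n + 1):
            if s == n:
                rich = np.array([np.count_nonzero(sub.any(axis=0))], dtype=float)
            else:
                rich = np.empty(n_draws)
                for d in range(n_draws):
                    pick = rng.choice(n, size=s, replace=False)
                    rich[d] = np.count_nonzero(sub[pick].any(axis=0))
            rows.append({
                "group": gname, "n_samples": s,
                "mean_richness": float(rich.mean()),
                "sd_richness": float(rich.std(ddof=0)),
            })
    return pd.DataFrame(rows)


@dataclass
class AmundsenPoint:
    prey: str
    fo: float      # frequency of occurrence, % of fish
    pi: float      # prey-specific abundance, %
    quadrant: str  # dominant-specialized | rare-occasional | BPC-leaning | WPC-leaning


def amundsen(
    table: pd.DataFrame,
    fo_threshold: float = 50.0,
    pi_threshold: float = 50.0,
) -> tuple[list[AmundsenPoint], pd.DataFrame]:
    """Amundsen-Costello feeding-strategy coordinates from a read table.

    Abundances are converted to relative reads per fish. For each prey:
    FO = 100 * (#fish containing it)/(#fish);
    P_i = 100 * sum(rel. abundance in fish containing it) / sum(total rel.
    abundance in those same fish). Prey absent from every fish are excluded.
    Quadrants are labelled from the FO/P_i thresholds: high-FO high-P_i prey
    are population-level dominants (specialization), low-low are rare
    occasional items, high-P_i low-FO points lean BPC (among-individual
    variation) and high-FO low-P_i points lean WPC (broad individual diets).
    The summary counts prey per quadrant.
    """
    if table.shape[0] == 0:
        raise ValueError("empty table")
    rel = relative_abundance(table)
    pts: list[AmundsenPoint] = []
    n_fish = rel.shape[0]
    for prey in rel.columns:
        present = rel[prey] > 0
        n_pres = int(present.sum())
        if n_pres == 0:
            continue
        fo = 100.0 * n_pres / n_fish
        sub = rel.loc[present]
        pi = 100.0 * sub[prey].sum() / sub.sum(axis=1).sum()
        if fo >= fo_threshold and pi >= pi_threshold:
            quad = "dominant-specialized"
        elif fo < fo_threshold and pi < pi_threshold:
            quad = "rare-occasional"
        elif pi >= pi_threshold:
            quad = "BPC-leaning"
        else:
            quad = "WPC-leaning"
        pts.append(AmundsenPoint(prey=str(prey), fo=float(fo), pi=float(pi), quadrant=quad))
    summary = (
        pd.Series([p.quadrant for p in pts], dtype="object")
        .value_counts()
        .reindex(["dominant-specialized", "rare-occasional", "BPC-leaning", "WPC-leaning"],
                 fill_value=0)
        .rename_axis("quadrant")
        .to_frame("n_prey")
        .reset_index()
    )
    return pts, summary


@dataclass
class GlmmResult:
    response: str
    predictor: str
    mode: str                 # "offset" (recommended) or "mimic"
    transformation: str | None
    coefficient: float
    se: float | None
    chi2: float
    p_value: float
    random: str
    full: NBMixedFit
    null: NBMixedFit


_TRANSFORMS = {
    None: lambda y: y,
    "sqrt": np.sqrt,
    "fourth_root": lambda y: y ** 0.25,
    "log": lambda y: np.log1p(y),
}


def fit_prey_glmm(
    counts,
    predictor,
    zone,
    reef=None,
    random: str = "zone/reef",
    mode: str = "offset",
    transformation: str | None = None,
    depth=None,
    n_nodes: int = 11,
    compute_se: bool = True,
) -> GlmmResult:
    """Test a predictor of prey read abundance with an NB mixed model.

    Two response conventions are provided. ``mode="offset"`` (recommended)
    models the raw prey counts with a log total-read-depth offset, so the
    model addresses relative consumption directly. ``mode="mimic"`` first
    applies the named response transformation (sqrt, fourth_root, log) and
    rounds to the nearest integer before the NB fit; it reproduces a
    transform-then-count-model convention and is clearly labelled as such.

    The test is a likelihood-ratio chi-square (df 1) of the full model
    against the same model without the predictor.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    x = np.asarray(predictor, dtype=float)
    if np.std(x) == 0:
        raise ValueError("predictor does not vary")
    if mode == "mimic":
        if transformation not in _TRANSFORMS:
            raise ValueError(f"unknown transformation {transformation!r}")
        y = np.round(_TRANSFORMS[transformation](y))
        offset = None
    elif mode == "offset":
        if depth is None:
            raise ValueError("mode='offset' requires per-fish total read depths")
        offset = np.log(np.asarray(depth, dtype=float))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    xc = x - x.mean()  # center for optimizer stability; slope unchanged
    X_full = np.column_stack([np.ones_like(xc), xc])
    X_null = X_full[:, :1]
    null = fit_nb_mixed(y, X_null, zone, reef, offset=offset, random=random,
                        n_nodes=n_nodes, compute_se=False)
    # warm-start the full model at the null optimum (slope 0): guarantees the
    # nested-model likelihood ordering up to optimizer tolerance
    warm = np.insert(null.params_, 1, 0.0)
    full = fit_nb_mixed(y, X_full, zone, reef, offset=offset, random=random,
                        n_nodes=n_nodes, compute_se=compute_se, x0_extra=warm)
    chi2, p = lrt(full, null)
    se = float(full.beta_se[1]) if full.beta_se is not None else None
    return GlmmResult(
        response="counts", predictor="x", mode=mode, transformation=transformation,
        coefficient=float(full.beta[1]), se=se, chi2=chi2, p_value=p,
        random=random, full=full, null=null,
    )


def prey_group_counts(
    otu: pd.DataFrame, taxonomy: pd.DataFrame, rank: str, label: str
) -> pd.Series:
    """Convenience: per-sample read counts of one taxon at a rank."""
    agg = aggregate_taxa(otu, taxonomy, rank)
    if label not in agg.columns:
        return pd.Series(0, index=otu.index, name=label)
    return agg[label].rename(label)


def habit_group_counts(
    otu: pd.DataFrame, taxonomy: pd.DataFrame, habits: dict[str, str], habit: str
) -> pd.Series:
    """Per-sample reads of arthropod genera with a given habit (benthic or
    planktonic), from a genus -> habit lookup."""
    genus = taxonomy["genus"].reindex(otu.columns)
    sel = [o for o, g in genus.items() if habits.get(g) == habit]
    return otu[sel].sum(axis=1).rename(f"{habit}_arthropods")
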