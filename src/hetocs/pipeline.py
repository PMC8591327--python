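"""Multigeneration breeding-program simulation and its statistical analyses.

Each generation: phenotype the candidates, refit the ridge evaluation on the
cumulative reference, build the (beta-adjusted) relationship matrices, solve
the contribution QP on the GEBVs, discretize contributions into a mate plan
(cost-minimizing LP or random control), and produce the next generation by
simulated meiosis. Trajectories record gain, contribution-weighted and
population "true" coancestry (always on the unmodified G, whatever beta
drove selection), breeding potential and evaluation accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from . import evaluation as ev
from .grm import build_relationship_set, coancestry, compute_grm
from .mating import contributions_to_gametes, random_mating, solve_mating
from .meiosis import make_offspring
from .ocs import OCSProblem, solve_ocs
from .popgen import (
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    TraitModel,
    encode_genotypes,
    simulate_phenotypes,
    true_breeding_value,
)

__all__ = [
    "ProgramConfig",
    "BreedingState",
    "run_generation",
    "run_program",
    "run_grid",
    "breeding_potential",
    "anova_type1",
    "AnovaResult",
    "pareto_report",
]


@dataclass
class ProgramConfig:
    """All knobs of one simulated breeding scenario.

    ``alpha`` weights coancestry against gain in the contribution QP;
    ``beta`` is the He x Ho value in the adjusted relationship matrix;
    ``mate_mode`` chooses the cost-minimizing allocator or the random
    control. ``sigma_g2_mode`` decides whether the environmental variance
    tracks the current generation's TBV variance (keeping realized h2 near
    nominal as variance erodes) or stays fixed at the founder value.
    """

    alpha: float
    beta: float = 0.0
    mate_mode: str = "lp"
    n_generations: int = 20
    n_replicates: int = 1
    h2: float = 0.5134
    population_size: int | None = None
    upper_bound: float = 0.5
    eig_floor: float | None = None
    ridge_lambda: float | str = "auto"
    sigma_g2_mode: str = "per_generation"
    root_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (-1.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [-1, 1]")
        if self.mate_mode not in ("lp", "random"):
            raise ValueError("mate_mode must be 'lp' or 'random'")
        if self.n_generations < 1 or self.n_replicates < 1:
            raise ValueError("n_generations and n_replicates must be >= 1")
        if self.sigma_g2_mode not in ("per_generation", "founder_fixed"):
            raise ValueError("sigma_g2_mode must be 'per_generation' or 'founder_fixed'")


@dataclass
class BreedingState:
    """Mutable state carried across generations of one replicate."""

    panel: HaplotypePanel
    gmap: GeneticMap
    trait: TraitModel
    X_ref: np.ndarray | None = None  # L x n cumulative reference genotypes
    y_ref: np.ndarray | None = None
    founder_tbv_mean: float = 0.0
    founder_sigma_g2: float = 0.0

    @classmethod
    def from_founders(
        cls, panel: HaplotypePanel, gmap: GeneticMap, trait: TraitModel
    ) -> "BreedingState":
        tbv = true_breeding_value(encode_genotypes(panel), trait)
        return cls(
            panel=panel,
            gmap=gmap,
            trait=trait,
            founder_tbv_mean=float(tbv.mean()),
            founder_sigma_g2=float(tbv.var()),
        )


def breeding_potential(
    X: GenotypeMatrix, effects: np.ndarray
) -> tuple[float, np.ndarray]:
    """GEBV mass on loci whose alleles still segregate.

    A locus is fixed when every individual carries the same homozygote; the
    per-individual value sums the (true) allelic effects over the
    non-fixed loci, and the population value is the mean. This measures how
    much breeding value can still be reshuffled by future selection.
    """
    effects = np.asarray(effects, dtype=float)
    Xm = X.X
    fixed = np.all(Xm == 1, axis=1) | np.all(Xm == -1, axis=1)
    seg = ~fixed
    per_ind = effects[seg] @ Xm[seg].astype(float)
    return float(per_ind.mean()) if per_ind.size else 0.0, per_ind


def _population_metrics(state: BreedingState) -> dict:
    X = encode_genotypes(state.panel)
    tbv = true_breeding_value(X, state.trait)
    n = state.panel.n_individuals
    L = state.panel.n_loci
    uniform = np.full(n, 1.0 / n)
    G = compute_grm(X)
    bp, _ = breeding_potential(X, state.trait.effects)
    fixed = np.all(X.X == 1, axis=1) | np.all(X.X == -1, axis=1)
    return {
        "generation": state.panel.generation,
        "n_individuals": n,
        "mean_TBV": float(tbv.mean()),
        "sd_TBV": float(tbv.std()),
        "gain": float(tbv.mean() - state.founder_tbv_mean),
        "population_true_coancestry": coancestry(uniform, G, n_loci=L),
        "breeding_potential": bp,
        "n_fixed_loci": int(fixed.sum()),
    }


def run_generation(
    state: BreedingState, config: ProgramConfig, seed_seq: np.random.SeedSequence
) -> tuple[BreedingState, dict]:
    """Advance one generation; returns the new state and the step record.

    The record describes the candidate generation that was just selected:
    its population metrics plus the selection-step quantities (GEBV mean,
    contribution-weighted coancestries, evaluation accuracy).
    """
    ss_pheno, ss_mating, ss_meiosis = seed_seq.spawn(3)
    panel, gmap, trait = state.panel, state.gmap, state.trait
    n = panel.n_individuals
    pop_size = config.population_size or n
    X = encode_genotypes(panel)
    tbv = true_breeding_value(X, trait)

    # (1) phenotype the candidates
    sigma_g2 = (
        float(tbv.var())
        if config.sigma_g2_mode == "per_generation"
        else state.founder_sigma_g2
    )
    y = simulate_phenotypes(tbv, trait.h2, sigma_g2, ss_pheno)

    # (2) grow the reference and refit the ridge evaluation
    X_ref = X.X if state.X_ref is None else np.hstack([state.X_ref, X.X])
    y_ref = y if state.y_ref is None else np.concatenate([state.y_ref, y])
    if config.ridge_lambda == "auto":
        p = (X_ref.mean(axis=1) + 1.0) / 2.0
        lam = max(
            ((1.0 - trait.h2) / trait.h2) * float(np.sum(2.0 * p * (1.0 - p))), 1e-8
        )
    else:
        lam = float(config.ridge_lambda)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-equal phenotypes at full fixation
        model = ev.fit_ridge(GenotypeMatrix(X_ref), y_ref, lam)
    gebv = ev.predict_gebv(model, X)

    # (3) relationship matrices on the candidates
    rel = build_relationship_set(X, config.beta, config.eig_floor)

    # (4) contributions from the QP on GEBVs
    sol = solve_ocs(
        OCSProblem(
            M=rel.Gstar_pd, Y=gebv, alpha=config.alpha, upper_bound=config.upper_bound
        )
    )

    # (5) discretize and allocate mates (LP cost = raw adjusted matrix)
    gametes = contributions_to_gametes(sol.c, pop_size)
    if config.mate_mode == "lp":
        plan = solve_mating(gametes, rel.Gstar)
    else:
        plan = random_mating(gametes, ss_mating)

    # (6) next generation by meiosis
    offspring, _ = make_offspring(panel, plan, gmap, ss_meiosis)

    record = _population_metrics(state)
    tbv_sd = tbv.std()
    record.update(
        {
            "mean_GEBV": float(gebv.mean()),
            "contribution_coancestry_Gstar": coancestry(
                sol.c, rel.Gstar, n_loci=panel.n_loci
            ),
            "contribution_true_coancestry_G": coancestry(
                sol.c, rel.G, n_loci=panel.n_loci
            ),
            "evaluation_accuracy": (
                float(np.corrcoef(gebv, tbv)[0, 1])
                if tbv_sd > 0 and gebv.std() > 0
                else float("nan")
            ),
            "ocs_status": sol.status,
        }
    )
    new_state = replace(state, panel=offspring, X_ref=X_ref, y_ref=y_ref)
    return new_state, record


def run_program(
    config: ProgramConfig,
    founders: HaplotypePanel,
    gmap: GeneticMap,
    effects: np.ndarray,
) -> pd.DataFrame:
    """Run all replicates of one scenario; one row per generation per replicate.

    Rows for generations 0..n_generations-1 carry selection-step fields; the
    terminal generation row carries population metrics only. Replicate seeds
    derive deterministically from ``root_seed``, and output row order is
    (replicate, generation) regardless of execution order.
    """
    trait = TraitModel(np.asarray(effects, dtype=float), config.h2)
    rows = []
    for rep in range(config.n_replicates):
        state = BreedingState.from_founders(founders, gmap, trait)
        try:
            for gen in range(config.n_generations):
                ss = np.random.SeedSequence(
                    entropy=config.root_seed, spawn_key=(rep, gen)
                )
                state, record = run_generation(state, config, ss)
                record["replicate"] = rep
                rows.append(record)
            final = _population_metrics(state)
            final["replicate"] = rep
            rows.append(final)
        except Exception as exc:  # record the failure, keep other replicates
            rows.append(
                {
                    "replicate": rep,
                    "generation": state.panel.generation,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    df["alpha"] = config.alpha
    df["beta"] = config.beta
    df["mate_mode"] = config.mate_mode
    return df.sort_values(["replicate", "generation"], kind="stable").reset_index(
        drop=True
    )


def run_grid(
    founders: HaplotypePanel,
    gmap: GeneticMap,
    effects: np.ndarray,
    alphas,
    betas,
    mate_modes=("lp",),
    **config_kwargs,
) -> pd.DataFrame:
    """Run the full alpha x beta x mating grid and stack the trajectories."""
    frames = []
    for alpha in alphas:
        for beta in betas:
            for mode in mate_modes:
                cfg = ProgramConfig(
                    alpha=float(alpha), beta=float(beta), mate_mode=mode,
                    **config_kwargs,
                )
                frames.append(run_program(cfg, founders, gmap, effects))
    return pd.concat(frames, ignore_index=True)


@dataclass
class AnovaResult:
    """Sequential-ANOVA table plus fit summary."""

    table: pd.DataFrame
    adj_r2: float
    degenerate: bool = False
    dropped: list = field(default_factory=list)


def anova_type1(
    results: pd.DataFrame, model: int, response: str = "Y"
) -> AnovaResult:
    """Type I (sequential) ANOVA of a trajectory summary.

    Model 1 fits ``Y ~ alpha + beta + alpha^2 + m`` and model 2 ``Y ~ beta + m``
    with alpha and beta as numeric covariates and m the 0/1 mate-allocation
    indicator, in exactly that term order. Sequential sums of squares are the
    successive drops in residual SS; %variance is SS divided by the total
    (centered) SS; F tests each term against the full-model residual.
    Rank-deficient terms (e.g. a quadratic term with a single alpha level)
    are dropped with a warning.
    """
    df = results.copy()
    if "m" not in df.columns and "mate_mode" in df.columns:
        df["m"] = (df["mate_mode"] == "lp").astype(float)
    y = df[response].to_numpy(dtype=float)
    n = y.shape[0]
    if model == 1:
        term_names = ["alpha", "beta", "alpha2", "m"]
        df["alpha2"] = df["alpha"].to_numpy(dtype=float) ** 2
    elif model == 2:
        term_names = ["beta", "m"]
    else:
        raise ValueError("model must be 1 or 2")
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0.0:
        table = pd.DataFrame(
            {
                "term": term_names,
                "estimate": 0.0,
                "ss": 0.0,
                "pct_variance": 0.0,
                "df": 1,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return AnovaResult(table=table, adj_r2=0.0, degenerate=True)

    # build the design sequentially, dropping aliased terms
    design = [np.ones(n)]
    kept, dropped = [], []
    for name in term_names:
        col = df[name].to_numpy(dtype=float)
        candidate = np.column_stack(design + [col])
        if np.linalg.matrix_rank(candidate) > len(design):
            design.append(col)
            kept.append(name)
        else:
            dropped.append(name)
            warnings.warn(f"dropping aliased ANOVA term {name!r}")
    Xd = np.column_stack(design)
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    rss_full = float(resid @ resid)
    p_full = Xd.shape[1]
    df_resid = n - p_full
    mse = rss_full / df_resid if df_resid > 0 else np.nan

    # sequential SS: drop in RSS as each term is added in order
    rows = []
    prev_rss = ss_total
    for k, name in enumerate(kept, start=1):
        Xk = Xd[:, : k + 1]
        ck, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        rk = y - Xk @ ck
        rss_k = float(rk @ rk)
        ss = prev_rss - rss_k
        prev_rss = rss_k
        F = (ss / 1.0) / mse if mse and np.isfinite(mse) and mse > 0 else np.nan
        pval = (
            float(scipy.stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else np.nan
        )
        rows.append(
            {
                "term": name,
                "estimate": float(coef[k]),
                "ss": ss,
                "pct_variance": 100.0 * ss / ss_total,
                "df": 1,
                "F": F,
                "p": pval,
            }
        )
    rows.append(
        {
            "term": "residual",
            "estimate": np.nan,
            "ss": rss_full,
            "pct_variance": 100.0 * rss_full / ss_total,
            "df": df_resid,
            "F": np.nan,
            "p": np.nan,
        }
    )
    r2 = 1.0 - rss_full / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
    return AnovaResult(
        table=pd.DataFrame(rows), adj_r2=float(adj_r2), dropped=dropped
    )


def pareto_report(
    final_records: pd.DataFrame,
    gain_col: str = "gain",
    coancestry_col: str = "population_true_coancestry",
    group_cols=("alpha", "beta", "mate_mode"),
) -> pd.DataFrame:
    """Group means of (gain, true coancestry) with pairwise dominance flags.

    A group dominates another when it attains at least the gain at no more
    coancestry, strictly better in one of the two.
    """
    group_cols = list(group_cols)
    g = final_records.groupby(group_cols, sort=True)
    summary = g.agg(
        gain_mean=(gain_col, "mean"),
        gain_sd=(gain_col, "std"),
        coancestry_mean=(coancestry_col, "mean"),
        coancestry_sd=(coancestry_col, "std"),
        n=(gain_col, "size"),
    ).reset_index()
    if len(summary) < 2:
        raise ValueError("pareto_report needs at least two groups")
    k = len(summary)
    dominates = [[] for _ in range(k)]
    dominated = np.zeros(k, dtype=bool)
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            ga, gb = summary.gain_mean[a], summary.gain_mean[b]
            ca, cb = summary.coancestry_mean[a], summary.coancestry_mean[b]
            if ga >= gb and ca <= cb and (ga > gb or ca < cb):
                dominates[a].append(b)
                dominated[b] = True
    summary["dominates"] = [",".join(map(str, d)) for d in dominates]
    summary["is_dominated"] = dominated
    return summary
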