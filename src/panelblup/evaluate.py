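"""CG-stratified cross-validation, external validation and MAS comparator.

The unit of bookkeeping is the evaluation record: one row per
(trait, cohort, strategy, panel size, replicate, fold) holding the
prediction accuracy cor(GEBV, y_adj)/sqrt(h2) (Spearman by default) and
the dispersion-bias slope of adjusted phenotype on GEBV (1 = unbiased,
<1 = GEBV differences over-dispersed).

Every cell's randomness derives from the master seed through a documented
counter scheme (SeedSequence spawn keys), so any single
(replicate, fold, panel) cell can be re-run independently and must
reproduce its record bit-identically — see :func:`run_cv_cell`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .gblup import GBLUPFit, backsolve_snp_effects, orient_dosages, predict_gebv, snp_pvalues, solve_mme
from .genotypes import MISSING, GenotypeMatrix, align_phenotypes
from .grm import allele_frequencies, regularize_grm, vanraden_grm
from .mas import mas_fit, mas_predict
from .panels import DEFAULT_PANEL_SIZES, rank_snps, sample_random_panel, take_top
from .reml import VarianceComponents, design_matrix, reml_fit

RECORD_COLUMNS = [
    "trait", "cohort", "strategy", "size", "size_realized", "replicate",
    "fold", "random_rep", "accuracy", "slope", "n_validated", "h2_used", "flag",
]


# ---------------------------------------------------------------------------
# Folds and phenotype adjustment
# ---------------------------------------------------------------------------

def make_folds(pheno: pd.DataFrame, n_folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Random folds stratified by contemporary group.

    Within each CG animals are shuffled and dealt round-robin to folds
    (rotating the starting fold across CGs), so each CG's animals spread
    over folds as evenly as counts allow (max-min per-CG load <= 1).
    Returns a DataFrame (animal_id, fold) with folds in 1..n_folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = pheno.groupby("cg")["animal_id"].count()
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"contemporary groups below the retained minimum of 5: {small}")
    rng = np.random.default_rng(seed)
    assign = {}
    for g_i, (cg, grp) in enumerate(sorted(pheno.groupby("cg"), key=lambda t: str(t[0]))):
        ids = grp["animal_id"].to_numpy().copy()
        rng.shuffle(ids)
        start = g_i % n_folds
        for j, a in enumerate(ids):
            assign[a] = 1 + (start + j) % n_folds
    return pd.DataFrame(
        {"animal_id": pheno["animal_id"], "fold": [assign[a] for a in pheno["animal_id"]]}
    )


def adjust_phenotypes(pheno: pd.DataFrame, trait: str, factors: list[str]) -> pd.DataFrame:
    """OLS residuals of the trait on the named factors (dummy coding plus
    intercept). A factor level with a single record forces its residual to
    zero; such records are flagged. Returns (animal_id, adjusted, flagged)."""
    rows = pheno.dropna(subset=[trait])
    y = rows[trait].to_numpy(dtype=np.float64)
    blocks = [np.ones((len(rows), 1))]
    flagged = np.zeros(len(rows), dtype=bool)
    for f in factors:
        vals = rows[f].astype(str)
        counts = vals.value_counts()
        singles = set(counts[counts == 1].index)
        if singles:
            flagged |= vals.isin(singles).to_numpy()
            warnings.warn(f"factor {f!r}: single-record level(s) {sorted(singles)[:5]}")
        blocks.append(design_matrix(vals.to_numpy(), n=len(rows))[:, 1:])
    X = np.hstack(blocks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.DataFrame(
        {"animal_id": rows["animal_id"].to_numpy(), "adjusted": y - X @ beta, "flagged": flagged}
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(gebv, y_adj, h2: float, method: str = "spearman") -> float:
    """cor(GEBV, y_adj) / sqrt(h2); |accuracy| may exceed 1 at finite n and
    is reported unclipped. Raises on constant inputs (undefined, not 0)."""
    gebv = np.asarray(gebv, dtype=np.float64)
    y_adj = np.asarray(y_adj, dtype=np.float64)
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    if gebv.size != y_adj.size or gebv.size < 3:
        raise ValueError("need >= 3 paired records")
    if np.ptp(gebv) == 0 or np.ptp(y_adj) == 0:
        raise ValueError("constant GEBV or adjusted phenotype: accuracy undefined")
    if method == "spearman":
        r = float(spearmanr(gebv, y_adj).statistic)
    elif method == "pearson":
        r = float(np.corrcoef(gebv, y_adj)[0, 1])
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return r / float(np.sqrt(h2))


def bias_slope(gebv, y_adj) -> float:
    """OLS slope (with intercept) of adjusted phenotype on GEBV."""
    gebv = np.asarray(gebv, dtype=np.float64)
    y_adj = np.asarray(y_adj, dtype=np.float64)
    if gebv.size != y_adj.size or gebv.size < 3:
        raise ValueError("need >= 3 records")
    v = np.var(gebv)
    if v == 0:
        raise ValueError("zero-variance GEBV")
    return float(np.cov(gebv, y_adj, ddof=1)[0, 1] / np.var(gebv, ddof=1))


# ---------------------------------------------------------------------------
# Shared training machinery
# ---------------------------------------------------------------------------

@dataclass
class FoldArtifacts:
    """Everything estimated on one training split (test data never enters)."""

    vc: VarianceComponents
    freqs: pd.Series  # training allele frequencies indexed by snp_id
    fit: GBLUPFit
    ranking: pd.DataFrame | None
    train_idx: np.ndarray
    X: np.ndarray
    y: np.ndarray


def _seed_int(master: int, *key: int) -> int:
    """Derived child seed (< 2^31) under the documented counter scheme."""
    return int(np.random.SeedSequence(int(master), spawn_key=tuple(int(k) for k in key)).generate_state(1)[0] >> 1)


def _fit_training(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    train_idx: np.ndarray,
    blend: float,
    with_gwas: bool = True,
) -> FoldArtifacts:
    G_tr = G.subset(rows=train_idx)
    rows = pheno.iloc[train_idx]
    y = rows[trait].to_numpy(dtype=np.float64)
    X = design_matrix(rows["cg"].to_numpy(), n=len(rows))
    freqs = allele_frequencies(G_tr)
    Gm = regularize_grm(vanraden_grm(G_tr, freqs), blend)
    vc = reml_fit(y, X, Gm)
    fit = solve_mme(y, X, Gm, vc)
    ranking = None
    if with_gwas:
        backsolve_snp_effects(fit, G_tr, Gm)
        snp_pvalues(fit, G_tr, Gm, vc)
        table = fit.solutions_table(G_tr.snp_map)
        ranking = rank_snps(table[["snp_id", "chrom", "pos", "neglog10p"]])
    return FoldArtifacts(
        vc=vc, freqs=pd.Series(freqs, index=G_tr.snp_map["snp_id"].to_numpy()),
        fit=fit, ranking=ranking, train_idx=train_idx, X=X, y=y,
    )


def _eval_panel(
    G: GenotypeMatrix,
    art: FoldArtifacts,
    test_idx: np.ndarray,
    panel_ids: np.ndarray,
    y_adj: pd.Series,
    blend: float,
    method: str = "spearman",
) -> dict:
    """Refit SNP effects on the training split for one panel and score the
    held-out animals. Panel SNPs monomorphic in training are dropped (with
    a warning); the realized panel size is recorded."""
    idx = pd.Index(G.snp_map["snp_id"])
    locs = np.sort(idx.get_indexer(panel_ids))  # genomic order
    p_panel = art.freqs.to_numpy()[locs]
    poly = (p_panel > 0.0) & (p_panel < 1.0)
    if not poly.all():
        warnings.warn(f"{int((~poly).sum())} panel SNP(s) monomorphic in training; dropped")
    locs = locs[poly]
    p_panel = p_panel[poly]
    if locs.size == 0:
        raise ValueError("no polymorphic panel SNPs left in training")

    G_tr = G.subset(rows=art.train_idx, cols=locs)
    Gm = regularize_grm(vanraden_grm(G_tr, p_panel), blend)
    fit = solve_mme(art.y, art.X, Gm, art.vc)
    ahat = backsolve_snp_effects(fit, G_tr, Gm)

    G_te = G.subset(rows=test_idx, cols=locs)
    gebv = predict_gebv(ahat, p_panel, G_te)
    ya = y_adj.loc[list(G_te.animal_ids)].to_numpy()
    rec = {"size_realized": int(locs.size), "n_validated": int(test_idx.size), "h2_used": art.vc.h2}
    rec.update(_metrics(gebv, ya, art.vc.h2, method))
    return rec


def _metrics(gebv, ya, h2, method) -> dict:
    """Accuracy and slope, each failing independently (an h2 boundary
    estimate invalidates the accuracy scale but not the slope)."""
    out = {"accuracy": np.nan, "slope": np.nan, "flag": ""}
    try:
        out["slope"] = bias_slope(gebv, ya)
    except ValueError as exc:
        out["flag"] = str(exc)
    try:
        out["accuracy"] = accuracy(gebv, ya, h2, method=method)
    except ValueError as exc:
        out["flag"] = (out["flag"] + "; " + str(exc)).strip("; ")
    return out


def _panel_plan(m: int, sizes, random_sizes, n_random_reps: int):
    plan = [("full", m, None)]
    for k in sizes:
        if k <= m:
            plan.append(("top", int(k), None))
    for k in random_sizes:
        if k <= m:
            for r in range(n_random_reps):
                plan.append(("random", int(k), r))
    return plan


def _panel_ids(strategy, size, random_rep, art: FoldArtifacts, rand_base: int):
    all_ids = art.freqs.index.to_numpy()
    if strategy == "full":
        return all_ids
    if strategy == "top":
        return take_top(art.ranking, size)
    if strategy == "random":
        return sample_random_panel(all_ids, size, seed=rand_base, replicate=random_rep)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Cross-validation experiment
# ---------------------------------------------------------------------------

def run_cv_experiment(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    sizes=DEFAULT_PANEL_SIZES,
    n_folds: int = 10,
    n_replicates: int = 10,
    n_random_reps: int = 10,
    random_sizes=None,
    blend: float = 0.01,
    seed: int = 0,
    adjust_scope: str = "population",
    method: str = "spearman",
    return_rankings: bool = False,
):
    """Replicated, CG-stratified k-fold cross-validation over SNP panels.

    Per replicate x fold: variance components and the GWAS ranking are
    estimated on the training folds only; for each panel (full, each
    top-k, each random-k x ``n_random_reps``) SNP effects are refit on the
    training folds and GEBVs predicted for the held-out fold. Accuracy
    uses the training-fold h2 and CG-adjusted phenotypes.
    """
    G, pheno = align_phenotypes(G, pheno, trait)
    m = G.n_snps
    if random_sizes is None:
        random_sizes = [k for k in sizes if k < m]
    plan = _panel_plan(m, sizes, random_sizes, n_random_reps)
    if adjust_scope == "population":
        adj = adjust_phenotypes(pheno, trait, ["cg"]).set_index("animal_id")["adjusted"]
    elif adjust_scope != "per_fold":
        raise ValueError("adjust_scope must be 'population' or 'per_fold'")

    records = []
    rankings = {}
    for rep in range(1, n_replicates + 1):
        folds = make_folds(pheno, n_folds, seed=_seed_int(seed, 1, rep))
        for fold in range(1, n_folds + 1):
            test_mask = (folds["fold"] == fold).to_numpy()
            train_idx = np.nonzero(~test_mask)[0]
            test_idx = np.nonzero(test_mask)[0]
            art = _fit_training(G, pheno, trait, train_idx, blend)
            rankings[(rep, fold)] = art.ranking
            if adjust_scope == "per_fold":
                adj = _per_fold_adjust(pheno, trait, train_idx)
            rand_base = _seed_int(seed, 2, rep, fold)
            for strategy, size, rr in plan:
                ids = _panel_ids(strategy, size, rr, art, rand_base)
                rec = _eval_panel(G, art, test_idx, ids, adj, blend, method)
                rec.update(
                    trait=trait, cohort="cv", strategy=strategy, size=size,
                    replicate=rep, fold=fold, random_rep=rr,
                )
                records.append(rec)
    table = pd.DataFrame(records)[RECORD_COLUMNS]
    return (table, rankings) if return_rankings else table


def _per_fold_adjust(pheno, trait, train_idx):
    """CG solutions fitted on the training folds, applied to everyone."""
    rows = pheno
    X = design_matrix(rows["cg"].to_numpy(), n=len(rows))
    beta, *_ = np.linalg.lstsq(
        X[train_idx], rows[trait].to_numpy(dtype=np.float64)[train_idx], rcond=None
    )
    resid = rows[trait].to_numpy(dtype=np.float64) - X @ beta
    return pd.Series(resid, index=rows["animal_id"].to_numpy())


def run_cv_cell(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    seed: int,
    replicate: int,
    fold: int,
    strategy: str,
    size: int | None = None,
    random_rep: int | None = None,
    n_folds: int = 10,
    blend: float = 0.01,
    adjust_scope: str = "population",
    method: str = "spearman",
) -> dict:
    """Recompute a single (replicate, fold, panel) record from the master
    seed; bit-identical to the corresponding row of
    :func:`run_cv_experiment` with the same configuration."""
    G, pheno = align_phenotypes(G, pheno, trait)
    folds = make_folds(pheno, n_folds, seed=_seed_int(seed, 1, replicate))
    test_mask = (folds["fold"] == fold).to_numpy()
    train_idx = np.nonzero(~test_mask)[0]
    test_idx = np.nonzero(test_mask)[0]
    art = _fit_training(G, pheno, trait, train_idx, blend, with_gwas=strategy == "top")
    if adjust_scope == "population":
        adj = adjust_phenotypes(pheno, trait, ["cg"]).set_index("animal_id")["adjusted"]
    else:
        adj = _per_fold_adjust(pheno, trait, train_idx)
    if strategy == "full":
        size = G.n_snps
    rand_base = _seed_int(seed, 2, replicate, fold)
    ids = _panel_ids(strategy, size, random_rep, art, rand_base)
    rec = _eval_panel(G, art, test_idx, ids, adj, blend, method)
    rec.update(
        trait=trait, cohort="cv", strategy=strategy, size=size,
        replicate=replicate, fold=fold, random_rep=random_rep,
    )
    return rec


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

def run_external_validation(
    G_train: GenotypeMatrix,
    pheno_train: pd.DataFrame,
    trait: str,
    G_external: GenotypeMatrix,
    pheno_external: pd.DataFrame,
    sizes=DEFAULT_PANEL_SIZES,
    n_random_reps: int = 10,
    random_sizes=None,
    blend: float = 0.01,
    seed: int = 0,
    method: str = "spearman",
) -> pd.DataFrame:
    """Train on the entire CV population, predict an independent cohort.

    One REML + GWAS on the full training data; panels as in CV; external
    GEBVs use TRAINING allele frequencies; accuracy uses the training h2
    and year-adjusted external phenotypes.
    """
    G_train, pheno_train = align_phenotypes(G_train, pheno_train, trait)
    G_ext, pheno_ext = align_phenotypes(G_external, pheno_external, trait)
    overlap = set(G_train.animal_ids) & set(G_ext.animal_ids)
    if overlap:
        raise ValueError(f"animals duplicated across cohorts: {sorted(overlap)[:5]}")
    m = G_train.n_snps
    if random_sizes is None:
        random_sizes = [k for k in sizes if k < m]
    plan = _panel_plan(m, sizes, random_sizes, n_random_reps)

    train_idx = np.arange(G_train.n_animals)
    art = _fit_training(G_train, pheno_train, trait, train_idx, blend)
    adj = adjust_phenotypes(pheno_ext, trait, ["year"]).set_index("animal_id")["adjusted"]

    panel_map = G_train.snp_map.set_index("snp_id")
    rand_base = _seed_int(seed, 3)
    records = []
    for strategy, size, rr in plan:
        ids = _panel_ids(strategy, size, rr, art, rand_base)
        locs_tr = np.sort(pd.Index(G_train.snp_map["snp_id"]).get_indexer(ids))
        ids = G_train.snp_map["snp_id"].to_numpy()[locs_tr]
        p_panel = art.freqs.to_numpy()[locs_tr]
        poly = (p_panel > 0) & (p_panel < 1)
        ids, p_panel, locs_tr = ids[poly], p_panel[poly], locs_tr[poly]
        G_tr_p = G_train.subset(cols=locs_tr)
        Gm = regularize_grm(vanraden_grm(G_tr_p, p_panel), blend)
        fit = solve_mme(art.y, art.X, Gm, art.vc)
        ahat = backsolve_snp_effects(fit, G_tr_p, Gm)

        panel_df = panel_map.loc[ids].reset_index()[["snp_id", "a1", "a2"]]
        gebv = predict_gebv(ahat, p_panel, G_ext, panel=panel_df)
        ya = adj.loc[list(G_ext.animal_ids)].to_numpy()
        rec = {
            "trait": trait, "cohort": "external", "strategy": strategy, "size": size,
            "size_realized": int(ids.size), "replicate": 1, "fold": None, "random_rep": rr,
            "n_validated": int(G_ext.n_animals), "h2_used": art.vc.h2,
        }
        rec.update(_metrics(gebv, ya, art.vc.h2, method))
        records.append(rec)
    return pd.DataFrame(records)[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# Marker-assisted comparator
# ---------------------------------------------------------------------------

def run_mas_experiment(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    G_external: GenotypeMatrix | None = None,
    pheno_external: pd.DataFrame | None = None,
    n_folds: int = 10,
    n_replicates: int = 10,
    blend: float = 0.01,
    seed: int = 0,
    adjust_scope: str = "population",
    method: str = "spearman",
) -> pd.DataFrame:
    """Single-marker prediction using the top GWAS SNP per training fold.

    Per fold the most significant training-GWAS SNP enters an OLS model
    (CG dummies + dosage); the held-out fold is predicted as g x dosage.
    For the external cohort the unique top SNPs pooled across folds are
    refit on the entire CV population and applied to the external animals.
    """
    G, pheno = align_phenotypes(G, pheno, trait)
    adj = adjust_phenotypes(pheno, trait, ["cg"]).set_index("animal_id")["adjusted"]
    snp_idx = pd.Index(G.snp_map["snp_id"])

    records = []
    top_snps = []
    for rep in range(1, n_replicates + 1):
        folds = make_folds(pheno, n_folds, seed=_seed_int(seed, 1, rep))
        for fold in range(1, n_folds + 1):
            test_mask = (folds["fold"] == fold).to_numpy()
            train_idx = np.nonzero(~test_mask)[0]
            test_idx = np.nonzero(test_mask)[0]
            art = _fit_training(G, pheno, trait, train_idx, blend)
            top_id = art.ranking["snp_id"].iloc[0]
            top_snps.append(top_id)
            j = int(snp_idx.get_loc(top_id))
            rows_tr = pheno.iloc[train_idx]
            rec = {
                "trait": trait, "cohort": "cv", "strategy": "mas", "size": 1,
                "size_realized": 1, "replicate": rep, "fold": fold, "random_rep": None,
                "n_validated": int(test_idx.size), "h2_used": art.vc.h2,
            }
            try:
                model = mas_fit(
                    art.y, rows_tr["cg"].to_numpy(), G.dosages[train_idx, j], snp_id=top_id
                )
                pred = mas_predict(model, G.dosages[test_idx, j])
                ya = adj.loc[list(G.animal_ids[test_idx])].to_numpy()
                rec.update(_metrics(pred, ya, art.vc.h2, method))
            except ValueError as exc:
                rec.update(accuracy=np.nan, slope=np.nan, flag=str(exc))
            records.append(rec)

    if G_external is not None:
        G_ext, pheno_ext = align_phenotypes(G_external, pheno_external, trait)
        adj_ext = adjust_phenotypes(pheno_ext, trait, ["year"]).set_index("animal_id")["adjusted"]
        ya = adj_ext.loc[list(G_ext.animal_ids)].to_numpy()
        all_idx = np.arange(G.n_animals)
        art_full = _fit_training(G, pheno, trait, all_idx, blend, with_gwas=False)
        ext_idx = pd.Index(G_ext.snp_map["snp_id"])
        for snp in sorted(set(top_snps)):
            j = int(snp_idx.get_loc(snp))
            rec = {
                "trait": trait, "cohort": "external", "strategy": "mas", "size": 1,
                "size_realized": 1, "replicate": 1, "fold": None, "random_rep": None,
                "n_validated": int(G_ext.n_animals), "h2_used": art_full.vc.h2,
            }
            try:
                model = mas_fit(art_full.y, pheno["cg"].to_numpy(), G.dosages[:, j], snp_id=snp)
                je = int(ext_idx.get_loc(snp))
                dos_ext = G_ext.dosages[:, je].astype(np.float64)
                row_tr = G.snp_map.iloc[j]
                row_ex = G_ext.snp_map.iloc[je]
                if (row_ex["a1"], row_ex["a2"]) == (row_tr["a2"], row_tr["a1"]):
                    obs = dos_ext != MISSING
                    dos_ext[obs] = 2 - dos_ext[obs]
                elif (row_ex["a1"], row_ex["a2"]) != (row_tr["a1"], row_tr["a2"]):
                    raise ValueError(f"allele mismatch for {snp}")
                pred = mas_predict(model, dos_ext)
                rec.update(_metrics(pred, ya, art_full.vc.h2, method))
            except (ValueError, KeyError) as exc:
                rec.update(accuracy=np.nan, slope=np.nan, flag=str(exc))
            records.append(rec)
    return pd.DataFrame(records)[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# Aggregation and reporting
# ---------------------------------------------------------------------------

def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of accuracy and slope per (trait, cohort, strategy, size);
    the SE is across all cells (replicates x folds x random draws)."""
    def _se(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    g = records.groupby(["trait", "cohort", "strategy", "size"], dropna=False)
    out = g.agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_se=("accuracy", _se),
        slope_mean=("slope", "mean"),
        slope_se=("slope", _se),
        n_cells=("accuracy", "count"),
    ).reset_index()
    return out.sort_values(["trait", "cohort", "strategy", "size"]).reset_index(drop=True)


def plot_summary(summary: pd.DataFrame, path, metric: str = "accuracy_mean") -> None:
    """Accuracy (or slope) versus panel size, one panel per trait/cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos = summary[["trait", "cohort"]].drop_duplicates().to_records(index=False)
    fig, axes = plt.subplots(1, len(combos), figsize=(5 * len(combos), 4), squeeze=False)
    for ax, (trait, cohort) in zip(axes[0], combos):
        sub = summary[(summary["trait"] == trait) & (summary["cohort"] == cohort)]
        for strategy, style in (("top", "o-g"), ("random", "s-r")):
            s = sub[sub["strategy"] == strategy].sort_values("size")
            if len(s):
                ax.plot(s["size"], s[metric], style, label=strategy)
        full = sub[sub["strategy"] == "full"]
        if len(full):
            ax.scatter(full["size"], full[metric], c="b", zorder=3, label="full")
        ax.set_xscale("log")
        ax.set_xlabel("panel size")
        ax.set_ylabel(metric)
        ax.set_title(f"{trait} ({cohort})")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
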