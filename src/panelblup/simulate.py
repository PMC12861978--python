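"""Synthetic admixed-population generator for genomic-prediction studies.

Emulates a composite-breed training population with a narrow admixture
spectrum (a Brangus-like cohort, ~60-80% of ancestry from breed A) and a
broader-ancestry external cohort, genotyped on a shared SNP panel, with
one or more traits of contrasting architecture:

* ``major_qtl`` — a single large-effect locus plus a polygenic background;
* ``polygenic`` — many small effects and no major locus.

Breed allele frequencies follow the Balding-Nichols construction: for
each SNP an ancestral frequency p0 ~ U(0.05, 0.95) and two breed
frequencies drawn from Beta(p0(1-F)/F, (1-p0)(1-F)/F) at differentiation
F. Individual genotypes are Binomial(2, alpha p_A + (1-alpha) p_B) given
the animal's admixture proportion alpha; the admixture spectrum induces
genome-wide correlation (admixture LD) between markers, which is what
makes GWAS-ranked panels redundant near a QTL.

All true values (breeding values, causal effects, group effects, realized
heritability) are retained for recovery testing.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, write_phenotypes, write_plink


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait.

    ``qtl_variance_fraction`` is the share of total genetic variance carried
    by the single major QTL (0 for polygenic traits); ``n_causal`` counts
    the background causal SNPs.
    """

    name: str
    h2_target: float
    architecture: str  # "major_qtl" | "polygenic"
    qtl_variance_fraction: float = 0.0
    n_causal: int = 500

    def __post_init__(self):
        if not 0.0 <= self.h2_target < 1.0:
            raise ValueError("h2_target must be in [0, 1)")
        if self.architecture not in ("major_qtl", "polygenic"):
            raise ValueError("architecture must be 'major_qtl' or 'polygenic'")
        if not 0.0 <= self.qtl_variance_fraction < 1.0:
            raise ValueError("qtl_variance_fraction must be in [0, 1)")
        if self.architecture == "polygenic" and self.qtl_variance_fraction != 0.0:
            raise ValueError("polygenic architecture implies qtl_variance_fraction = 0")


def major_qtl_trait(
    name: str = "wbsf_like",
    h2: float = 0.34,
    qtl_variance_fraction: float = 0.30,
    n_causal: int = 300,
) -> TraitSpec:
    """Tenderness-like trait: moderate h2 with one large-effect QTL."""
    return TraitSpec(name, h2, "major_qtl", qtl_variance_fraction, n_causal)


def polygenic_trait(name: str = "marb_like", h2: float = 0.52, n_causal: int = 500) -> TraitSpec:
    """Marbling-like trait: higher h2, fully polygenic."""
    return TraitSpec(name, h2, "polygenic", 0.0, n_causal)


@dataclass(frozen=True)
class SimConfig:
    n_train: int = 1000
    n_external: int = 300
    m_snps: int = 5000
    n_chromosomes: int = 10
    fst: float = 0.2
    train_ancestry: tuple[float, float] = (0.6, 0.8)
    external_ancestry: tuple[float, float] = (0.0, 1.0)
    n_cg: int = 32
    cg_sd: float = 0.5  # SD of group effects, in phenotypic-SD units
    n_years: int = 4  # external-cohort year factor
    traits: tuple[TraitSpec, ...] = (major_qtl_trait(), polygenic_trait())
    missing_rate: float = 0.0
    ld_flip: bool = False  # major-QTL tagging phase does not transfer externally
    marker_ld_train: float = 0.9
    marker_ld_external: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_train", "n_external", "m_snps", "n_chromosomes", "n_cg", "n_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        for rng_name in ("train_ancestry", "external_ancestry"):
            lo, hi = getattr(self, rng_name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{rng_name} must be an ordered range within [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = [dataclasses.asdict(t) for t in self.traits]
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SimTruth:
    trait: str
    tbv: np.ndarray  # training-cohort true breeding values
    causal: pd.DataFrame  # snp_id, effect (phenotypic-SD units per allele)
    qtl_snp_id: str | None
    qtl_effect: float
    qtl_hidden: bool  # effect sits on an ungenotyped locus tagged by qtl_snp_id
    cg_effects: dict
    realized_h2: float
    sigma_e: float
    intercept: float
    tbv_external: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Founders and genotypes
# ---------------------------------------------------------------------------

def simulate_founder_frequencies(m: int, fst: float, seed) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols breed frequencies for two divergent founder breeds.

    p0 ~ U(0.05, 0.95); p_A, p_B ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=m)
    c = (1.0 - fst) / fst
    eps = 1e-9
    p_a = np.clip(rng.beta(p0 * c, (1.0 - p0) * c), eps, 1.0 - eps)
    p_b = np.clip(rng.beta(p0 * c, (1.0 - p0) * c), eps, 1.0 - eps)
    return p_a, p_b


def _snp_map(m: int, n_chromosomes: int) -> pd.DataFrame:
    width = len(str(m))
    per = np.full(n_chromosomes, m // n_chromosomes)
    per[: m % n_chromosomes] += 1
    chrom = np.repeat([str(c + 1) for c in range(n_chromosomes)], per)
    pos = np.concatenate([10_000 * (np.arange(k) + 1) for k in per])
    return pd.DataFrame(
        {
            "snp_id": [f"snp{str(j).zfill(width)}" for j in range(m)],
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "a1": "A",
            "a2": "B",
        }
    )


def simulate_genotypes(
    freqs: tuple[np.ndarray, np.ndarray],
    config: SimConfig,
    cohort: str,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw an admixed cohort: alpha ~ U(cohort range) per animal and
    dosage ~ Binomial(2, alpha p_A + (1-alpha) p_B) per SNP."""
    p_a, p_b = freqs
    if cohort == "train":
        lo, hi = config.train_ancestry
        n, prefix, key = config.n_train, "tr", 1
    elif cohort == "external":
        lo, hi = config.external_ancestry
        n, prefix, key = config.n_external, "ex", 2
    else:
        raise ValueError("cohort must be 'train' or 'external'")
    if hi < lo:
        raise ValueError("empty cohort ancestry range")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))
    alpha = rng.uniform(lo, hi, size=n)
    P = alpha[:, None] * p_a[None, :] + (1.0 - alpha[:, None]) * p_b[None, :]
    dos = rng.binomial(2, P).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = MISSING
    width = len(str(n))
    ids = np.array([f"{prefix}{str(i).zfill(width)}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dos, _snp_map(config.m_snps, config.n_chromosomes), ids), alpha


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _cg_blocks(n: int, n_groups: int, prefix: str = "cg") -> np.ndarray:
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    if sizes.min() < 5:
        raise ValueError(
            f"contemporary group of size {int(sizes.min())} < 5; "
            "reduce n_cg or increase the cohort size"
        )
    width = len(str(n_groups))
    labels = [f"{prefix}{str(g + 1).zfill(width)}" for g in range(n_groups)]
    return np.repeat(labels, sizes)


def simulate_trait(
    G: GenotypeMatrix,
    spec: TraitSpec,
    n_cg: int,
    cg_sd: float,
    seed,
    qtl_dosage: np.ndarray | None = None,
    qtl_snp_id: str | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one trait on a genotyped cohort.

    Background effects are iid normal on ``n_causal`` random SNPs. For a
    major-QTL trait one locus (sample MAF >= 0.15) receives an effect sized
    so its variance contribution is ``qtl_variance_fraction`` of the total
    genetic variance; pass ``qtl_dosage`` to attach the effect to an
    external (possibly ungenotyped) locus instead. Environmental noise is
    calibrated on the REALIZED genetic variance so that
    Var(g)/(Var(g)+Var(e)) targets ``h2_target``; effects are rescaled to
    unit phenotypic variance (excluding group effects), so ``cg_sd`` reads
    in phenotypic-SD units. Contemporary groups are contiguous blocks of
    roughly equal size (each >= 5 animals) with N(0, cg_sd^2) effects.
    """
    rng = np.random.default_rng(seed)
    n, m = G.dosages.shape
    n_extra = 1 if spec.architecture == "major_qtl" else 0
    if spec.n_causal + n_extra > m:
        raise ValueError("n_causal (+ major QTL) exceeds the SNP count")

    dos = G.dosages.astype(np.float64)
    dos[G.dosages == MISSING] = np.nan
    freq = np.nanmean(dos, axis=0) / 2.0
    dos = np.where(np.isnan(dos), 2.0 * freq[None, :], dos)

    intercept = 10.0

    # --- major QTL locus ---------------------------------------------------
    qtl_id = None
    qtl_hidden = False
    x_q = None
    if spec.architecture == "major_qtl":
        if qtl_dosage is not None:
            x_q = np.asarray(qtl_dosage, dtype=np.float64)
            qtl_id = qtl_snp_id
            qtl_hidden = True
        else:
            maf = np.minimum(freq, 1.0 - freq)
            eligible = np.nonzero(maf >= 0.15)[0]
            if eligible.size == 0:
                raise ValueError("no SNP with MAF >= 0.15 available for the major QTL")
            j_q = int(rng.choice(eligible))
            x_q = dos[:, j_q]
            qtl_id = G.snp_map["snp_id"].iloc[j_q]

    # --- background effects ------------------------------------------------
    exclude = {qtl_id} if (qtl_id and not qtl_hidden) else set()
    candidates = np.array([j for j in range(m) if G.snp_map["snp_id"].iloc[j] not in exclude])
    causal_idx = np.sort(rng.choice(candidates, size=spec.n_causal, replace=False))
    beta = rng.standard_normal(spec.n_causal)

    h2 = spec.h2_target
    if h2 == 0.0:
        beta = np.zeros_like(beta)
        qtl_effect = 0.0
        g = np.zeros(n)
        sigma_e = 1.0
    else:
        g_bg = dos[:, causal_idx] @ beta
        vg_bg = float(np.var(g_bg))
        qtl_effect = 0.0
        if spec.architecture == "major_qtl" and spec.qtl_variance_fraction > 0:
            f = spec.qtl_variance_fraction
            var_q_target = vg_bg * f / (1.0 - f)
            vx = float(np.var(x_q))
            if vx <= 0:
                raise ValueError("major-QTL locus is monomorphic in this cohort")
            qtl_effect = float(rng.choice([-1.0, 1.0])) * np.sqrt(var_q_target / vx)
            g = g_bg + qtl_effect * x_q
        else:
            g = g_bg
        vg = float(np.var(g))
        sigma_e = float(np.sqrt(vg * (1.0 - h2) / h2))
        # rescale so phenotypic variance (g + e, excluding CG) is ~1
        scale = np.sqrt(vg / h2)
        beta = beta / scale
        qtl_effect = qtl_effect / scale
        g = g / scale
        sigma_e = sigma_e / scale

    e = rng.normal(0.0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
    cg = _cg_blocks(n, n_cg)
    levels = list(dict.fromkeys(cg))
    cg_eff = {lev: rng.normal(0.0, cg_sd) for lev in levels}
    y = intercept + np.array([cg_eff[c] for c in cg]) + g + e

    var_g, var_e = float(np.var(g)), float(np.var(e))
    realized_h2 = var_g / (var_g + var_e) if (var_g + var_e) > 0 else 0.0

    pheno = pd.DataFrame({"animal_id": G.animal_ids, "cg": cg, spec.name: y})
    causal = pd.DataFrame(
        {"snp_id": G.snp_map["snp_id"].iloc[causal_idx].to_numpy(), "effect": beta}
    )
    truth = SimTruth(
        trait=spec.name,
        tbv=g,
        causal=causal,
        qtl_snp_id=qtl_id,
        qtl_effect=float(qtl_effect),
        qtl_hidden=qtl_hidden,
        cg_effects=cg_eff,
        realized_h2=realized_h2,
        sigma_e=sigma_e,
        intercept=intercept,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# Whole-study datasets
# ---------------------------------------------------------------------------

@dataclass
class SimData:
    config: SimConfig
    genotypes_train: GenotypeMatrix
    genotypes_external: GenotypeMatrix
    ancestry_train: np.ndarray
    ancestry_external: np.ndarray
    pheno_train: pd.DataFrame
    pheno_external: pd.DataFrame
    truths: dict
    founder_freqs: tuple[np.ndarray, np.ndarray]


def _linked_pair(rng, p_site, rho, n):
    """Gamete-level tagging: causal allele a ~ Bern(p); the tag allele
    copies a with probability rho, otherwise is an independent Bern(p).
    Returns (causal dosage, tag dosage)."""
    a = rng.random((n, 2)) < p_site[:, None]
    copy = rng.random((n, 2)) < rho
    indep = rng.random((n, 2)) < p_site[:, None]
    b = np.where(copy, a, indep)
    return a.sum(axis=1).astype(np.float64), b.sum(axis=1).astype(np.int8)


def simulate_dataset(config: SimConfig) -> SimData:
    """Generate the full two-cohort study: shared founder frequencies,
    train + external genotypes, and every trait in ``config.traits``
    applied consistently to both cohorts.

    With ``ld_flip`` the major QTL of each major-QTL trait is a hidden
    (ungenotyped) causal locus tagged by one genotyped marker whose
    gamete-level phase correlation is ``marker_ld_train`` in the training
    cohort but ``marker_ld_external`` externally — the mechanism by which
    single-marker (MAS) predictions fail to transfer across populations.
    """
    ss = np.random.SeedSequence(config.seed)
    freq_seed = np.random.SeedSequence(config.seed, spawn_key=(0,))
    p_a, p_b = simulate_founder_frequencies(config.m_snps, config.fst, freq_seed)

    G_tr, alpha_tr = simulate_genotypes((p_a, p_b), config, "train")
    G_ex, alpha_ex = simulate_genotypes((p_a, p_b), config, "external")

    hidden_train = hidden_ext = None
    tag_id = None
    if config.ld_flip:
        # The tag site must be ancestry-neutral (comparable frequencies in
        # both founder breeds): the transfer failure should come from the
        # broken marker-QTL phase, not from the marker predicting ancestry.
        ok = (np.minimum(p_a, p_b) >= 0.25) & (np.maximum(p_a, p_b) <= 0.75)
        cands = np.nonzero(ok)[0]
        if cands.size == 0:
            raise ValueError("no suitable tag SNP for the linked pair")
        j_tag = int(cands[np.argmin(np.abs(p_a[cands] - p_b[cands]))])
        tag_id = G_tr.snp_map["snp_id"].iloc[j_tag]
        rng_pair = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
        p_tr = alpha_tr * p_a[j_tag] + (1.0 - alpha_tr) * p_b[j_tag]
        hidden_train, tag_tr = _linked_pair(rng_pair, p_tr, config.marker_ld_train, config.n_train)
        p_ex = alpha_ex * p_a[j_tag] + (1.0 - alpha_ex) * p_b[j_tag]
        hidden_ext, tag_ex = _linked_pair(rng_pair, p_ex, config.marker_ld_external, config.n_external)
        G_tr.dosages[:, j_tag] = tag_tr
        G_ex.dosages[:, j_tag] = tag_ex

    pheno_tr = pd.DataFrame({"animal_id": G_tr.animal_ids})
    pheno_ex = pd.DataFrame({"animal_id": G_ex.animal_ids})
    years = _cg_blocks(config.n_external, config.n_years, prefix="y")
    truths: dict[str, SimTruth] = {}
    snp_index = pd.Index(G_ex.snp_map["snp_id"])
    for t_i, spec in enumerate(config.traits):
        trait_seed = np.random.SeedSequence(config.seed, spawn_key=(10 + t_i,))
        use_hidden = config.ld_flip and spec.architecture == "major_qtl"
        ph, truth = simulate_trait(
            G_tr,
            spec,
            config.n_cg,
            config.cg_sd,
            trait_seed,
            qtl_dosage=hidden_train if use_hidden else None,
            qtl_snp_id=tag_id if use_hidden else None,
        )
        pheno_tr["cg"] = ph["cg"]
        pheno_tr[spec.name] = ph[spec.name]

        # same effects applied to the external cohort
        rng_ext = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(100 + t_i,)))
        dos_ex = G_ex.dosages.astype(np.float64)
        obs = G_ex.dosages != MISSING
        col_mean = np.where(obs, dos_ex, np.nan)
        fr = np.nanmean(col_mean, axis=0) / 2.0
        dos_ex = np.where(obs, dos_ex, 2.0 * fr[None, :])
        locs = snp_index.get_indexer(truth.causal["snp_id"])
        g_ex = dos_ex[:, locs] @ truth.causal["effect"].to_numpy()
        if spec.architecture == "major_qtl" and truth.qtl_effect != 0.0:
            if use_hidden:
                g_ex = g_ex + truth.qtl_effect * hidden_ext
            else:
                j_q = int(snp_index.get_loc(truth.qtl_snp_id))
                g_ex = g_ex + truth.qtl_effect * dos_ex[:, j_q]
        year_eff = {lev: rng_ext.normal(0.0, config.cg_sd) for lev in dict.fromkeys(years)}
        e_ex = rng_ext.normal(0.0, truth.sigma_e, size=config.n_external)
        pheno_ex["year"] = years
        pheno_ex[spec.name] = (
            truth.intercept + np.array([year_eff[yv] for yv in years]) + g_ex + e_ex
        )
        truth.tbv_external = g_ex
        truths[spec.name] = truth

    pheno_tr["year"] = "y1"
    return SimData(
        config=config,
        genotypes_train=G_tr,
        genotypes_external=G_ex,
        ancestry_train=alpha_tr,
        ancestry_external=alpha_ex,
        pheno_train=pheno_tr,
        pheno_external=pheno_ex,
        truths=truths,
        founder_freqs=(p_a, p_b),
    )


def write_run(data: SimData, outdir) -> Path:
    """Emit PLINK triples, phenotype tables and the truth/manifest files
    under a run directory; file names are deterministic from the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(data.genotypes_train, outdir / "train")
    write_plink(data.genotypes_external, outdir / "external")
    write_phenotypes(data.pheno_train, outdir / "pheno_train.tsv")
    write_phenotypes(data.pheno_external, outdir / "pheno_external.tsv")
    truth_payload = {}
    for name, t in data.truths.items():
        truth_payload[name] = {
            "tbv": dict(zip(map(str, data.genotypes_train.animal_ids), t.tbv.tolist())),
            "causal": t.causal.to_dict(orient="records"),
            "qtl_snp_id": t.qtl_snp_id,
            "qtl_effect": t.qtl_effect,
            "qtl_hidden": t.qtl_hidden,
            "cg_effects": t.cg_effects,
            "realized_h2": t.realized_h2,
            "sigma_e": t.sigma_e,
            "intercept": t.intercept,
        }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    manifest = {"config": data.config.to_dict(), "config_digest": data.config.digest()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
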