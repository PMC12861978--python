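"""GWAS-ranked top-k SNP panels and size-matched random panels.

Markers are ranked by -log10(P); ties break deterministically by
(chromosome, position, id) so rankings are reproducible across platforms.
Random panels are uniform draws without replacement from the same SNP
universe, deterministic in (seed, replicate, k).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import _chrom_key

DEFAULT_PANEL_SIZES = (50, 100, 250, 500, 1000, 5000, 20000, 50000)


def rank_snps(pvalue_table: pd.DataFrame) -> pd.DataFrame:
    """Order SNPs by descending -log10(P).

    ``pvalue_table`` needs columns snp_id, chrom, pos, neglog10p. Returns
    the same columns plus ``rank`` (1-based), sorted.
    """
    if len(pvalue_table) == 0:
        raise ValueError("empty p-value table")
    df = pvalue_table.copy()
    keys = [_chrom_key(c) for c in df["chrom"]]
    df["_ck"] = keys
    df = df.sort_values(
        by=["neglog10p", "_ck", "pos", "snp_id"],
        ascending=[False, True, True, True],
        kind="mergesort",  # stable
    ).drop(columns="_ck")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def take_top(ranking: pd.DataFrame, k: int) -> np.ndarray:
    """First k SNP ids of a ranking (ordered)."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range 1..{len(ranking)}")
    return ranking["snp_id"].to_numpy()[:k].copy()


def sample_random_panel(snp_ids, k: int, seed: int, replicate: int = 0) -> np.ndarray:
    """Uniform sample of k SNP ids without replacement; deterministic in
    (seed, replicate, k); different replicate indices are independent."""
    snp_ids = np.asarray(snp_ids, dtype=object)
    if k > snp_ids.size:
        raise ValueError(f"k={k} exceeds the {snp_ids.size} available SNPs")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(replicate), int(k))))
    idx = rng.choice(snp_ids.size, size=k, replace=False)
    return snp_ids[np.sort(idx)]


def inclusion_frequency(rankings: "list[pd.DataFrame]", bins) -> pd.DataFrame:
    """Per-SNP inclusion percentage in the top-k of each ranking.

    For every SNP and bin k: the percentage of rankings in which the SNP
    ranks within the top k, plus median/min/max -log10(P) across rankings.
    All rankings must cover the same SNP universe.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = set(rankings[0]["snp_id"])
    for r in rankings[1:]:
        if set(r["snp_id"]) != universe:
            raise ValueError("inconsistent SNP universes across rankings")
    bins = sorted(int(b) for b in bins)
    base = rankings[0].set_index("snp_id")
    n_runs = len(rankings)
    ranks = np.empty((n_runs, len(universe)), dtype=np.int64)
    neglogs = np.empty_like(ranks, dtype=np.float64)
    order = base.index
    for i, r in enumerate(rankings):
        s = r.set_index("snp_id")
        ranks[i] = s["rank"].reindex(order).to_numpy()
        neglogs[i] = s["neglog10p"].reindex(order).to_numpy()
    out = pd.DataFrame(
        {
            "snp_id": order.to_numpy(),
            "chrom": base["chrom"].to_numpy(),
            "pos": base["pos"].to_numpy(),
            "median_neglog10p": np.median(neglogs, axis=0),
            "min_neglog10p": neglogs.min(axis=0),
            "max_neglog10p": neglogs.max(axis=0),
        }
    )
    for k in bins:
        out[f"top{k}_pct"] = 100.0 * (ranks <= k).mean(axis=0)
    out = out.sort_values(
        by=[f"top{bins[0]}_pct", "median_neglog10p"], ascending=[False, False]
    ).reset_index(drop=True)
    return out
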