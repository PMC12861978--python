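"""VanRaden (method 1) genomic relationship matrix.

G = M M' / k with M the column-centered dosage matrix (x - 2p) and
k = 2 * sum_j p_j (1 - p_j). Missing dosages are imputed to 2p_j before
centering so they contribute nothing to relationships. For predicting
animals outside the training set, centering always uses TRAINING allele
frequencies: SNP effects are estimated on the training scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class GRMatrix:
    values: np.ndarray  # symmetric (n, n)
    animal_ids: np.ndarray
    scale_k: float  # 2 sum p(1-p)
    freqs: np.ndarray  # allele-1 frequencies used for centering
    blend_weight: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP allele-1 frequency: mean dosage among non-missing calls / 2."""
    d = G.dosages
    obs = d != MISSING
    calls = obs.sum(axis=0)
    if (calls == 0).any():
        bad = G.snp_ids[calls == 0]
        raise ValueError(f"all-missing SNP(s): {list(bad[:5])}")
    return np.where(obs, d, 0).sum(axis=0) / (2.0 * calls)


def centered_dosages(G: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    """M = dosages - 2p, with missing calls imputed to 2p (centered to 0)."""
    d = G.dosages.astype(np.float64)
    M = d - 2.0 * freqs[None, :]
    M[G.dosages == MISSING] = 0.0
    return M


def vanraden_scale(freqs: np.ndarray) -> float:
    return float(2.0 * np.sum(freqs * (1.0 - freqs)))


def vanraden_grm(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRMatrix:
    """VanRaden method-1 GRM; ``freqs`` defaults to frequencies computed
    from ``G`` (pass training frequencies for cross-population use)."""
    if freqs is None:
        freqs = allele_frequencies(G)
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.shape != (G.n_snps,):
        raise ValueError("freqs length must equal SNP count")
    k = vanraden_scale(freqs)
    if k <= 0.0:
        raise ValueError("k = 0: all SNPs monomorphic under the supplied frequencies")
    M = centered_dosages(G, freqs)
    values = (M @ M.T) / k
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return GRMatrix(values=values, animal_ids=G.animal_ids.copy(), scale_k=k, freqs=freqs)


def regularize_grm(Gm: GRMatrix, blend_weight: float = 0.01) -> GRMatrix:
    """Blend toward the identity: (1-w) G + w I; guarantees positive
    definiteness for the mixed-model equations and SNP-effect backsolving."""
    if not 0.0 <= blend_weight <= 0.25:
        raise ValueError("blend_weight must be in [0, 0.25]")
    n = Gm.n
    values = (1.0 - blend_weight) * Gm.values + blend_weight * np.eye(n)
    return GRMatrix(
        values=values,
        animal_ids=Gm.animal_ids.copy(),
        scale_k=Gm.scale_k,
        freqs=Gm.freqs.copy(),
        blend_weight=blend_weight,
    )


def export_grm(Gm: GRMatrix, path) -> None:
    """Text export of the lower triangle (id1, id2, value) for inspection."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i in range(Gm.n):
            for j in range(i + 1):
                fh.write(f"{Gm.animal_ids[i]}\t{Gm.animal_ids[j]}\t{Gm.values[i, j]:.6g}\n")
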