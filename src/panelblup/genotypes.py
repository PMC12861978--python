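"""Genotype containers, PLINK bed/bim/fam I/O, phenotype tables, and QC.

Dosages count copies of allele1 (the first allele column of the .bim line)
and live in {0, 1, 2, MISSING}. The missing sentinel is a reserved negative
code and is never fed to analysis matrices without imputation (the GRM
module imputes missing calls to twice the allele frequency).
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 1 two-bit codes (SNP-major): 00=hom A1, 01=missing, 10=het, 11=hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = np.zeros(3, dtype=np.uint8)
_DOSAGE_TO_CODE[2], _DOSAGE_TO_CODE[1], _DOSAGE_TO_CODE[0] = 0b00, 0b10, 0b11
_MISSING_CODE = 0b01

#: chromosome labels treated as non-autosomal under ``autosomes_only``
NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "0"}

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]


def _chrom_key(label: str):
    """Sort key: numeric chromosomes in natural order, others after."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def is_autosome(label: str) -> bool:
    s = str(label).upper()
    return s not in NON_AUTOSOMES and s.isdigit()


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with its marker map.

    Parameters
    ----------
    dosages : (n_animals, n_snps) int8 array with entries in {0,1,2,MISSING}.
    snp_map : DataFrame with columns snp_id, chrom, pos, a1, a2, sorted by
        (chromosome, base-pair position); positions are 1-based.
    animal_ids : ordered unique animal identifiers.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    animal_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match dosage rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or the missing sentinel")
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids")
        if self.snp_map["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        pos = self.snp_map["pos"].to_numpy().astype(np.int64)
        keys = [_chrom_key(c) for c in self.snp_map["chrom"].to_numpy()]
        tuples = [(k, p) for k, p in zip(keys, pos.tolist())]
        if any(tuples[i] > tuples[i + 1] for i in range(m - 1)):
            raise ValueError("snp_map must be sorted by (chromosome, position)")
        if m and (pos < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        """Row/column subset (index arrays or boolean masks); keeps map order."""
        d = self.dosages
        ids = self.animal_ids
        smap = self.snp_map
        if rows is not None:
            rows = np.asarray(rows)
            d = d[rows]
            ids = ids[rows]
        if cols is not None:
            cols = np.asarray(cols)
            d = d[:, cols]
            if cols.dtype == bool:
                smap = smap.loc[cols]
            else:
                smap = smap.iloc[cols]
        return GenotypeMatrix(d.copy(), smap.reset_index(drop=True), ids.copy())

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Subset to the given SNP ids, kept in genomic (map) order."""
        wanted = set(snp_ids)
        missing = wanted - set(self.snp_map["snp_id"])
        if missing:
            raise KeyError(f"SNP ids absent from genotype matrix: {sorted(missing)[:5]}")
        mask = self.snp_map["snp_id"].isin(wanted).to_numpy()
        return self.subset(cols=mask)


# ---------------------------------------------------------------------------
# PLINK binary triple
# ---------------------------------------------------------------------------

def _check_ids(ids) -> None:
    for i in ids:
        s = str(i)
        if not s or any(ch.isspace() for ch in s):
            raise ValueError(f"id {s!r} is empty or contains whitespace (PLINK field separator conflict)")


def write_plink(G: GenotypeMatrix, path_prefix) -> None:
    """Write a PLINK v1.00 SNP-major bed/bim/fam triple.

    ``read_plink(write_plink(G))`` is the identity on dosages and maps.
    """
    G.validate()
    _check_ids(G.animal_ids)
    _check_ids(G.snp_map["snp_id"])
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    fam = pd.DataFrame(
        {
            "fid": G.animal_ids,
            "iid": G.animal_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": G.snp_map["chrom"],
            "snp_id": G.snp_map["snp_id"],
            "cm": 0,
            "pos": G.snp_map["pos"],
            "a1": G.snp_map["a1"],
            "a2": G.snp_map["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = G.dosages.shape
    n_pad = -n % 4
    codes = np.empty((m, n + n_pad), dtype=np.uint8)
    dos = G.dosages.T  # SNP-major
    miss = dos == MISSING
    codes[:, :n] = _DOSAGE_TO_CODE[np.where(miss, 0, dos)]
    codes[:, :n][miss] = _MISSING_CODE
    codes[:, n:] = 0
    if m == 0:
        packed = np.empty((0, 0), dtype=np.uint8)
    else:
        c = codes.reshape(m, -1, 4)
        packed = (c[:, :, 0] | (c[:, :, 1] << 2) | (c[:, :, 2] << 4) | (c[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(path_prefix) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triple into a :class:`GenotypeMatrix`.

    Dosages count copies of allele1 (A1, fifth .bim column). Missing
    genotypes map to :data:`MISSING`.
    """
    prefix = Path(path_prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(prefix.with_suffix(ext))

    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    animal_ids = fam.iloc[:, 1].to_numpy(dtype=object)
    if len(set(animal_ids)) != len(animal_ids):
        raise ValueError("duplicate animal ids in .fam")

    try:
        bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=range(6))
    if bim.shape[1] != 6:
        raise ValueError(".bim must have 6 columns")
    snp_map = pd.DataFrame(
        {
            "snp_id": bim.iloc[:, 1],
            "chrom": bim.iloc[:, 0],
            "pos": bim.iloc[:, 3].astype(np.int64),
            "a1": bim.iloc[:, 4],
            "a2": bim.iloc[:, 5],
        }
    )
    if snp_map["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids in .bim")

    n, m = len(animal_ids), len(snp_map)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a PLINK v1.00 SNP-major .bed file (bad magic bytes)")
    bytes_per_snp = (n + 3) // 4
    payload = raw[3:]
    if len(payload) != bytes_per_snp * m:
        raise ValueError(
            f".bed payload size {len(payload)} does not match "
            f"{m} SNPs x {bytes_per_snp} bytes from .bim/.fam"
        )
    if m == 0:
        dosages = np.empty((n, 0), dtype=np.int8)
    else:
        data = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_snp)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = ((data[:, :, None] >> shifts) & 3).reshape(m, -1)[:, :n]
        dosages = _CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeMatrix(dosages, snp_map, animal_ids)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

class QCError(ValueError):
    pass


@dataclass
class QCReport:
    n_animals_in: int
    n_animals_out: int
    n_snps_in: int
    n_snps_out: int
    removed_animals: list = field(default_factory=list)  # (id, reason)
    removed_snps: list = field(default_factory=list)  # (id, reason)
    thresholds: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_animals_out == self.n_animals_in - len(self.removed_animals)
        assert self.n_snps_out == self.n_snps_in - len(self.removed_snps)


def apply_qc(
    G: GenotypeMatrix,
    sample_call_rate: float = 0.90,
    snp_call_rate: float = 0.90,
    maf_min: float = 0.05,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sample-then-SNP quality control.

    Samples with call rate strictly below ``sample_call_rate`` are removed
    first; SNP call rate and MAF are then computed on the retained samples.
    A SNP is removed (single primary reason, in priority order) when it is
    non-autosomal, its call rate < ``snp_call_rate``, or its MAF
    < ``maf_min``. MAF exactly at the threshold is retained ("less than").
    """
    for name, t in (("sample_call_rate", sample_call_rate), ("snp_call_rate", snp_call_rate), ("maf_min", maf_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    obs = G.dosages != MISSING
    n, m = G.dosages.shape

    removed_animals = []
    if m:
        cr_sample = obs.mean(axis=1)
    else:
        cr_sample = np.ones(n)
    keep_rows = cr_sample >= sample_call_rate
    for i in np.nonzero(~keep_rows)[0]:
        removed_animals.append((G.animal_ids[i], "sample_call_rate"))
    if not keep_rows.any():
        raise QCError("all animals removed by the sample_call_rate filter")

    d = G.dosages[keep_rows]
    obs = obs[keep_rows]
    n_kept = d.shape[0]

    removed_snps = []
    keep_cols = np.ones(m, dtype=bool)
    chroms = G.snp_map["chrom"].to_numpy()
    calls = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cr_snp = calls / n_kept
        alt = np.where(obs, d, 0).sum(axis=0)
        p = np.divide(alt, 2.0 * calls, out=np.zeros(m), where=calls > 0)
    maf = np.minimum(p, 1.0 - p)
    for j in range(m):
        if autosomes_only and not is_autosome(chroms[j]):
            reason = "non_autosomal"
        elif cr_snp[j] < snp_call_rate:
            reason = "snp_call_rate"
        elif maf[j] < maf_min:
            reason = "maf"
        else:
            continue
        keep_cols[j] = False
        removed_snps.append((G.snp_map["snp_id"].iloc[j], reason))
    if m and not keep_cols.any():
        from collections import Counter

        top = Counter(r for _, r in removed_snps).most_common(1)[0][0]
        raise QCError(f"all SNPs removed; binding filter: {top}")

    out = G.subset(rows=keep_rows, cols=keep_cols)
    report = QCReport(
        n_animals_in=n,
        n_animals_out=out.n_animals,
        n_snps_in=m,
        n_snps_out=out.n_snps,
        removed_animals=removed_animals,
        removed_snps=removed_snps,
        thresholds={
            "sample_call_rate": sample_call_rate,
            "snp_call_rate": snp_call_rate,
            "maf_min": maf_min,
            "autosomes_only": autosomes_only,
        },
    )
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited phenotype table (header: animal_id, traits, cg, year).

    Empty fields and the tokens NA/NaN are read as missing phenotypes.
    """
    df = pd.read_csv(path, sep=sep, dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise ValueError("phenotype table must have an 'animal_id' column")
    for col in ("cg", "year"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def align_phenotypes(G: GenotypeMatrix, pheno: pd.DataFrame, trait: str) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Intersect genotyped animals with animals having a non-missing trait
    record, preserving genotype order on the intersection."""
    has = pheno.dropna(subset=[trait]).set_index("animal_id")
    keep = np.array([a in has.index for a in G.animal_ids])
    if not keep.any():
        raise ValueError("no genotyped animal has a phenotype record")
    Gs = G.subset(rows=keep)
    aligned = has.loc[list(Gs.animal_ids)].reset_index()
    return Gs, aligned
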