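"""Genotype and summary-statistics file formats.

Genotypes travel as hard-call allele-count matrices (0/1/2, missing) in the
PLINK-1 binary triple (``.bed``/``.bim``/``.fam``, SNP-major).  GWAS summary
statistics travel as a tab-separated table with a fixed header
(``vid chrom pos a1 a2 beta se p freq n``).  Throughout the package the
*counted* allele — the one whose copies a dosage counts and whose effect size
``beta`` refers to — is the first allele (A1) of the bim record, the PLINK-1
convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "PlinkFormatError",
    "SumstatsFormatError",
    "VariantInfo",
    "GenotypeMatrix",
    "SummaryStats",
    "read_plink",
    "write_plink",
    "read_sumstats",
    "write_sumstats",
    "read_fam_phenotype",
    "read_phenotype_table",
]

#: Sentinel dosage for a missing hard call.  Distinct from every valid count.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK-1 codes -> dosage of allele1 (A1).
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2 (0 copies).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Malformed PLINK-1 binary input (bad magic, size mismatch, bad field)."""


class SumstatsFormatError(ValueError):
    """Malformed summary-statistics table."""


@dataclass(frozen=True)
class VariantInfo:
    """Identity and metadata of one variant.

    ``allele1`` is the counted allele (A1); ``info_score`` is the imputation
    quality in [0, 1] or ``None`` for directly genotyped (array) variants.
    """

    chrom: str
    pos: int
    vid: str
    allele1: str
    allele2: str
    info_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.vid}: position must be >= 1, got {self.pos}")
        if self.allele1 == self.allele2:
            raise ValueError(f"variant {self.vid}: alleles must differ")
        if self.info_score is not None and not (0.0 <= self.info_score <= 1.0):
            raise ValueError(f"variant {self.vid}: info_score outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of counted-allele dosages.

    ``genotypes[i, j]`` is the number of copies of ``variants[j].allele1``
    carried by ``sample_ids[i]``, one of {0, 1, 2} or :data:`MISSING`.
    """

    genotypes: np.ndarray
    variants: list[VariantInfo]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-dimensional")
        n, m = self.genotypes.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{n} genotype rows but {len(self.sample_ids)} sample ids")
        if m != len(self.variants):
            raise ValueError(f"{m} genotype columns but {len(self.variants)} variants")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        vids = [v.vid for v in self.variants]
        if len(set(vids)) != m:
            raise ValueError("variant ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or the missing sentinel")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def vid_index(self) -> dict[str, int]:
        return {v.vid: j for j, v in enumerate(self.variants)}

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def subset_variants(self, which: Sequence[int] | Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given variant indices or vids (in order)."""
        if len(which) > 0 and isinstance(which[0], str):
            idx_map = self.vid_index()
            cols = [idx_map[v] for v in which]
        else:
            cols = list(which)  # type: ignore[arg-type]
        return GenotypeMatrix(
            genotypes=self.genotypes[:, cols].copy(),
            variants=[self.variants[j] for j in cols],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            genotypes=self.genotypes[rows, :].copy(),
            variants=list(self.variants),
            sample_ids=[self.sample_ids[i] for i in rows],
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_variants), key=lambda j: (self.variants[j].chrom, self.variants[j].pos, self.variants[j].vid))
        if order == list(range(self.n_variants)):
            return self
        return self.subset_variants(order)


SUMSTATS_COLUMNS = ["vid", "chrom", "pos", "a1", "a2", "beta", "se", "p", "freq", "n"]


@dataclass
class SummaryStats:
    """Per-variant GWAS summary statistics.

    One row per variant id; ``beta`` is the estimated effect per copy of the
    counted allele ``a1``, ``freq`` its allele frequency, ``p`` the two-sided
    association p-value in (0, 1].  Extra columns (e.g. a ``flag`` for
    degenerate fits) are carried along untouched.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumstatsFormatError(f"summary statistics missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if t["vid"].duplicated().any():
            dups = t.loc[t["vid"].duplicated(), "vid"].tolist()
            raise SumstatsFormatError(f"duplicate variant ids in summary statistics: {dups[:5]}")
        p = t["p"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
            raise SumstatsFormatError("p-values must lie in (0, 1]")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def vids(self) -> list[str]:
        return self.table["vid"].tolist()

    def lookup(self, vid: str) -> pd.Series:
        row = self.table.loc[self.table["vid"] == vid]
        if row.empty:
            raise KeyError(vid)
        return row.iloc[0]

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("vid", drop=False)


# ---------------------------------------------------------------------------
# PLINK-1 binary triple
# ---------------------------------------------------------------------------


def _decode_bed_payload(payload: bytes, n_samples: int, n_variants: int) -> np.ndarray:
    """Decode an SNP-major bed payload into an (n_samples, n_variants) dosage matrix."""
    bytes_per_variant = (n_samples + 3) // 4
    expected = bytes_per_variant * n_variants
    if len(payload) != expected:
        raise PlinkFormatError(
            f"bed payload is {len(payload)} bytes but bim/fam imply {expected} "
            f"({n_variants} variants x {bytes_per_variant} bytes)"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_variants, bytes_per_variant)
    # expand each byte to 4 two-bit codes, low bits first (sample order)
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    codes = codes[:, :n_samples]
    return _CODE_TO_DOSAGE[codes].T.copy()


def _encode_bed_payload(genotypes: np.ndarray) -> bytes:
    n_samples, n_variants = genotypes.shape
    bytes_per_variant = (n_samples + 3) // 4
    codes = np.zeros((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage % 4] = code  # MISSING=-1 -> index 3
    codes[:, :n_samples] = lut[(genotypes.T % 4).astype(np.intp)]
    # unused trailing slots in the last byte are zero, per the format
    out = np.zeros((n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        out |= (codes[:, k::4].astype(np.uint16) << (2 * k)).astype(np.uint8)
    return out.tobytes()


def read_plink(path_prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK-1 ``.bed``/``.bim``/``.fam`` triple into a :class:`GenotypeMatrix`.

    The counted allele of each variant is the bim A1 allele; the bed file must
    be SNP-major (third magic byte 0x01).
    """
    prefix = os.fspath(path_prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(prefix + ext)

    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "vid": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )

    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise PlinkFormatError(
                f"{prefix}.bed does not start with the PLINK-1 SNP-major magic bytes "
                f"6c 1b 01 (got {magic.hex(' ')})"
            )
        payload = fh.read()

    genotypes = _decode_bed_payload(payload, n_samples=len(fam), n_variants=len(bim))
    variants = [
        VariantInfo(chrom=r.chrom, pos=int(r.pos), vid=r.vid, allele1=r.a1, allele2=r.a2)
        for r in bim.itertuples()
    ]
    return GenotypeMatrix(genotypes=genotypes, variants=variants, sample_ids=fam["iid"].tolist())


def write_plink(
    g: GenotypeMatrix,
    path_prefix: str | os.PathLike,
    phenotype: np.ndarray | None = None,
    trait_type: str = "binary",
) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK-1 triple.

    Variants are written sorted by (chrom, pos); an optional phenotype fills
    fam column 6 (binary traits recoded 0/1 -> 1/2, missing -> -9).
    """
    if g.n_variants == 0:
        raise ValueError("refusing to write a genotype matrix with zero variants")
    if g.n_samples == 0:
        raise ValueError("refusing to write a genotype matrix with zero samples")
    g = g.sorted_by_position()
    prefix = os.fspath(path_prefix)

    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(_encode_bed_payload(g.genotypes))

    with open(prefix + ".bim", "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\t{v.allele1}\t{v.allele2}\n")

    if phenotype is None:
        pheno_col = ["-9"] * g.n_samples
    else:
        phenotype = np.asarray(phenotype, dtype=float)
        if phenotype.shape != (g.n_samples,):
            raise ValueError("phenotype length must equal sample count")
        pheno_col = []
        for y in phenotype:
            if np.isnan(y):
                pheno_col.append("-9")
            elif trait_type == "binary":
                pheno_col.append(str(int(y) + 1))  # 0/1 -> 1/2
            else:
                pheno_col.append(repr(float(y)))
    with open(prefix + ".fam", "w") as fh:
        for iid, ph in zip(g.sample_ids, pheno_col):
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t{ph}\n")


def read_fam_phenotype(path_prefix: str | os.PathLike, trait_type: str = "binary") -> np.ndarray:
    """Phenotype from fam column 6: 1/2 recoded to 0/1 for binary traits, -9 -> NaN."""
    fam = pd.read_csv(
        os.fspath(path_prefix) + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    y = fam["pheno"].to_numpy(dtype=float)
    out = np.where(y == -9, np.nan, y)
    if trait_type == "binary":
        valid = ~np.isnan(out)
        if not np.isin(out[valid], (1.0, 2.0)).all():
            raise ValueError("binary fam phenotype must be coded 1/2 (or -9 missing)")
        out = np.where(valid, out - 1.0, np.nan)
    return out


def read_phenotype_table(path: str | os.PathLike, sample_ids: Sequence[str]) -> np.ndarray:
    """Two-column id/value table aligned to ``sample_ids`` (NaN where absent)."""
    t = pd.read_csv(path, sep="\t", header=None, names=["iid", "value"], dtype={"iid": str})
    mapping = dict(zip(t["iid"], t["value"].astype(float)))
    return np.array([mapping.get(s, np.nan) for s in sample_ids], dtype=float)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_sumstats(path: str | os.PathLike) -> SummaryStats:
    t = pd.read_csv(path, sep="\t", dtype={"vid": str, "chrom": str, "a1": str, "a2": str},
                    float_precision="round_trip")
    return SummaryStats(table=t)


def write_sumstats(s: SummaryStats, path: str | os.PathLike) -> None:
    """Write the table losslessly (floats at full round-trip precision)."""
    t = s.table.copy()
    with open(path, "w") as fh:
        fh.write("\t".join(t.columns) + "\n")
        for row in t.itertuples(index=False):
            fields = [repr(float(x)) if isinstance(x, float) else str(x) for x in row]
            fh.write("\t".join(fields) + "\n")
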