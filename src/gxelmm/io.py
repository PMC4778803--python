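"""Readers and writers for genotypes, phenotypes, exposures, kinships and results.

Supported on-disk formats
-------------------------
* genotypes: PLINK .bed/.bim/.fam triples (SNP-major) and a plain dosage
  TSV dialect (first column = sample ID, header row = variant IDs,
  missing = ``NA``);
* kinship: square TSV with an ID column/header, and the GCTA GRM dialects
  (gzipped text ``.grm.gz`` triple-column and float32 ``.grm.bin``
  lower-triangle, each with a ``.grm.id`` file);
* phenotype / exposure: two-column whitespace-delimited files
  (sample ID, value), no FID column;
* association results: the tab-delimited table written by
  :func:`write_assoc_results`.
"""

from __future__ import annotations

import gzip
import struct
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    ExposureVector,
    GenotypeMatrix,
    KinshipMatrix,
    PhenotypeVector,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_exposure",
    "write_exposure",
    "read_kinship",
    "write_kinship",
    "read_assoc_results",
    "write_assoc_results",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # magic + SNP-major flag

# 2-bit PLINK codes -> dosage of allele A1: 00 hom A1, 01 missing, 10 het,
# 11 hom A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from ``plink-bed`` or ``dosage-tsv`` files.

    For PLINK input, ``path`` may be the ``.bed`` file or the shared
    prefix of the ``.bed/.bim/.fam`` triple.
    """
    path = Path(path)
    if format == "auto":
        format = "plink-bed" if path.suffix == ".bed" or path.with_suffix(".bed").exists() else "dosage-tsv"
    if format == "plink-bed":
        return _read_plink(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", index_col=0, na_values=["NA"])
    samples = [str(s) for s in df.index]
    variant_ids = [str(v) for v in df.columns]
    dosages = df.to_numpy(dtype=float)
    ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{path}: non-{{0,1,2,NA}} dosage {dosages[i, j]!r} at sample "
            f"{samples[i]!r}, variant {variant_ids[j]!r}"
        )
    variants = pd.DataFrame(
        {"chrom": "0", "pos": 0, "a1": "A", "a2": "B"},
        index=pd.Index(variant_ids, name="id"),
    )
    return GenotypeMatrix(samples, variants, dosages, validate=False)


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".bed" else path


def _read_plink(path: Path) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file {f}")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = fam_df[1].tolist()
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None, dtype={0: str, 1: str, 4: str, 5: str},
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    variants = bim_df.set_index("id")[["chrom", "pos", "a1", "a2"]]
    n, m = len(samples), len(variants)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes {raw[:3]!r} (not SNP-major PLINK bed)")
    nbytes = (n + 3) // 4
    if len(raw) - 3 != nbytes * m:
        raise FormatError(
            f"{bed}: payload of {len(raw) - 3} bytes does not match "
            f"{n} samples x {m} variants from .fam/.bim"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, nbytes)
    # unpack the 2-bit pairs, least-significant first within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    dosages = _BED_DECODE[codes].T  # samples x variants
    return GenotypeMatrix(samples, variants, dosages, validate=False)


def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str = "dosage-tsv") -> None:
    """Write genotypes as ``dosage-tsv`` or a PLINK ``plink-bed`` triple."""
    path = Path(path)
    if format == "dosage-tsv":
        df = pd.DataFrame(G.dosages, index=G.samples, columns=G.variants.index)
        df.index.name = "sample"
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", na_rep="NA", float_format="%g")
    elif format == "plink-bed":
        _write_plink(G, _plink_prefix(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_plink(G: GenotypeMatrix, prefix: Path) -> None:
    fam = pd.DataFrame(
        {0: G.samples, 1: G.samples, 2: 0, 3: 0, 4: 0, 5: -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    v = G.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v.index,
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    n, m = G.n_samples, G.n_variants
    d = G.dosages
    codes = np.full(d.shape, 1, dtype=np.uint8)  # 01 = missing
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    nbytes = (n + 3) // 4
    padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(m, nbytes, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# phenotype / exposure
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path, name: str | None = None) -> PhenotypeVector:
    """Read a two-column (sample ID, value) phenotype file; NA = missing."""
    df = pd.read_csv(path, sep=r"\s+", header=None, na_values=["NA"], dtype={0: str})
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns (ID, value), got {df.shape[1]}")
    return PhenotypeVector(df[0].tolist(), df[1].to_numpy(float), name or Path(path).stem)


def write_phenotype(y: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({0: y.samples, 1: y.values}).to_csv(
        path, sep="\t", header=False, index=False, na_rep="NA", float_format="%.17g"
    )


def read_exposure(path: str | Path, mode: str = "auto") -> ExposureVector:
    """Read a two-column exposure file; mode inferred unless given."""
    df = pd.read_csv(path, sep=r"\s+", header=None, na_values=["NA"], dtype={0: str})
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns (ID, value), got {df.shape[1]}")
    values = df[1].to_numpy(float)
    if mode == "auto":
        mode = "binary" if np.isin(values, (0.0, 1.0)).all() else "continuous"
    return ExposureVector(df[0].tolist(), values, mode)


def write_exposure(D: ExposureVector, path: str | Path) -> None:
    pd.DataFrame({0: D.samples, 1: D.values}).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def read_kinship(
    path: str | Path,
    dialect: str = "auto",
    role: str = "genetic",
    check_psd: bool = False,
) -> KinshipMatrix:
    """Read a kinship matrix (``square-tsv`` or ``gcta-grm``).

    For the GCTA dialect, ``path`` may be ``prefix``, ``prefix.grm.gz``
    or ``prefix.grm.bin``; ``prefix.grm.id`` must exist alongside.
    """
    path = Path(path)
    if dialect == "auto":
        s = path.name
        if s.endswith((".grm.gz", ".grm.bin", ".grm")):
            dialect = "gcta-grm"
        elif (
            Path(str(path) + ".grm.gz").exists()
            or Path(str(path) + ".grm.bin").exists()
        ):
            dialect = "gcta-grm"
        else:
            dialect = "square-tsv"
    if dialect == "square-tsv":
        K = _read_square_tsv(path, role)
    elif dialect == "gcta-grm":
        K = _read_gcta(path, role)
    else:
        raise ValueError(f"unknown kinship dialect {dialect!r}")
    if check_psd and role == "genetic":
        K.check_psd()
    return K


def _read_square_tsv(path: Path, role: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise FormatError(f"{path}: row IDs and column IDs disagree")
    values = df.to_numpy(float)
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > 1e-8 * max(1.0, np.abs(values).max(initial=0.0)):
        raise FormatError(f"{path}: matrix asymmetric (max |K - K'| = {asym:g})")
    return KinshipMatrix(ids, values, role)


def _gcta_prefix(path: Path) -> Path:
    s = str(path)
    for suffix in (".grm.gz", ".grm.bin", ".grm.id", ".grm"):
        if s.endswith(suffix):
            return Path(s[: -len(suffix)])
    return path


def _read_gcta(path: Path, role: str) -> KinshipMatrix:
    prefix = _gcta_prefix(path)
    id_file = Path(str(prefix) + ".grm.id")
    if not id_file.exists():
        raise FileNotFoundError(f"missing GCTA id file {id_file}")
    ids_df = pd.read_csv(id_file, sep=r"\s+", header=None, dtype=str)
    ids = ids_df.iloc[:, -1].tolist()  # FID IID -> use IID
    n = len(ids)
    gz = Path(str(prefix) + ".grm.gz")
    bin_ = Path(str(prefix) + ".grm.bin")
    values = np.zeros((n, n))
    if gz.exists():
        tab = pd.read_csv(gz, sep=r"\s+", header=None, compression="gzip")
        i = tab[0].to_numpy(int) - 1
        j = tab[1].to_numpy(int) - 1
        if i.max() >= n or j.max() >= n:
            raise FormatError(f"{gz}: index exceeds {n} IDs in {id_file}")
        values[i, j] = tab[3].to_numpy(float)
        values[j, i] = values[i, j]
        if len(tab) != n * (n + 1) // 2:
            raise FormatError(
                f"{gz}: {len(tab)} entries, expected {n * (n + 1) // 2} "
                f"for {n} samples"
            )
    elif bin_.exists():
        flat = np.fromfile(bin_, dtype=np.float32)
        if len(flat) != n * (n + 1) // 2:
            raise FormatError(
                f"{bin_}: {len(flat)} float32 values, expected "
                f"{n * (n + 1) // 2} for {n} samples"
            )
        iu = np.tril_indices(n)
        values[iu] = flat
        values.T[iu] = flat
    else:
        raise FileNotFoundError(f"neither {gz} nor {bin_} exists")
    return KinshipMatrix(ids, values, role)


def write_kinship(K: KinshipMatrix, path: str | Path, dialect: str = "square-tsv") -> None:
    """Write a kinship matrix; for ``gcta-grm``/``gcta-grm-bin`` ``path`` is a prefix."""
    path = Path(path)
    if dialect == "square-tsv":
        df = pd.DataFrame(K.values, index=K.samples, columns=K.samples)
        df.index.name = "ID"
        df.to_csv(path, sep="\t", float_format="%.17g")
        return
    if dialect not in ("gcta-grm", "gcta-grm-bin"):
        raise ValueError(f"unknown kinship dialect {dialect!r}")
    prefix = _gcta_prefix(path)
    pd.DataFrame({0: K.samples, 1: K.samples}).to_csv(
        Path(str(prefix) + ".grm.id"), sep="\t", header=False, index=False
    )
    n = K.n_samples
    il, jl = np.tril_indices(n)
    if dialect == "gcta-grm":
        with gzip.open(Path(str(prefix) + ".grm.gz"), "wt") as fh:
            for i, j in zip(il, jl):
                fh.write(f"{i + 1}\t{j + 1}\t1\t{K.values[i, j]:.17g}\n")
    else:
        K.values[il, jl].astype(np.float32).tofile(Path(str(prefix) + ".grm.bin"))


# ---------------------------------------------------------------------------
# association results
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = [
    "variant",
    "chrom",
    "pos",
    "beta_snp",
    "se_snp",
    "p_snp",
    "gamma_gei",
    "se_gei",
    "p_gei",
    "model",
]


def write_assoc_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write an association-result table as TSV with a fixed column order."""
    if len(results) == 0:
        raise ValueError("refusing to write an empty association table")
    missing = [c for c in ASSOC_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"association table missing columns {missing}")
    extra = [c for c in results.columns if c not in ASSOC_COLUMNS]
    results[ASSOC_COLUMNS + extra].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.17g"
    )


def read_assoc_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"variant": str, "chrom": str})
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df
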