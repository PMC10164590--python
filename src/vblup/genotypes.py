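"""Genotype containers and PLINK 1 binary (.bed/.bim/.fam) input/output.

Additive genotypes are coded as counts of the .bim allele-1 (A1): 2 means
homozygous A1, 0 homozygous A2.  Missing calls carry the sentinel
:data:`MISSING` (-1), distinct from any valid count; imputation is the
responsibility of downstream kinship construction, not of the reader.

Decoding uses a 256-entry lookup table so each byte (four individuals) is
translated in a single indexed read rather than per-2-bit arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 1 2-bit codes (little-endian within a byte):
#   00 -> 2 copies of A1, 01 -> missing, 10 -> heterozygous, 11 -> 0 copies.
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _build_lut() -> np.ndarray:
    """256 x 4 table: byte value -> additive counts of its four genotypes."""
    lut = np.empty((256, 4), dtype=np.int8)
    for byte in range(256):
        for slot in range(4):
            lut[byte, slot] = _CODE_TO_COUNT[(byte >> (2 * slot)) & 0b11]
    return lut


_LUT = _build_lut()

_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK binary files."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive genotype matrix with metadata.

    Parameters
    ----------
    codes : ndarray of int8, shape (n_individuals, n_markers)
        Counts of allele 1 in {0, 1, 2} or :data:`MISSING`.
    individual_ids : list of str
        Unique identifiers, one per row.
    markers : pandas.DataFrame
        One row per marker with columns ``chrom``, ``id``, ``pos``,
        ``allele1``, ``allele2``.
    """

    codes: np.ndarray
    individual_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x markers)")
        n, m = self.codes.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one individual and one marker")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match codes rows")
        if len(self.markers) != m:
            raise ValueError("marker table length does not match codes columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual IDs must be unique")
        if self.markers["id"].duplicated().any():
            raise ValueError("marker IDs must be unique")
        valid = np.isin(self.codes, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("genotype codes must be in {0,1,2} or missing")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


def decode_bed_bytes(raw: np.ndarray, n_individuals: int) -> np.ndarray:
    """Decode one marker's packed bytes into additive counts via the LUT."""
    counts = _LUT[raw].reshape(-1)
    return counts[:n_individuals]


def read_plink_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset given its path stem.

    Only the SNP-major (variant-major) layout of format version 1.00 is
    supported; the individual-major layout is rejected.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise PlinkFormatError(f"{fam_path}: expected >= 2 columns")
    individual_ids = fam.iloc[:, 1].tolist()

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise PlinkFormatError(f"{bim_path}: expected 6 columns")
    markers = pd.DataFrame(
        {
            "chrom": bim.iloc[:, 0],
            "id": bim.iloc[:, 1],
            "pos": bim.iloc[:, 3].astype(np.int64),
            "allele1": bim.iloc[:, 4],
            "allele2": bim.iloc[:, 5],
        }
    )

    n = len(individual_ids)
    m = len(markers)
    bytes_per_marker = (n + 3) // 4

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3].tobytes()[:2]) != _BED_MAGIC[:2]:
        raise PlinkFormatError(f"{bed_path}: not a PLINK .bed file (bad magic)")
    if raw[2] != 0x01:
        raise PlinkFormatError(
            f"{bed_path}: only SNP-major v1.00 .bed files are supported"
        )
    body = raw[3:]
    if len(body) != bytes_per_marker * m:
        raise PlinkFormatError(
            f"{bed_path}: size inconsistent with {n} individuals x {m} markers"
        )

    # LUT decode: all bytes at once, then drop per-marker padding columns.
    decoded = _LUT[body.reshape(m, bytes_per_marker)].reshape(m, -1)[:, :n]
    return GenotypeMatrix(decoded.T.copy(), individual_ids, markers)


def write_plink_bed(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK 1 SNP-major binary fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.codes.shape
    bytes_per_marker = (n + 3) // 4

    # counts -> 2-bit codes, padded with "homozygous A2" (code 11).
    code_of = np.zeros(256, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        code_of[np.int8(count).view(np.uint8)] = code
    # pad with count 2 (2-bit code 00) so padding bytes are zero bits,
    # matching what PLINK itself emits
    padded = np.full((m, bytes_per_marker * 4), 2, dtype=np.int8)
    padded[:, :n] = geno.codes.T
    two_bit = code_of[padded.view(np.uint8)]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (two_bit.reshape(m, bytes_per_marker, 4) << shifts).sum(
        axis=2, dtype=np.uint8
    )

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)

    fam = pd.DataFrame(
        {
            "fid": geno.individual_ids,
            "iid": geno.individual_ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    mk = geno.markers
    bim = pd.DataFrame(
        {
            "chrom": mk["chrom"],
            "id": mk["id"],
            "cm": 0,
            "pos": mk["pos"],
            "allele1": mk["allele1"],
            "allele2": mk["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)


def allele_frequencies(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker allele-1 frequency and genotype counts.

    Returns a DataFrame indexed like the marker table with columns
    ``freq`` (allele-1 frequency over non-missing calls; NaN if every call
    is missing), ``n0``, ``n1``, ``n2`` and ``n_missing``.
    """
    codes = geno.codes
    n0 = (codes == 0).sum(axis=0)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    nmiss = (codes == MISSING).sum(axis=0)
    called = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called > 0, (n1 + 2 * n2) / (2.0 * called), np.nan)
    return pd.DataFrame(
        {
            "id": geno.markers["id"].to_numpy(),
            "freq": freq,
            "n0": n0,
            "n1": n1,
            "n2": n2,
            "n_missing": nmiss,
        }
    )
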