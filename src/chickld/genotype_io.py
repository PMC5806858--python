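"""PLINK 1 binary genotype I/O and the in-memory panel model.

A panel is a samples × variants matrix of diploid calls counting copies of
.bim allele1 (the PLINK A1, minor by convention): 0, 1, 2 or missing.
Variant and sample metadata travel as pandas DataFrames mirroring the .bim
and .fam column layouts.

.bed layout: 3 header bytes (0x6c, 0x1b, then 0x01 for SNP-major mode),
followed by one row of ceil(n_samples/4) bytes per variant.  Each genotype
occupies 2 bits, little-endian within the byte:

    00 -> homozygous A1/A1 (call 2)
    01 -> missing
    10 -> heterozygous     (call 1)
    11 -> homozygous A2/A2 (call 0)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call in the int8 calls matrix.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

BIM_COLUMNS = ["chrom", "id", "cm", "bp", "allele1", "allele2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

# 2-bit code -> call value (per variant-major .bed spec above)
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam trio violates the PLINK 1 format."""


def _ext(prefix: Path, ext: str) -> Path:
    # suffix-append, not Path.with_suffix: prefixes may contain dots
    return prefix.parent / (prefix.name + ext)


@dataclass
class GenotypeDataset:
    """A diploid biallelic SNP panel.

    Attributes
    ----------
    samples : DataFrame with FAM_COLUMNS, one row per sample (order = matrix rows).
    variants : DataFrame with BIM_COLUMNS, one row per variant (order = matrix
        columns), sorted by (chrom, bp) with input order breaking ties.
    calls : int8 array (n_samples, n_variants); copies of allele1, MISSING = -1.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples × variants matrix")
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples × {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must take values in {0, 1, 2, missing}")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def sort_variants(self) -> "GenotypeDataset":
        """Return a copy sorted by (chrom, bp), stable in input order.

        Numeric chromosome labels sort numerically and before alphabetic
        labels (sex chromosomes, linkage groups).
        """
        key = self.variants["chrom"].map(chrom_sort_key)
        order = (
            self.variants.assign(_key=key)
            .sort_values(["_key", "bp"], kind="stable")
            .index.to_numpy()
        )
        return GenotypeDataset(
            samples=self.samples,
            variants=self.variants.iloc[order],
            calls=self.calls[:, order],
        )


def chrom_sort_key(label: str) -> tuple[int, float, str]:
    """Sort key placing numeric chromosome labels first, in numeric order."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0.0, s)


def _decode_bed_body(body: np.ndarray, n_samples: int, n_variants: int) -> np.ndarray:
    bytes_per_variant = (n_samples + 3) // 4
    rows = body.reshape(n_variants, bytes_per_variant)
    # unpack 2-bit fields, little-endian within each byte
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (rows >> (2 * k)) & 0b11
    return _CODE_TO_CALL[codes[:, :n_samples]].T.copy()  # samples × variants


def _encode_bed_body(calls: np.ndarray) -> bytes:
    n_samples, n_variants = calls.shape
    bytes_per_variant = (n_samples + 3) // 4
    codes = np.empty_like(calls, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        codes[calls == call] = code
    padded = np.ones((n_variants, bytes_per_variant * 4), dtype=np.uint8) * _CALL_TO_CODE[0]
    # pad slots beyond n_samples encode as hom A2/A2 (0b11), PLINK's convention
    padded[:, :n_samples] = codes.T
    out = np.zeros((n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    return out.tobytes()


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 binary trio ``prefix``.bed/.bim/.fam into a dataset.

    Variants are re-sorted by (chrom, bp) on load; ties keep file order.
    Raises :class:`PlinkFormatError` on a missing file, bad magic bytes,
    sample-major mode, or a truncated .bed body.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not _ext(prefix, ext).exists():
            raise PlinkFormatError(f"missing {_ext(prefix, ext)}")

    variants = pd.read_csv(
        _ext(prefix, ".bim"),
        sep=r"\s+",
        names=BIM_COLUMNS,
        dtype={"chrom": str, "id": str, "cm": float, "bp": np.int64, "allele1": str, "allele2": str},
    )
    samples = pd.read_csv(
        _ext(prefix, ".fam"),
        sep=r"\s+",
        names=FAM_COLUMNS,
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )

    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2:3]!r})")
    n_samples, n_variants = len(samples), len(variants)
    expected = (n_samples + 3) // 4 * n_variants + 3
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: size {len(raw)} != expected {expected} "
            f"for {n_samples} samples × {n_variants} variants"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    calls = _decode_bed_body(body, n_samples, n_variants)
    return GenotypeDataset(samples=samples, variants=variants, calls=calls).sort_variants()


def write_plink(ds: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``ds`` as a PLINK 1 binary trio; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(_encode_bed_body(ds.calls))
    ds.variants[BIM_COLUMNS].to_csv(
        _ext(prefix, ".bim"), sep="\t", header=False, index=False
    )
    ds.samples[FAM_COLUMNS].to_csv(
        _ext(prefix, ".fam"), sep="\t", header=False, index=False
    )


def split_by_line(ds: GenotypeDataset) -> dict[str, GenotypeDataset]:
    """Partition samples by .fam family id (the line/population label)."""
    parts: dict[str, GenotypeDataset] = {}
    for fid in ds.samples["fid"].unique():
        idx = np.flatnonzero((ds.samples["fid"] == fid).to_numpy())
        parts[str(fid)] = subset(ds, keep_samples=idx)
    return parts


def subset(
    ds: GenotypeDataset,
    keep_samples: np.ndarray | list[int] | None = None,
    keep_variants: np.ndarray | list[int] | None = None,
) -> GenotypeDataset:
    """Order-preserving subset by sample and/or variant positional indices."""
    s_idx = np.arange(ds.n_samples) if keep_samples is None else np.asarray(keep_samples, dtype=np.intp)
    v_idx = np.arange(ds.n_variants) if keep_variants is None else np.asarray(keep_variants, dtype=np.intp)
    if s_idx.size and (s_idx.min() < 0 or s_idx.max() >= ds.n_samples):
        raise IndexError("sample index out of range")
    if v_idx.size and (v_idx.min() < 0 or v_idx.max() >= ds.n_variants):
        raise IndexError("variant index out of range")
    return GenotypeDataset(
        samples=ds.samples.iloc[s_idx],
        variants=ds.variants.iloc[v_idx],
        calls=ds.calls[np.ix_(s_idx, v_idx)],
    )
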