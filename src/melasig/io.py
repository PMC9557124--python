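"""Readers and writers for the formats the pipeline touches.

MAF (GDC column dialect), minimal VCF, BED3 panel regions, FASTA genomes and
COSMIC-v3-layout signature matrices.  MAF/VCF positions are 1-based
inclusive; BED intervals are 0-based half-open; the conversion between the
two happens only inside interval intersection (see :mod:`melasig.panel`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import BASES, CONTEXT_INDEX, CONTEXT_LABELS, MutationCatalog, normalize_chrom
from .errors import EmptyResultError, FormatError, ParameterError

MAF_REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
)


def read_maf(path: str | os.PathLike, snv_only: bool = True) -> MutationCatalog:
    """Read a tab-delimited MAF (GDC dialect) into a :class:`MutationCatalog`.

    Rows with ``Variant_Type == 'SNP'`` and single-base ACGT alleles become
    SNV records; every other row is ``variant_class='other'`` and dropped
    when ``snv_only``.  Chromosome names are normalized ('chr7' -> '7').
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    except pd.errors.EmptyDataError:
        raise EmptyResultError(f"MAF file {path} contains no records") from None
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF file {path} lacks required column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyResultError(f"MAF file {path} contains no records")
    ref = df["Reference_Allele"].str.upper()
    alt = df["Tumor_Seq_Allele2"].str.upper()
    is_snv = (
        (df["Variant_Type"] == "SNP")
        & ref.isin(list(BASES))
        & alt.isin(list(BASES))
        & (ref != alt)
    )
    records = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "chrom": df["Chromosome"].map(normalize_chrom),
            "pos": pd.to_numeric(df["Start_Position"]).astype(np.int64),
            "ref": ref,
            "alt": alt,
            "variant_class": np.where(is_snv, "SNV", "other"),
        }
    )
    sample_ids = list(dict.fromkeys(records["sample_id"]))
    if snv_only:
        records = records[records["variant_class"] == "SNV"].reset_index(drop=True)
    return MutationCatalog(records, sample_ids)


def write_maf(catalog: MutationCatalog, path: str | os.PathLike) -> None:
    """Write a catalog back out with the GDC column names used on input."""
    rec = catalog.records
    out = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": rec["sample_id"],
            "Chromosome": rec["chrom"],
            "Start_Position": rec["pos"],
            "End_Position": rec["pos"],
            "Reference_Allele": rec["ref"],
            "Tumor_Seq_Allele2": rec["alt"],
            "Variant_Type": np.where(rec["variant_class"] == "SNV", "SNP", "OTHER"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | os.PathLike, sample_id: str | None = None) -> MutationCatalog:
    """Read a minimal VCF (CHROM/POS/REF/ALT) into a catalog.

    The sample id is taken from the first genotype column if present,
    otherwise from ``sample_id`` or the file stem.  Multi-allelic records
    contribute one row per ALT.
    """
    import pysam

    rows = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        header_samples = list(vf.header.samples)
        sid = sample_id or (header_samples[0] if header_samples else Path(path).stem)
        for rec in vf:
            for alt in rec.alts or ():
                is_snv = (
                    len(rec.ref) == 1
                    and len(alt) == 1
                    and rec.ref.upper() in BASES
                    and alt.upper() in BASES
                    and rec.ref.upper() != alt.upper()
                )
                rows.append(
                    (
                        sid,
                        normalize_chrom(rec.chrom),
                        rec.pos,
                        rec.ref.upper(),
                        alt.upper(),
                        "SNV" if is_snv else "other",
                    )
                )
    if not rows:
        raise EmptyResultError(f"VCF file {path} contains no records")
    records = pd.DataFrame(rows, columns=list(MutationCatalog.COLUMNS))
    return MutationCatalog(records, [records["sample_id"].iloc[0]])


# ---------------------------------------------------------------------------
# panel regions


@dataclass
class PanelRegions:
    """Merged, sorted capture intervals in BED convention (0-based half-open)."""

    intervals: pd.DataFrame  # columns chrom, start, end; merged and sorted

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "PanelRegions":
        df = pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])
        if df.empty:
            raise ParameterError("panel has no intervals")
        if (df["end"] <= df["start"]).any():
            raise FormatError("panel interval with end <= start")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        merged = []
        for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
            cur_s, cur_e = None, None
            for s, e in grp[["start", "end"]].itertuples(index=False):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlapping or adjacent-touching: merge overlaps only
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
        return cls(out.astype({"start": np.int64, "end": np.int64}))

    @property
    def total_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def __len__(self) -> int:
        return len(self.intervals)


def read_bed(path: str | os.PathLike) -> PanelRegions:
    """Read a BED3 file of capture regions (strand ignored, intervals merged)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        raise ParameterError(f"BED file {path} is empty") from None
    return PanelRegions.from_intervals(df.itertuples(index=False, name=None))


def write_bed(panel: PanelRegions, path: str | os.PathLike) -> None:
    panel.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# signature matrices


@dataclass
class ReferenceSignatureSet:
    """Named 96-class signature profiles, columns summing to 1.

    ``profiles`` is 96 x m in canonical context order.
    """

    names: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise ParameterError(
                f"profiles shape {self.profiles.shape} != (96, {len(self.names)})"
            )
        if (self.profiles < 0).any():
            raise ParameterError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ParameterError("signature columns must sum to 1 within 1e-6")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.profiles[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "ReferenceSignatureSet":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise ParameterError(f"signatures not in set: {missing}")
        idx = [self.names.index(n) for n in names]
        return ReferenceSignatureSet(list(names), self.profiles[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=list(CONTEXT_LABELS), columns=self.names)


def read_signature_matrix(path: str | os.PathLike) -> ReferenceSignatureSet:
    """Read a COSMIC-v3-layout signature TSV (96 rows, label column first).

    Rows may be in any order; they are reordered to the canonical index.
    Columns whose sum is within 1e-3 of 1 are renormalized exactly;
    anything further off is a format error.
    """
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    if len(df) != 96:
        raise FormatError(f"signature matrix must have 96 data rows, found {len(df)}")
    labels = df[label_col].astype(str)
    unknown = [l for l in labels if l not in CONTEXT_INDEX]
    if unknown:
        raise FormatError(f"unknown context label(s): {unknown[:3]}")
    if labels.duplicated().any():
        raise FormatError("duplicated context labels in signature matrix")
    df = df.set_index(label_col).reindex(list(CONTEXT_LABELS))
    profiles = df.to_numpy(dtype=float)
    if (profiles < 0).any():
        raise FormatError("negative entries in signature matrix")
    sums = profiles.sum(axis=0)
    off = np.abs(sums - 1.0) > 1e-3
    if off.any():
        bad = [df.columns[i] for i in np.flatnonzero(off)]
        raise FormatError(f"signature column(s) do not sum to 1: {bad}")
    profiles = profiles / sums
    return ReferenceSignatureSet(list(df.columns), profiles)


def write_signature_matrix(sigset: ReferenceSignatureSet, path: str | os.PathLike) -> None:
    sigset.to_frame().rename_axis("Type").to_csv(path, sep="\t")


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    """Write a dict of contig -> sequence as FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_context_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a samples x 96 context-count TSV (samples in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CONTEXT_LABELS if c not in df.columns]
    if missing:
        raise FormatError(f"context matrix lacks {len(missing)} context columns")
    return df[list(CONTEXT_LABELS)]


def write_context_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.rename_axis("sample_id").to_csv(path, sep="\t")
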