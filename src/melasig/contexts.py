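"""96-class trinucleotide substitution contexts.

Somatic single-nucleotide variants are classified on the pyrimidine strand:
a substitution whose reference base is a purine is reverse-complemented
(together with both flanking bases) before classification.  The resulting
class is one of 6 substitutions (C>A, C>G, C>T, T>A, T>C, T>G) x 16
flanking-base combinations = 96 classes, enumerated here in the canonical
COSMIC order (substitution blocks in the order above; within a block the 5'
flank is the outer loop and the 3' flank the inner one, both alphabetical).
All matrices in the package use this ordering, so COSMIC-layout signature
files are drop-in comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, EmptyResultError, ParameterError

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 context labels, canonical COSMIC order, e.g. "A[C>A]A".
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

#: The 32 pyrimidine-centred trinucleotides, C-centred block first.
TRINUCLEOTIDES_32: tuple[str, ...] = tuple(
    f"{five}{centre}{three}"
    for centre in PYRIMIDINES
    for five in BASES
    for three in BASES
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class ContextClass(NamedTuple):
    """One of the 96 pyrimidine-strand substitution classes."""

    substitution: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return CONTEXT_INDEX[self.label]

    @property
    def trinucleotide(self) -> str:
        """Pyrimidine-strand reference trinucleotide, e.g. 'ACA' for A[C>T]A."""
        return f"{self.five_prime}{self.substitution[0]}{self.three_prime}"

    @classmethod
    def from_label(cls, label: str) -> "ContextClass":
        if label not in CONTEXT_INDEX:
            raise ParameterError(f"unknown context label: {label!r}")
        return cls(substitution=label[2:5], five_prime=label[0], three_prime=label[6])


def normalize_chrom(name: str) -> str:
    """Strip a 'chr' prefix and unify mitochondrial synonyms to 'MT'."""
    name = str(name)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in ("M", "m"):
        name = "MT"
    return name


@dataclass
class MutationCatalog:
    """Per-sample somatic SNV records.

    ``records`` is a DataFrame with columns ``sample_id, chrom, pos, ref,
    alt, variant_class`` (pos 1-based; chrom normalized, no 'chr' prefix;
    variant_class in {'SNV', 'other'}).  ``sample_ids`` preserves cohort
    sample order, including samples whose records were all filtered away.
    """

    records: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "variant_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ParameterError(f"catalog records missing columns: {missing}")
        if not self.sample_ids:
            self.sample_ids = list(dict.fromkeys(self.records["sample_id"]))

    def __len__(self) -> int:
        return len(self.records)

    def snvs(self) -> pd.DataFrame:
        return self.records[self.records["variant_class"] == "SNV"]

    def snv_counts(self) -> pd.Series:
        """Per-sample SNV counts, indexed in ``sample_ids`` order."""
        counts = self.snvs().groupby("sample_id").size()
        return counts.reindex(self.sample_ids, fill_value=0).astype(int)

    def subset_samples(self, keep: Iterable[str]) -> "MutationCatalog":
        keep = list(keep)
        kset = set(keep)
        rec = self.records[self.records["sample_id"].isin(kset)].reset_index(drop=True)
        return MutationCatalog(rec, [s for s in self.sample_ids if s in kset])


def _contig_sequence(genome, chrom: str):
    """Resolve a normalized contig name against a genome mapping.

    Accepts any object supporting ``genome[contig][start:end]`` (a plain
    dict of strings, pyfaidx.Fasta, a ToyGenome).  Tries the bare name,
    then 'chr'-prefixed, then mitochondrial synonyms.
    """
    candidates = [chrom, f"chr{chrom}"]
    if chrom == "MT":
        candidates += ["M", "chrM"]
    for cand in candidates:
        try:
            return genome[cand]
        except KeyError:
            continue
    raise DataIntegrityError(f"contig {chrom!r} not present in reference genome")


def reference_trinucleotide(genome, chrom: str, pos: int) -> str | None:
    """Genome-strand trinucleotide centred on 1-based ``pos``.

    Returns None when the position is at a contig edge (no flank).
    """
    if pos < 2:
        return None
    seq = _contig_sequence(genome, chrom)
    tri = str(seq[pos - 2 : pos + 1]).upper()
    return tri if len(tri) == 3 else None


def mutation_context(
    genome, chrom: str, pos: int, ref: str, alt: str, *, skip_mismatch: bool = False
) -> ContextClass | None:
    """Classify one SNV into its pyrimidine-strand 96-class context.

    Returns None (caller should skip and count) when the flanking context
    contains a non-ACGT base or the position has no flank.  Raises
    :class:`DataIntegrityError` when the genome base disagrees with the
    claimed reference allele, unless ``skip_mismatch`` (then None).
    """
    tri = reference_trinucleotide(genome, chrom, pos)
    if tri is None:
        logger.warning("no flanking context at %s:%d; record skipped", chrom, pos)
        return None
    centre = tri[1]
    if centre not in BASES:
        logger.warning("ambiguous base %r at %s:%d; record skipped", centre, chrom, pos)
        return None
    if centre != ref:
        if skip_mismatch:
            logger.warning(
                "reference mismatch at %s:%d (genome %s, record %s); skipped",
                chrom, pos, centre, ref,
            )
            return None
        raise DataIntegrityError(
            f"reference mismatch at {chrom}:{pos}: genome has {centre}, record claims {ref}"
        )
    if any(b not in BASES for b in tri):
        logger.warning("flank contains non-ACGT base at %s:%d; record skipped", chrom, pos)
        return None
    if ref in "AG":  # purine: report on the pyrimidine strand
        tri = revcomp(tri)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return ContextClass(f"{ref}>{alt}", tri[0], tri[2])


def build_context_matrix(
    catalog: MutationCatalog, genome, *, skip_mismatch: bool = False
) -> pd.DataFrame:
    """Count each sample's SNVs into the 96 context classes.

    Returns a samples x 96 integer DataFrame (rows in ``catalog.sample_ids``
    order, columns :data:`CONTEXT_LABELS`).  Row sums equal the number of
    successfully classified SNVs per sample; records whose context contains
    an ambiguous base are skipped and the skip count logged.
    """
    if len(catalog) == 0:
        raise EmptyResultError("cannot build a context matrix from an empty catalog")
    counts = np.zeros((len(catalog.sample_ids), 96), dtype=np.int64)
    row_of = {s: i for i, s in enumerate(catalog.sample_ids)}
    snvs = catalog.snvs()
    n_skipped = 0
    # cache contig strings to avoid repeated pyfaidx fetch machinery
    contig_cache: dict[str, str] = {}
    for sample_id, chrom, pos, ref, alt in snvs[
        ["sample_id", "chrom", "pos", "ref", "alt"]
    ].itertuples(index=False):
        if chrom not in contig_cache:
            contig_cache[chrom] = str(_contig_sequence(genome, chrom)[:]).upper()
        ctx = mutation_context(
            {chrom: contig_cache[chrom]}, chrom, pos, ref, alt, skip_mismatch=skip_mismatch
        )
        if ctx is None:
            n_skipped += 1
            continue
        counts[row_of[sample_id], ctx.index] += 1
    if n_skipped:
        logger.info("skipped %d records with unusable context", n_skipped)
    return pd.DataFrame(counts, index=list(catalog.sample_ids), columns=list(CONTEXT_LABELS))


def filter_min_snv(matrix: pd.DataFrame, min_snv: int = 5) -> pd.DataFrame:
    """Drop samples with fewer than ``min_snv`` classified SNVs.

    The boundary is inclusive: a sample with exactly ``min_snv`` SNVs is
    retained.  Row order is preserved.
    """
    if min_snv < 1:
        raise ParameterError("min_snv must be >= 1")
    kept = matrix[matrix.sum(axis=1) >= min_snv]
    if kept.shape[0] == 0:
        raise EmptyResultError(f"no sample has >= {min_snv} SNVs")
    return kept


def spectra_to_proportions(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Row-normalize count spectra to per-sample proportions."""
    arr = np.asarray(matrix, dtype=float)
    sums = arr.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ParameterError("cannot normalize an all-zero spectrum")
    return arr / sums
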