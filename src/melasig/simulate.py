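"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the structure of a cutaneous-melanoma WES cohort:
two latent clusters (UV-high, ~84% of samples, high burden, spectra
dominated by a UV-like signature; UV-low, low burden, clock-like spectra),
per-sample mutation counts drawn log-normally, 96-class contexts drawn
from the cluster's signature mixture, mutations placed on a random toy
genome at positions whose trinucleotide matches the drawn context (so the
drawn tally is exactly recoverable from the catalog), plus exponential
survival times with a specified UV-low : UV-high hazard ratio and
independent exponential censoring.  Truth tables are first-class outputs;
tests read truth rather than re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import (
    BASES,
    CONTEXT_LABELS,
    ContextClass,
    MutationCatalog,
    PYRIMIDINES,
    revcomp,
)
from .errors import ParameterError
from .io import PanelRegions, ReferenceSignatureSet, write_fasta
from .references import sbs1_like, sbs5_like, sbs7a_like, sbs7b_like

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
DAYS_PER_YEAR = 365.25


@dataclass
class GeneratorSignatures:
    """The two generating processes: a UV-like and a flat clock-like profile."""

    uv_like: np.ndarray
    flat_clock: np.ndarray

    @classmethod
    def default(cls) -> "GeneratorSignatures":
        # UV: SBS7a/7b-like blend (C>T at TpCpC / TpCpT); clock: SBS1/5-like
        # blend (C>T-at-CpG spike on a near-uniform background).
        uv = 0.6 * sbs7a_like() + 0.4 * sbs7b_like()
        clock = 0.5 * sbs1_like() + 0.5 * sbs5_like()
        return cls(uv / uv.sum(), clock / clock.sum())

    def as_reference(self) -> ReferenceSignatureSet:
        return ReferenceSignatureSet(
            ["UV", "Clock"], np.column_stack([self.uv_like, self.flat_clock])
        )


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Burdens are (median, log-scale sigma) of a log-normal; mixtures are
    (UV-like, flat clock-like) proportions; hazards are per year, with
    clinical time written in days.  Defaults echo the shape of the TCGA
    melanoma cohort: 84% UV-high, burden medians 300 vs 30 SNVs, UV-low
    hazard ratio 2.2, ~60% event fraction.
    """

    n_samples: int = 200
    frac_uv_high: float = 391 / 466
    burden_uv_high: tuple[float, float] = (300.0, 1.0)
    burden_uv_low: tuple[float, float] = (30.0, 0.8)
    mix_uv_high: tuple[float, float] = (0.85, 0.15)
    mix_uv_low: tuple[float, float] = (0.10, 0.90)
    hr_uv_low: float = 2.2
    baseline_hazard: float = 0.25      # events / year in UV-high
    censor_rate: float = 0.18          # censorings / year
    genome_length: int = 1_000_000
    seed: int = 0


@dataclass
class ToyGenome:
    """A random single-contig genome plus a context-placement index.

    ``context_positions`` maps each pyrimidine-centred trinucleotide to the
    0-based centre positions whose pyrimidine-strand trinucleotide matches,
    so a drawn context class can be placed without rejection sampling.
    """

    sequences: dict[str, str]
    context_positions: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def write_fasta(self, path) -> None:
        write_fasta(self.sequences, path)


def _index_trinucleotides(seq: str) -> dict[str, np.ndarray]:
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    a = lut[code]
    tri = a[:-2] * 16 + a[1:-1] * 4 + a[2:]          # genome-strand trinuc code
    rc = (3 - a[2:]) * 16 + (3 - a[1:-1]) * 4 + (3 - a[:-2])
    canonical = np.where(np.isin(a[1:-1], (1, 3)), tri, rc)  # centre C/T kept
    order = np.argsort(canonical, kind="stable")
    sorted_codes = canonical[order]
    centres = order + 1                               # centre position, 0-based
    index: dict[str, np.ndarray] = {}
    bounds = np.searchsorted(sorted_codes, np.arange(65))
    for t in range(64):
        s = "".join(BASES[(t >> k) & 3] for k in (4, 2, 0))
        if s[1] in PYRIMIDINES:
            index[s] = centres[bounds[t] : bounds[t + 1]]
    return index


def make_toy_genome(length: int = 1_000_000, seed: int = 0, contig: str = "1") -> ToyGenome:
    """Generate a random A/C/G/T genome and its trinucleotide index.

    In the (practically impossible for length >= 10 kb) event that one of
    the 32 pyrimidine-centred trinucleotides has no placeable position, the
    sequence is regenerated with a warning.
    """
    if length < 10_000:
        raise ParameterError("toy genome must be at least 10 kb")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        index = _index_trinucleotides(seq)
        if all(len(v) > 0 for v in index.values()):
            return ToyGenome({contig: seq}, index)
        import warnings

        warnings.warn("toy genome missing a trinucleotide context; regenerating")
    raise ParameterError("could not generate a genome covering all 32 trinucleotides")


def simulate_catalog(
    spec: CohortSpec,
    sigs: GeneratorSignatures | None = None,
    genome: ToyGenome | None = None,
) -> tuple[MutationCatalog, pd.DataFrame, pd.DataFrame]:
    """Draw a cohort mutation catalog with full ground truth.

    Per sample: cluster ~ Bernoulli(frac_uv_high); burden ~ round of a
    log-normal (minimum 1); context counts ~ Multinomial(burden, mixture of
    the generator signatures); each mutation is placed at a uniformly
    chosen indexed position of its trinucleotide, emitted in MAF
    convention on the genome strand (purine-strand placements are
    reverse-complemented, exercising downstream strand normalization).

    Returns ``(catalog, truth, tally)`` where ``truth`` has one row per
    sample (cluster, mix_uv, n_snv) and ``tally`` is the drawn samples x 96
    context count matrix — exactly what build_context_matrix must recover.
    """
    sigs = sigs or GeneratorSignatures.default()
    genome = genome or make_toy_genome(spec.genome_length, seed=spec.seed + 101)
    contig = next(iter(genome.sequences))
    seq = genome.sequences[contig]
    rng = np.random.default_rng(spec.seed)

    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    clusters = np.where(rng.random(n) < spec.frac_uv_high, "UV-high", "UV-low")
    mix_uv = np.where(clusters == "UV-high", spec.mix_uv_high[0], spec.mix_uv_low[0])
    burdens = np.empty(n, dtype=np.int64)
    for cl, (median, sigma) in (("UV-high", spec.burden_uv_high), ("UV-low", spec.burden_uv_low)):
        m = clusters == cl
        burdens[m] = np.maximum(
            1, np.round(np.exp(rng.normal(np.log(median), sigma, size=m.sum())))
        )

    tri_of = [ContextClass.from_label(lab).trinucleotide for lab in CONTEXT_LABELS]
    alt_of = [lab[4] for lab in CONTEXT_LABELS]       # pyrimidine-strand ALT
    ref_of = [lab[2] for lab in CONTEXT_LABELS]
    tally = np.zeros((n, 96), dtype=np.int64)
    sid_col, pos_col, ref_col, alt_col = [], [], [], []
    for i in range(n):
        probs = mix_uv[i] * sigs.uv_like + (1 - mix_uv[i]) * sigs.flat_clock
        counts = rng.multinomial(burdens[i], probs)
        tally[i] = counts
        for c in np.flatnonzero(counts):
            positions = genome.context_positions[tri_of[c]]
            if positions.size == 0:
                raise ParameterError(f"no placeable position for context {CONTEXT_LABELS[c]}")
            chosen = positions[rng.integers(0, positions.size, size=counts[c])]
            for p in chosen:
                if seq[p] in PYRIMIDINES:             # genome strand is the pyrimidine strand
                    ref, alt = ref_of[c], alt_of[c]
                else:
                    ref, alt = _COMP[ref_of[c]], _COMP[alt_of[c]]
                sid_col.append(sample_ids[i])
                pos_col.append(p + 1)                 # 1-based MAF convention
                ref_col.append(ref)
                alt_col.append(alt)

    records = pd.DataFrame(
        {
            "sample_id": sid_col,
            "chrom": [contig] * len(sid_col),
            "pos": np.array(pos_col, dtype=np.int64),
            "ref": ref_col,
            "alt": alt_col,
            "variant_class": ["SNV"] * len(sid_col),
        }
    )
    truth = pd.DataFrame(
        {"cluster": clusters, "mix_uv": mix_uv, "n_snv": burdens}, index=sample_ids
    ).rename_axis("sample_id")
    tally_df = pd.DataFrame(tally, index=sample_ids, columns=list(CONTEXT_LABELS))
    return MutationCatalog(records, sample_ids), truth, tally_df


def simulate_survival(
    truth: pd.DataFrame, spec: CohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw survival outcomes and clinical covariates for a truth table.

    Event times are exponential with hazard baseline_hazard x hr_uv_low
    for UV-low samples, censoring independently exponential at
    censor_rate; times are written in days.  Covariates are drawn from
    melanoma-like marginals, with BRAF-hotspot mutations enriched in the
    UV-high cluster.
    """
    if truth.empty:
        raise ParameterError("truth table is empty")
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    n = len(truth)
    uv_low = (truth["cluster"] == "UV-low").to_numpy()
    hazard = spec.baseline_hazard * np.where(uv_low, spec.hr_uv_low, 1.0) / DAYS_PER_YEAR
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_censor = rng.exponential(DAYS_PER_YEAR / spec.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    p_braf = np.where(uv_low, 0.15, 0.50)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": np.clip(rng.normal(58, 13, size=n), 20, 95).round(1),
            "sex": np.where(rng.random(n) < 0.62, "male", "female"),
            "stage": np.where(rng.random(n) < 0.40, "III/IV", "I/II"),
            "mutation_class": np.where(rng.random(n) < p_braf, "BRAF hotspot", "non-BRAF"),
            "cluster": truth["cluster"].to_numpy(),
        },
        index=truth.index,
    )


def simulate_panel(
    genome: ToyGenome,
    coverage_fraction: float = 0.012,
    seed: int = 0,
    n_intervals: int = 30,
) -> PanelRegions:
    """Random disjoint capture intervals totalling a fraction of the genome.

    The default 1.2% coverage mirrors a 1.2 Mb panel against a 100 Mb
    captured exome, scaled to the toy genome.  Realized coverage is exact
    by construction.
    """
    if not 0 < coverage_fraction <= 1:
        raise ParameterError("coverage_fraction must be in (0, 1]")
    contig = next(iter(genome.sequences))
    length = len(genome.sequences[contig])
    total = max(1, int(round(coverage_fraction * length)))
    if coverage_fraction == 1:
        return PanelRegions.from_intervals([(contig, 0, length)])
    rng = np.random.default_rng(seed)
    k = min(n_intervals, total)
    sizes = np.full(k, total // k, dtype=np.int64)
    sizes[: total - sizes.sum()] += 1
    free = length - total
    gaps = np.sort(rng.integers(0, free + 1, size=k))
    starts = gaps + np.concatenate([[0], np.cumsum(sizes)[:-1]])
    intervals = [(contig, int(s), int(s + sz)) for s, sz in zip(starts, sizes)]
    return PanelRegions.from_intervals(intervals)


def simulate_cohort(
    spec: CohortSpec, sigs: GeneratorSignatures | None = None
) -> dict:
    """Convenience bundle: genome, catalog, truth, tally, clinical, panel."""
    sigs = sigs or GeneratorSignatures.default()
    genome = make_toy_genome(spec.genome_length, seed=spec.seed + 101)
    catalog, truth, tally = simulate_catalog(spec, sigs, genome)
    clinical = simulate_survival(truth, spec)
    panel = simulate_panel(genome, seed=spec.seed + 211)
    return {
        "spec": spec,
        "signatures": sigs,
        "genome": genome,
        "catalog": catalog,
        "truth": truth,
        "tally": tally,
        "clinical": clinical,
        "panel": panel,
    }
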