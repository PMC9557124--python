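"""In-silico targeted-panel simulation and panel-based UV classification.

A WES/WGS catalog is restricted positionally to panel capture regions
(no depth or error modelling — panel restriction is the coordinate
intersection only).  Each panel sample is then refit on the two extracted
signatures (SigA = clock-like, SigB = UV-like) and called UV-high when the
SigB weight exceeds 0.5 (strictly; an exact 0.5 is UV-low).  Samples with
fewer than five panel SNVs are excluded and carry no label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS, MutationCatalog, spectra_to_proportions
from .errors import AlignmentError, ParameterError
from .io import PanelRegions, ReferenceSignatureSet
from .nmf import ClusterAssignment, cosine_similarity
from .refit import refit_sample

logger = logging.getLogger(__name__)


def intersect_panel(catalog: MutationCatalog, panel: PanelRegions) -> MutationCatalog:
    """Retain the records falling inside the (merged) panel intervals.

    A record at 1-based position ``pos`` is retained when ``pos - 1`` lies
    in some half-open interval [start, end).  Sample order is preserved and
    samples losing every record remain in ``sample_ids`` (they classify as
    excluded downstream).
    """
    if len(panel) == 0:
        raise ParameterError("empty panel")
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in panel.intervals.groupby("chrom")
    }
    rec = catalog.records
    keep = np.zeros(len(rec), dtype=bool)
    for chrom, idx in rec.groupby("chrom").groups.items():
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        pos0 = rec.loc[idx, "pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        keep[rec.index.get_indexer(idx)] = ok
    return MutationCatalog(rec[keep].reset_index(drop=True), list(catalog.sample_ids))


@dataclass
class PanelClassification:
    """UV call for one panel-restricted sample."""

    sample_id: str
    sigb_weight: float | None   # None when excluded
    label: str | None           # "UV-high" / "UV-low"; None when excluded
    n_snv_panel: int
    excluded: bool


def classify_panel_sample(
    spectrum,
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    *,
    threshold: float = 0.5,
    min_snv: int = 5,
    sample_id: str = "",
) -> PanelClassification:
    """Call one panel spectrum UV-high/UV-low by two-signature refitting.

    Refits the spectrum on {SigA, SigB} with no pruning; UV-high iff the
    SigB weight is strictly greater than ``threshold``.  Spectra with fewer
    than ``min_snv`` mutations are excluded (a normal outcome, not an
    error).
    """
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    n = int(round(spectrum.sum()))
    if n < min_snv:
        return PanelClassification(sample_id, None, None, n, True)
    ref = ReferenceSignatureSet(["SigA", "SigB"], np.column_stack([sig_a, sig_b]))
    res = refit_sample(spectrum, ref, prune_threshold=0.0, sample_id=sample_id)
    w = res.weights["SigB"]
    label = "UV-high" if w > threshold else "UV-low"
    return PanelClassification(sample_id, w, label, n, False)


def classify_panel_cohort(
    matrix: pd.DataFrame,
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    *,
    threshold: float = 0.5,
    min_snv: int = 5,
) -> pd.DataFrame:
    """Classify every row of a panel context matrix.

    Returns a DataFrame indexed by sample with columns ``sigb_weight,
    label, n_snv_panel, excluded``.
    """
    rows = [
        classify_panel_sample(
            matrix.loc[sid].to_numpy(), sig_a, sig_b,
            threshold=threshold, min_snv=min_snv, sample_id=str(sid),
        )
        for sid in matrix.index
    ]
    return pd.DataFrame(
        {
            "sigb_weight": [r.sigb_weight for r in rows],
            "label": [r.label for r in rows],
            "n_snv_panel": [r.n_snv_panel for r in rows],
            "excluded": [r.excluded for r in rows],
        },
        index=matrix.index,
    )


def pre_post_concordance(wes_matrix: pd.DataFrame, panel_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample spectrum cosine and count retention before/after panel.

    Both matrices must cover the same samples.  Samples with an empty panel
    spectrum get cosine NaN (reported as missing) and retention 0.
    """
    if set(wes_matrix.index) != set(panel_matrix.index):
        raise AlignmentError("WES and panel matrices cover different samples")
    panel_matrix = panel_matrix.loc[wes_matrix.index]
    wes_counts = wes_matrix.sum(axis=1).to_numpy(dtype=float)
    panel_counts = panel_matrix.sum(axis=1).to_numpy(dtype=float)
    if np.any(wes_counts == 0):
        raise ParameterError("WES matrix contains an all-zero sample")
    cosines = np.full(len(wes_matrix), np.nan)
    for i in range(len(wes_matrix)):
        if panel_counts[i] > 0:
            cosines[i] = cosine_similarity(
                wes_matrix.iloc[i].to_numpy(), panel_matrix.iloc[i].to_numpy()
            )
    return pd.DataFrame(
        {"cosine": cosines, "retention": panel_counts / wes_counts},
        index=wes_matrix.index,
    )


def average_context(
    matrix: pd.DataFrame, labels: ClusterAssignment | Mapping[str, str]
) -> pd.DataFrame:
    """Mean proportion spectrum per cluster label (rows sum to 1).

    Labelled samples must be present in the matrix; label groups that end
    up empty are skipped with a warning.
    """
    label_of = labels.label_of() if isinstance(labels, ClusterAssignment) else dict(labels)
    missing = [s for s in label_of if s not in matrix.index]
    if missing:
        raise AlignmentError(f"labelled sample(s) absent from matrix: {missing[:3]}")
    props = pd.DataFrame(
        spectra_to_proportions(matrix.loc[list(label_of)]),
        index=list(label_of), columns=list(CONTEXT_LABELS),
    )
    rows = {}
    for lab in dict.fromkeys(label_of.values()):
        members = [s for s, l in label_of.items() if l == lab]
        if not members:
            logger.warning("label %s has no samples; skipped", lab)
            continue
        rows[lab] = props.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T
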