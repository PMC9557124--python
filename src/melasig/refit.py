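"""Signature refitting: non-negative decomposition onto fixed references.

Each sample spectrum (normalized to proportions p) is expressed as a
non-negative linear combination of reference profiles R by solving

    min_w || p - R w ||^2   s.t.  w >= 0

with non-negative least squares; reported weights are w normalized to sum
to 1.  Following the deconstructSigs convention, signatures whose
normalized weight falls below a pruning threshold (default 0.06) are
dropped and the remainder refitted, iterating until the active set is
stable.  Fit quality is the cosine between the observed and reconstructed
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import TRINUCLEOTIDES_32, ContextClass, CONTEXT_LABELS
from .errors import ParameterError
from .io import ReferenceSignatureSet
from .nmf import cosine_similarity


@dataclass
class RefitResult:
    """Per-sample relative signature contributions and fit quality."""

    sample_id: str
    weights: dict[str, float]      # signature name -> weight in [0, 1], sum 1
    residual_cosine: float         # cos(observed, reconstructed)
    n_snv: int


def _trinucleotide_rescale(profiles: np.ndarray, weights) -> np.ndarray:
    """Rescale profile rows by a 32-trinucleotide weight vector and renormalize.

    Hook for opportunity-normalization (e.g. exome-to-genome trinucleotide
    frequency correction); ``weights`` maps the pyrimidine-strand reference
    trinucleotide of each context to a multiplier, as a dict or an array in
    :data:`TRINUCLEOTIDES_32` order.
    """
    if not isinstance(weights, dict):
        weights = dict(zip(TRINUCLEOTIDES_32, np.asarray(weights, dtype=float)))
    row_w = np.array(
        [weights[ContextClass.from_label(lab).trinucleotide] for lab in CONTEXT_LABELS]
    )
    scaled = profiles * row_w[:, None]
    return scaled / scaled.sum(axis=0, keepdims=True)


def refit_sample(
    spectrum,
    reference: ReferenceSignatureSet,
    *,
    prune_threshold: float = 0.06,
    trinucleotide_weights=None,
    sample_id: str = "",
) -> RefitResult:
    """Refit one 96-class count spectrum against reference signatures.

    Scale-invariant in the spectrum.  With ``prune_threshold=0`` the result
    is the plain NNLS solution (normalized); otherwise signatures below the
    threshold are zeroed and the fit repeated until stable (the largest
    weight is always retained).
    """
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    if spectrum.shape[0] != 96 or reference.profiles.shape[0] != 96:
        raise ParameterError("spectrum and reference must have 96 context classes")
    total = spectrum.sum()
    if total <= 0:
        raise ParameterError("cannot refit an all-zero spectrum")
    p = spectrum / total
    R = reference.profiles
    if trinucleotide_weights is not None:
        R = _trinucleotide_rescale(R, trinucleotide_weights)

    active = np.arange(R.shape[1])
    while True:
        w_act, _ = nnls(R[:, active], p)
        s = w_act.sum()
        if s <= 0:
            raise ParameterError("NNLS returned an all-zero solution")
        frac = w_act / s
        drop = frac < prune_threshold
        if drop.all():  # keep at least the dominant signature
            drop[np.argmax(frac)] = False
        if not drop.any():
            break
        active = active[~drop]

    w_full = np.zeros(R.shape[1])
    w_full[active] = w_act
    recon = R @ w_full
    weights = dict(zip(reference.names, w_full / w_full.sum()))
    return RefitResult(
        sample_id=sample_id,
        weights={k: float(v) for k, v in weights.items()},
        residual_cosine=cosine_similarity(p, recon),
        n_snv=int(round(total)),
    )


def refit_cohort(
    matrix: pd.DataFrame,
    reference: ReferenceSignatureSet,
    *,
    prune_threshold: float = 0.06,
    trinucleotide_weights=None,
) -> list[RefitResult]:
    """Refit every row of a samples x 96 context matrix, preserving order."""
    return [
        refit_sample(
            matrix.loc[sid].to_numpy(),
            reference,
            prune_threshold=prune_threshold,
            trinucleotide_weights=trinucleotide_weights,
            sample_id=str(sid),
        )
        for sid in matrix.index
    ]


def refit_frame(results: Sequence[RefitResult]) -> pd.DataFrame:
    """Tabulate refit results: one row per sample, one column per signature."""
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, **r.weights,
               "residual_cosine": r.residual_cosine, "n_snv": r.n_snv}
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
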