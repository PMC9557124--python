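"""Synthetic COSMIC-like reference signature profiles.

These are *synthetic stand-ins* that reproduce the qualitative shapes of
the COSMIC v3 SBS signatures reported in cutaneous melanoma — SBS7a/7b
(UV: C>T at dipyrimidine sites, peaking in the TpCpN context), SBS1
(deamination: C>T at NpCpG), SBS5/SBS3 (flat, clock-like / HRD-like) and
SBS38 (indirect UV damage, C>A heavy).  They are built in code, not copied
from COSMIC; magnitudes are plausible but not the published values.  For
analyses against the real catalog, load it with
:func:`melasig.io.read_signature_matrix`.
"""

from __future__ import annotations

import numpy as np

from .contexts import CONTEXT_INDEX, CONTEXT_LABELS, SUBSTITUTIONS
from .io import ReferenceSignatureSet


def _profile(peaks: dict[str, float], background: float = 0.0,
             block_extra: dict[str, float] | None = None) -> np.ndarray:
    """Build a normalized 96-profile from named peaks plus uniform mass.

    ``background`` is total mass spread uniformly over all 96 classes;
    ``block_extra`` maps a substitution (e.g. 'C>A') to total extra mass
    spread uniformly over its 16 classes.
    """
    p = np.full(96, background / 96.0)
    if block_extra:
        for sub, mass in block_extra.items():
            for lab, i in CONTEXT_INDEX.items():
                if lab[2:5] == sub:
                    p[i] += mass / 16.0
    for lab, w in peaks.items():
        p[CONTEXT_INDEX[lab]] += w
    return p / p.sum()


def sbs7a_like() -> np.ndarray:
    """UV signature: C>T dominated, highest at T[C>T]C / T[C>T]T."""
    return _profile(
        {
            "T[C>T]C": 0.28, "T[C>T]T": 0.24, "C[C>T]C": 0.09, "C[C>T]T": 0.08,
            "T[C>T]A": 0.06, "T[C>T]G": 0.05, "C[C>T]A": 0.04,
            "A[C>T]C": 0.02, "G[C>T]C": 0.02,
        },
        background=0.12,
    )


def sbs7b_like() -> np.ndarray:
    """UV signature: C>T spread more evenly over CpC and TpC contexts."""
    return _profile(
        {
            "C[C>T]C": 0.18, "T[C>T]C": 0.16, "C[C>T]T": 0.12, "T[C>T]T": 0.12,
            "A[C>T]C": 0.06, "A[C>T]T": 0.05, "G[C>T]C": 0.05, "G[C>T]T": 0.04,
            "C[C>T]A": 0.04, "T[C>T]A": 0.04,
        },
        background=0.14,
    )


def sbs1_like() -> np.ndarray:
    """Deamination clock: C>T spike at NpCpG."""
    return _profile(
        {"A[C>T]G": 0.22, "C[C>T]G": 0.15, "G[C>T]G": 0.16, "T[C>T]G": 0.24},
        background=0.23,
    )


def sbs5_like() -> np.ndarray:
    """Flat clock-like signature with a mild T>C tilt."""
    return _profile({}, background=0.60, block_extra={"T>C": 0.25, "C>T": 0.15})


def sbs3_like() -> np.ndarray:
    """Flat signature tilted toward C>A / C>G."""
    return _profile({}, background=0.70, block_extra={"C>A": 0.15, "C>G": 0.15})


def sbs38_like() -> np.ndarray:
    """Indirect-UV signature: C>A heavy."""
    return _profile(
        {"T[C>A]T": 0.10, "A[C>A]A": 0.07, "C[C>A]T": 0.06, "T[C>A]A": 0.06},
        background=0.21,
        block_extra={"C>A": 0.50},
    )


def synthetic_cosmic_like() -> ReferenceSignatureSet:
    """Synthetic stand-in for the melanoma COSMIC v3 reference set.

    Contains SBS1, SBS3, SBS5, SBS7a, SBS7b and SBS38 — the signatures
    reported in whole-exome studies of cutaneous melanoma and the default
    refitting reference in this package.
    """
    names = ["SBS1", "SBS3", "SBS5", "SBS7a", "SBS7b", "SBS38"]
    profiles = np.column_stack(
        [sbs1_like(), sbs3_like(), sbs5_like(), sbs7a_like(), sbs7b_like(), sbs38_like()]
    )
    return ReferenceSignatureSet(names, profiles)
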