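"""Library search with forward and reverse match factors.

The match factor (MF) is a weighted-cosine identity score in the NIST
style: both spectra are transformed with weights ``w(m, I) = m * sqrt(I)``
on the union integer m/z grid, and

    MF = round(999 * cos^2(weighted query, weighted library)).

The reverse match factor (RMF) applies the same score after deleting query
peaks at m/z values absent from the library entry, so impurity peaks in the
unknown do not penalize the comparison; RMF >= MF always. Absolute values
from this scorer will not numerically equal those of proprietary library
search engines, but the scale, the 0-999 range and the standard quality
bands carry over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chrom_io import LibrarySpectrum

__all__ = [
    "MatchResult",
    "match_factor",
    "reverse_match_factor",
    "classify_quality",
    "search_library",
    "QUALITY_BANDS",
]

MF_SCALE = 999

# lower bound (inclusive) -> label; the 600-700 band has no published name
# in the standard guidance and is labelled "poor" here by convention
QUALITY_BANDS = (
    (900, "excellent"),
    (800, "good"),
    (700, "fair"),
    (600, "poor"),
    (0, "very poor"),
)


@dataclass(frozen=True)
class MatchResult:
    name: str
    mf: int
    rmf: int
    rank: int
    quality_class: str


def _weighted(mz: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    return mz * np.sqrt(intensity)


def _to_arrays(spec: LibrarySpectrum):
    peaks = sorted(spec.peaks)
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([max(float(p[1]), 0.0) for p in peaks])
    return mz, inten


def _weighted_cos2(q_mz, q_int, l_mz, l_int) -> float:
    union = np.union1d(q_mz, l_mz)
    q = np.zeros(union.size)
    l = np.zeros(union.size)
    q[np.searchsorted(union, q_mz)] = _weighted(q_mz, q_int)
    l[np.searchsorted(union, l_mz)] = _weighted(l_mz, l_int)
    nq, nl = np.linalg.norm(q), np.linalg.norm(l)
    if nq == 0:
        raise ValueError("all-zero query spectrum")
    if nl == 0:
        raise ValueError("all-zero library spectrum")
    cos = float(np.dot(q, l) / (nq * nl))
    return cos * cos


def match_factor(query: LibrarySpectrum, library: LibrarySpectrum) -> int:
    """Forward match factor, 0-999, on the union m/z grid."""
    q_mz, q_int = _to_arrays(query)
    l_mz, l_int = _to_arrays(library)
    return int(round(MF_SCALE * _weighted_cos2(q_mz, q_int, l_mz, l_int)))


def reverse_match_factor(query: LibrarySpectrum,
                         library: LibrarySpectrum) -> int:
    """Reverse match factor: query peaks absent from the library are ignored."""
    q_mz, q_int = _to_arrays(query)
    l_mz, l_int = _to_arrays(library)
    keep = np.isin(q_mz, l_mz)
    q_mz, q_int = q_mz[keep], q_int[keep]
    if q_mz.size == 0 or not np.any(q_int > 0):
        return 0  # nothing in common: worst possible reverse match
    return int(round(MF_SCALE * _weighted_cos2(q_mz, q_int, l_mz, l_int)))


def classify_quality(mf: int) -> str:
    """Map a match factor to its quality band (>=900 excellent, ...)."""
    if not 0 <= mf <= MF_SCALE:
        raise ValueError(f"match factor {mf} outside [0, {MF_SCALE}]")
    for lower, label in QUALITY_BANDS:
        if mf >= lower:
            return label
    raise AssertionError("unreachable")


def search_library(query: LibrarySpectrum, library,
                   top_n: int = 5, min_mf: int = 600) -> list:
    """Rank library entries against a query spectrum.

    Returns up to ``top_n`` hits with MF >= ``min_mf``, sorted by MF
    descending, ties broken by RMF descending then library order.
    """
    scored = []
    for order, entry in enumerate(library):
        mf = match_factor(query, entry)
        if mf < min_mf:
            continue
        rmf = reverse_match_factor(query, entry)
        scored.append((-mf, -rmf, order, entry.name))
    scored.sort()
    return [
        MatchResult(
            name=name,
            mf=-neg_mf,
            rmf=-neg_rmf,
            rank=rank,
            quality_class=classify_quality(-neg_mf),
        )
        for rank, (neg_mf, neg_rmf, _, name) in enumerate(scored[:top_n], start=1)
    ]
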