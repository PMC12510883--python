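"""String metrics and whitelist correction for cell and sample barcodes.

Cell barcodes (BC1/BC2) have a known endpoint within the segmented read and
are corrected to a whitelist entry within Levenshtein distance 1 when that
entry is unique.  The sample barcode sits directly upstream of the UMI, so
an insertion or deletion makes its endpoint unknowable; it is therefore
corrected under *free divergence* — the minimum Levenshtein distance from
the whitelist barcode to any prefix of the observed window — with a margin
rule: accept the best entry only if no other entry is within one unit of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import edlib

from .barcode_schema import SchemaError, Whitelist

__all__ = [
    "CorrectionResult",
    "levenshtein",
    "free_divergence",
    "correct_fixed_bc",
    "correct_sample_bc",
    "SAMPLE_BC_WINDOW_EXTRA",
]

# Bases of read context taken past the sample-barcode segment (spilling into
# the UMI) when building the free-divergence observation window: insertions
# shift the true barcode end rightward and the surplus is tolerated by the
# metric.
SAMPLE_BC_WINDOW_EXTRA = 2


@dataclass(frozen=True)
class CorrectionResult:
    observed: str
    corrected: str | None
    distance: int | None
    reason: str  # "none" (success), "no_candidate", or "ambiguous"

    def __post_init__(self):
        if (self.corrected is None) != (self.reason != "none"):
            raise ValueError("corrected must be null exactly when rejected")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def free_divergence(barcode: str, observed_window: str) -> int:
    """Minimum Levenshtein distance from ``barcode`` to any prefix of
    ``observed_window`` (including the empty prefix and the whole window).

    Zero iff the barcode is a prefix of (or equals) the window; never larger
    than the plain Levenshtein distance to the full window.  Asymmetric.
    """
    if not barcode:
        return 0
    if not observed_window:
        return len(barcode)
    # Prefix-mode alignment: trailing gap in the target is free, which is
    # exactly the min-over-prefixes Levenshtein distance.
    return edlib.align(barcode, observed_window, mode="SHW", task="distance")["editDistance"]


def correct_fixed_bc(
    observed: str, whitelist: Whitelist, max_dist: int = 1
) -> CorrectionResult:
    """Correct a fixed-endpoint barcode: unique whitelist entry within
    ``max_dist`` Levenshtein edits, else rejected."""
    if not observed:
        return CorrectionResult(observed, None, None, "no_candidate")
    hits = _fixed_bc_hits(observed, whitelist.barcodes, max_dist)
    if len(hits) == 1:
        bc, d = hits[0]
        return CorrectionResult(observed, bc, d, "none")
    if not hits:
        return CorrectionResult(observed, None, None, "no_candidate")
    return CorrectionResult(observed, None, None, "ambiguous")


@lru_cache(maxsize=1_000_000)
def _fixed_bc_hits(
    observed: str, barcodes: tuple[str, ...], max_dist: int
) -> tuple[tuple[str, int], ...]:
    hits = []
    for bc in barcodes:
        d = edlib.align(bc, observed, mode="NW", task="distance", k=max_dist)["editDistance"]
        if d != -1:
            hits.append((bc, d))
    return tuple(hits)


def correct_sample_bc(observed_window: str, whitelist: Whitelist) -> CorrectionResult:
    """Correct a sample barcode under free divergence with a margin rule.

    Let d* be the minimum free divergence over the whitelist, achieved by w.
    Accept w iff d* <= 1 and no *other* entry has free divergence <= d* + 1;
    otherwise reject as ambiguous (margin violated) or no_candidate (d* > 1).
    The margin is applied literally even at d* = 0.
    """
    if not observed_window:
        return CorrectionResult(observed_window, None, None, "no_candidate")
    return _sample_bc_cached(observed_window, whitelist.barcodes)


@lru_cache(maxsize=1_000_000)
def _sample_bc_cached(
    observed_window: str, barcodes: tuple[str, ...]
) -> CorrectionResult:
    divergences = [(free_divergence(bc, observed_window), bc) for bc in barcodes]
    d_star, best = min(divergences)
    if d_star > 1:
        return CorrectionResult(observed_window, None, None, "no_candidate")
    for d, bc in divergences:
        if bc != best and d <= d_star + 1:
            return CorrectionResult(observed_window, None, None, "ambiguous")
    return CorrectionResult(observed_window, best, d_star, "none")
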