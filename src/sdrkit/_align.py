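"""Batched semi-global alignment of reads against a backbone template.

The backbone must align end to end; the read aligns from its start and may
extend past the backbone (the surplus is payload).  Scoring is linear
(match / mismatch / gap), with 'N' template positions matching any read base
at the match score.  The dynamic program is vectorised across a batch of
reads: both loops run over the (short) template and read dimensions while
every cell update operates on the whole batch at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}
_N_CODE = _BASE_CODE["N"]
_PAD = 5  # padding code for positions past a read's end

_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -1


def encode_sequences(seqs: list[str], length: int) -> np.ndarray:
    """Encode sequences into a (n, length) uint8 matrix, padded with _PAD."""
    arr = np.full((len(seqs), length), _PAD, dtype=np.uint8)
    for i, s in enumerate(seqs):
        row = np.frombuffer(s[:length].encode(), dtype=np.uint8)
        codes = _CODE_LUT[row]
        arr[i, : len(codes)] = codes
    return arr


_CODE_LUT = np.full(256, _N_CODE, dtype=np.uint8)
for _c, _i in _BASE_CODE.items():
    _CODE_LUT[ord(_c)] = _i
    _CODE_LUT[ord(_c.lower())] = _i


@dataclass
class BatchAlignment:
    """Per-read results of fitting one template against a read batch."""

    scores: np.ndarray  # (n,) best raw score with template fully aligned
    ends: np.ndarray  # (n,) read position just past the last template-aligned base
    boundaries: np.ndarray  # (n, tlen+1) read position where template row i begins


def fit_template_batch(
    reads: list[str],
    template: str,
    scoring: Scoring = Scoring(),
    traceback: bool = True,
) -> BatchAlignment:
    """Align ``template`` (fully) against a prefix of each read.

    Returns, per read, the optimal raw score, the read offset where the
    template alignment ends, and (if ``traceback``) the projection of every
    template position onto the read: ``boundaries[r, i]`` is the read offset
    where template position ``i`` starts, so the read substring observed for
    a template interval [a, b) is ``read[boundaries[a]:boundaries[b]]``.
    """
    n = len(reads)
    tlen = len(template)
    rmax = max((len(r) for r in reads), default=0)
    read_lens = np.fromiter((len(r) for r in reads), dtype=np.int64, count=n)
    enc = encode_sequences(reads, rmax)
    tmpl = encode_sequences([template], tlen)[0]

    match, mismatch, gap = scoring.match, scoring.mismatch, scoring.gap
    neg_inf = np.iinfo(np.int32).min // 2

    # H has shape (n, rmax+1): current template row of the DP matrix.
    H = np.empty((n, rmax + 1), dtype=np.int32)
    H[:, 0] = 0
    H[:, 1:] = gap * np.arange(1, rmax + 1, dtype=np.int32)[None, :]
    # Forbid alignment ends past each read's true length.
    col_valid = np.arange(rmax + 1)[None, :] <= read_lens[:, None]

    if traceback:
        D = np.zeros((tlen + 1, n, rmax + 1), dtype=np.uint8)
        D[0, :, 1:] = _LEFT

    prev = np.empty_like(H)
    for i in range(1, tlen + 1):
        prev, H = H, prev
        tchar = tmpl[i - 1]
        if tchar == _N_CODE:
            sub = np.full((n, rmax), match, dtype=np.int32)
            sub[enc == _PAD] = mismatch
        else:
            sub = np.where(enc == tchar, match, mismatch).astype(np.int32)
        H[:, 0] = prev[:, 0] + gap
        if traceback:
            D[i, :, 0] = _UP
        diag = prev[:, :-1] + sub  # candidate for H[:, 1:]
        up = prev[:, 1:] + gap
        # left dependency is sequential along the read axis
        for j in range(1, rmax + 1):
            left = H[:, j - 1] + gap
            best = np.maximum(np.maximum(diag[:, j - 1], up[:, j - 1]), left)
            H[:, j] = best
            if traceback:
                # tie preference: diagonal, then template gap, then read gap
                d = np.full(n, _LEFT, dtype=np.uint8)
                d[up[:, j - 1] == best] = _UP
                d[diag[:, j - 1] == best] = _DIAG
                D[i, :, j] = d

    final = np.where(col_valid, H, neg_inf)
    ends = final.argmax(axis=1).astype(np.int64)
    scores = final[np.arange(n), ends]

    boundaries = np.zeros((n, tlen + 1), dtype=np.int64)
    if traceback:
        for r in range(n):
            i, j = tlen, int(ends[r])
            boundaries[r, tlen] = j
            while i > 0:
                d = D[i, r, j]
                if d == _DIAG:
                    i -= 1
                    j -= 1
                    boundaries[r, i] = j
                elif d == _UP:
                    i -= 1
                    boundaries[r, i] = j
                else:
                    j -= 1
    else:
        boundaries[:, tlen] = ends
    return BatchAlignment(scores=scores, ends=ends, boundaries=boundaries)
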