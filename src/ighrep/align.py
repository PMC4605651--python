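"""Local alignment of consensus reads against germline reference sets.

The annotation stage needs only one thing from an aligner: the best local
(Smith-Waterman) hit of a consensus read against a small set of V-segment or
constant-region references, with enough detail to derive a somatic mutation
count (mismatches in the aligned V region) and an identity fraction. BLAST-like
heuristics are unnecessary at this scale, so the aligner is an exact
affine-gap Smith-Waterman, JIT-compiled with numba so that the full pipeline
(~10^6 alignments per cohort) stays fast.

Scoring convention: ``match`` is added per identical column, ``mismatch`` per
substitution column; a gap of length L scores ``gap_open + (L-1)*gap_extend``
(the opening score covers the first gapped base). Defaults: +1/-1/-2/-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lowercase

#: codes 0..3 = A,C,G,T (lexicographic order matters for consensus tie-breaks)
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3).

    Characters outside ACGT (e.g. N) get code 255 and never match anything.
    """
    arr = _BASE_TO_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    return arr


def decode(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = BASES[codes[ok]]
    return out.tobytes().decode("ascii")


@dataclass(frozen=True)
class AlignParams:
    """Aligner scores and best-hit acceptance cutoffs."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_identity: float = 0.80
    min_len: int = 40


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a query against one reference."""

    reference_id: str
    score: float
    identity: float
    mismatches: int  # substitution columns + gap columns
    aligned_length: int  # alignment columns including gaps
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.mismatches > self.aligned_length:
            raise ValueError("mismatches cannot exceed aligned length")


@njit(cache=True)
def _sw_score(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    # single rolling row: h[j] holds H[i-1][j] until overwritten, diag = H[i-1][j-1]
    n, m = q.shape[0], r.shape[0]
    h = np.zeros(m + 1, dtype=np.int64)
    e = np.full(m + 1, -(10 ** 9), dtype=np.int64)
    best = 0
    for i in range(n):
        qi = q[i]
        diag = 0
        f = -(10 ** 9)
        prev = 0  # H[i][j-1]
        for j in range(1, m + 1):
            up = h[j]
            ev = up + gap_open
            e2 = e[j] + gap_extend
            if e2 > ev:
                ev = e2
            e[j] = ev
            fv = prev + gap_open
            f2 = f + gap_extend
            if f2 > fv:
                fv = f2
            f = fv
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            hv = diag + s
            if ev > hv:
                hv = ev
            if fv > hv:
                hv = fv
            if hv < 0:
                hv = 0
            diag = up
            h[j] = hv
            prev = hv
            if hv > best:
                best = hv
    return best


@njit(cache=True)
def _sw_align(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Full DP with traceback.

    Returns (score, q_start, q_end, r_start, r_end, matches, mismatch_cols,
    gap_cols). End coordinates are exclusive. Traceback prefers diagonal over
    vertical over horizontal moves and, among equal-scoring end cells, the
    first one in row-major order — all deterministic.
    """
    n, m = q.shape[0], r.shape[0]
    # rolling rows + packed traceback bytes:
    #   bits 0-1: H source (0=stop/zero, 1=diagonal, 2=E/vertical, 3=F/horizontal)
    #   bit 2: E opened here (vs extended);  bit 3: F opened here (vs extended)
    tb = np.zeros((n, m), dtype=np.uint8)
    h = np.zeros(m + 1, dtype=np.int64)
    e = np.full(m + 1, -(10 ** 9), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(n):
        qi = q[i]
        diag = 0
        f = -(10 ** 9)
        prev = 0
        for j in range(1, m + 1):
            up = h[j]
            flags = np.uint8(0)
            ev = up + gap_open
            e2 = e[j] + gap_extend
            if ev >= e2:
                flags |= 4
            else:
                ev = e2
            e[j] = ev
            fv = prev + gap_open
            f2 = f + gap_extend
            if fv >= f2:
                flags |= 8
            else:
                fv = f2
            f = fv
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            hv = diag + s
            src = np.uint8(1)
            if ev > hv:
                hv = ev
                src = np.uint8(2)
            if fv > hv:
                hv = fv
                src = np.uint8(3)
            if hv <= 0:
                # local alignment restarts at score zero
                hv = 0
                src = np.uint8(0)
            tb[i, j - 1] = flags | src
            diag = up
            h[j] = hv
            prev = hv
            if hv > best:
                best = hv
                bi = i + 1
                bj = j
    # traceback over packed bytes
    i, j = bi, bj
    matches = 0
    mism = 0
    gaps = 0
    state = 0  # 0=H, 1=E (vertical), 2=F (horizontal)
    while i > 0 and j > 0:
        cell = tb[i - 1, j - 1]
        if state == 0:
            src = cell & 3
            if src == 0:
                break
            if src == 1:
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    matches += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            gaps += 1
            if cell & 4:
                state = 0
            i -= 1
        else:
            gaps += 1
            if cell & 8:
                state = 0
            j -= 1
    return best, i, bi, j, bj, matches, mism, gaps


# warm-up happens lazily on first use; numba caches compiled kernels on disk.


def smith_waterman(
    query: str | np.ndarray, ref: str | np.ndarray, params: AlignParams = AlignParams()
) -> Tuple[float, int, int, int, int, int, int, int]:
    """Exact local alignment of ``query`` vs ``ref``.

    Returns (score, q_start, q_end, r_start, r_end, matches, mismatch_cols,
    gap_cols).
    """
    q = encode(query) if isinstance(query, str) else query
    r = encode(ref) if isinstance(ref, str) else ref
    if q.size == 0 or r.size == 0:
        raise ValueError("cannot align empty sequences")
    res = _sw_align(
        q, r, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    return (float(res[0]),) + tuple(int(x) for x in res[1:])  # type: ignore[return-value]


def align_to_references(
    seq: str | np.ndarray,
    refs: Sequence[Tuple[str, str | np.ndarray]],
    params: AlignParams = AlignParams(),
) -> Optional[AlignmentHit]:
    """Best local hit of ``seq`` against an ordered reference set.

    The highest-scoring reference wins; ties go to the earlier reference in
    ``refs`` (deterministic). Returns ``None`` (no hit) when the best
    alignment has identity below ``params.min_identity`` or spans fewer than
    ``params.min_len`` columns. Gap columns count as one mismatch each toward
    the hit's ``mismatches``; identity is matches over alignment columns.
    """
    q = encode(seq) if isinstance(seq, str) else seq
    if q.size == 0:
        raise ValueError("cannot align an empty sequence")
    if len(refs) == 0:
        raise ValueError("empty reference set")
    best_score = -np.inf
    best_idx = -1
    encoded = []
    for idx, (_rid, rseq) in enumerate(refs):
        r = encode(rseq) if isinstance(rseq, str) else rseq
        if r.size == 0:
            raise ValueError("empty reference sequence")
        encoded.append(r)
        score = _sw_score(
            q, r, params.match, params.mismatch, params.gap_open, params.gap_extend
        )
        if score > best_score:
            best_score = score
            best_idx = idx
    score, qs, qe, rs, re_, matches, mism, gaps = smith_waterman(
        q, encoded[best_idx], params
    )
    cols = matches + mism + gaps
    if cols == 0:
        return None
    identity = matches / cols
    if identity < params.min_identity or cols < params.min_len:
        return None
    return AlignmentHit(
        reference_id=refs[best_idx][0],
        score=score,
        identity=identity,
        mismatches=mism + gaps,
        aligned_length=cols,
        query_start=qs,
        query_end=qe,
        ref_start=rs,
        ref_end=re_,
    )
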