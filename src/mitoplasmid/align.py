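"""Local nucleotide alignment with Karlin–Altschul E-value statistics.

Two engines behind one interface:

* ``seed`` — BLAST-like seed-and-extend: exact word seeds locate candidate
  diagonals, and the optimal ungapped segment(s) on each diagonal are
  extracted exactly (best-scoring subarray of the per-position score
  profile). Scales to full contigs.
* ``dp`` — exact affine-gap Smith–Waterman (numba kernels, linear-memory
  score passes plus a windowed traceback), used automatically for small
  inputs and available on demand for anything up to chromosome-arm scale.

Raw scores are converted to E-values with E = K·m·n·exp(−λS); λ solves the
Karlin–Altschul identity for the ungapped scores and background base
frequencies, and K comes from the standard ungapped series approximation.
Gapped alignments reuse the ungapped λ/K (a documented approximation, as in
classical BLAST).

The default scoring follows classical BLASTn: match +2, mismatch −3, gap
open 5, gap extend 2 (a gap of length k costs 5 + 2k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .seqs import SequenceRecord, encode, revcomp

MASK_CODE = 5  # residue code excluded from any match (used for segment masking)
_NEG = -10**6


class NoSolutionError(ValueError):
    """Raised when the Karlin–Altschul identity has no positive root."""


@dataclass
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus calibrated λ and K.

    Gap penalties are stored as positive magnitudes; ``background`` are the
    base frequencies (A, C, G, T) used for the statistics.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lam: float | None = None
    K: float | None = None

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive magnitudes")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    def calibrated(self) -> "ScoringScheme":
        return self if self.lam is not None else estimate_karlin_altschul(self)

    @property
    def p_match(self) -> float:
        return float(sum(p * p for p in self.background))


def blastn_scheme() -> ScoringScheme:
    """The classical BLASTn dialect printed in most methods sections."""
    return ScoringScheme().calibrated()


def megablast_scheme() -> ScoringScheme:
    """A megablast-like dialect: larger word, softer mismatch (+1/−2)."""
    return ScoringScheme(match=1, mismatch=-2, gap_open=2, gap_extend=2,
                         word_size=28).calibrated()


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics


def _ka_identity(lam: float, scheme: ScoringScheme) -> float:
    pm = scheme.p_match
    return pm * math.exp(lam * scheme.match) + (1 - pm) * math.exp(lam * scheme.mismatch) - 1.0


def estimate_karlin_altschul(scheme: ScoringScheme, k_terms: int = 80) -> ScoringScheme:
    """Solve λ to residual ≤ 1e−9 and set K by the ungapped series formula.

    λ is the positive root of  Σ_ij p_i p_j exp(λ s_ij) = 1.  K is computed
    from the per-step score distribution via the classical series
    C = exp(−2 Σ_k k⁻¹ [E(e^{λS_k}; S_k<0) + P(S_k ≥ 0)]) on the score
    lattice with span d, giving K = C·d / (A·(1−e^{−λd})) where A is the
    mean step of the λ-conjugate walk (so λ·A is the relative entropy H).
    """
    pm = scheme.p_match
    expected = pm * scheme.match + (1 - pm) * scheme.mismatch
    if expected >= 0:
        raise NoSolutionError(
            f"expected score per aligned pair is {expected:.3f} >= 0; "
            "no Karlin-Altschul statistics exist for this scheme")
    hi = 1.0
    while _ka_identity(hi, scheme) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - cannot happen with expected < 0
            raise NoSolutionError("failed to bracket lambda")
    lam = float(brentq(_ka_identity, 1e-12, hi, args=(scheme,), xtol=1e-15, rtol=1e-15))
    # polish by Newton so the residual is comfortably below 1e-9
    for _ in range(4):
        f = _ka_identity(lam, scheme)
        df = (pm * scheme.match * math.exp(lam * scheme.match)
              + (1 - pm) * scheme.mismatch * math.exp(lam * scheme.mismatch))
        lam -= f / df

    # per-step score pmf on the integer lattice
    d = math.gcd(abs(scheme.match), abs(scheme.mismatch))
    lo = min(scheme.match, scheme.mismatch)
    span = abs(scheme.match - scheme.mismatch) + 1
    step = np.zeros(span)
    step[scheme.match - lo] = pm
    step[scheme.mismatch - lo] = 1 - pm

    total = 0.0
    pmf = np.array([1.0])
    offset = 0  # value of index 0
    for k in range(1, k_terms + 1):
        pmf = np.convolve(pmf, step)
        offset += lo
        values = offset + np.arange(len(pmf))
        neg = values < 0
        term = float(np.sum(pmf[neg] * np.exp(lam * values[neg])) + np.sum(pmf[~neg]))
        total += term / k
        if term < 1e-14:
            break
    C = math.exp(-2.0 * total)
    A = (pm * scheme.match * math.exp(lam * scheme.match)
         + (1 - pm) * scheme.mismatch * math.exp(lam * scheme.mismatch))
    K = C * d / (A * (1.0 - math.exp(-lam * d)))
    return replace(scheme, lam=lam, K=K)


def evalue_of(score: float, query_len: int, subject_len: int, scheme: ScoringScheme) -> float:
    """E = K·m·n·exp(−λS); linear in each sequence length."""
    if scheme.lam is None or scheme.K is None:
        raise ValueError("scheme is not calibrated; call .calibrated() first")
    return scheme.K * query_len * subject_len * math.exp(-scheme.lam * score)


# ---------------------------------------------------------------------------
# Segments


@dataclass
class HomologySegment:
    """A scored local alignment between a query and a subject sequence.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; ``strand`` records whether the reverse complement of the
    query was aligned.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    length: int
    identity: float
    evalue: float
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be >= 1")


def filter_segments(segments: Iterable[HomologySegment], min_len: int = 50,
                    max_e: float = 1e-3) -> list[HomologySegment]:
    """Keep segments strictly longer than ``min_len`` with E strictly below ``max_e``."""
    return [s for s in segments if s.length > min_len and s.evalue < max_e]


def segments_to_outfmt6(segments: Sequence[HomologySegment]) -> "pd.DataFrame":
    """Tabular export in BLAST outfmt-6 column order (1-based inclusive coords).

    On the minus strand the subject interval is reported descending, as
    BLAST does.
    """
    import pandas as pd

    rows = []
    for s in segments:
        if s.strand == "+":
            ss, se = s.s_start + 1, s.s_end
        else:
            ss, se = s.s_end, s.s_start + 1
        rows.append({
            "qseqid": s.query_id, "sseqid": s.subject_id,
            "pident": round(100.0 * s.identity, 3), "length": s.length,
            "mismatch": s.mismatches, "gapopen": s.gap_opens,
            "qstart": s.q_start + 1, "qend": s.q_end,
            "sstart": ss, "send": se,
            "evalue": s.evalue,
            "bitscore": round(_bitscore(s), 3),
        })
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    return pd.DataFrame(rows, columns=cols)


def _bitscore(seg: HomologySegment) -> float:
    # raw score in half-bit-ish units using the default calibration
    sch = _default_calibrated()
    return (sch.lam * seg.score - math.log(sch.K)) / math.log(2.0)


_DEFAULT_CAL: ScoringScheme | None = None


def _default_calibrated() -> ScoringScheme:
    global _DEFAULT_CAL
    if _DEFAULT_CAL is None:
        _DEFAULT_CAL = ScoringScheme().calibrated()
    return _DEFAULT_CAL


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _kadane_multi(scores, floor, max_segs, starts, ends, totals):  # pragma: no cover - jit
    """Repeatedly extract the best-scoring subarray, masking each find."""
    n = scores.shape[0]
    found = 0
    for _ in range(max_segs):
        best = -1.0
        best_s = 0
        best_e = 0
        cur = 0.0
        cur_s = 0
        for i in range(n):
            if cur <= 0.0:
                cur = scores[i]
                cur_s = i
            else:
                cur += scores[i]
            if cur > best:
                best = cur
                best_s = cur_s
                best_e = i + 1
        if best < floor:
            break
        starts[found] = best_s
        ends[found] = best_e
        totals[found] = best
        found += 1
        for i in range(best_s, best_e):
            scores[i] = -1.0e9
    return found


@njit(cache=True)
def _sw_end(q, s, match, mismatch, gox, gex):  # pragma: no cover - jit
    """Affine local DP, linear memory; returns (best score, end_i, end_j)."""
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, -10**9, dtype=np.int64)  # vertical gaps, per column
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qa = q[i - 1]
        diag = 0  # H[i-1][0]
        e = -10**9  # horizontal gap state, carried along the row
        H[0] = 0
        for j in range(1, n + 1):
            sb = s[j - 1]
            if qa == sb and qa < 4:
                sub = match
            elif qa >= MASK_CODE or sb >= MASK_CODE:
                sub = _NEG
            else:
                sub = mismatch
            e = max(H[j - 1] - gox - gex, e - gex)
            f = max(H[j] - gox - gex, F[j] - gex)
            h = diag + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            F[j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _sw_window(q, s, match, mismatch, gox, gex):  # pragma: no cover - jit
    """Full-pointer local DP over a window; returns matrices for traceback."""
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int64)
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up(del), 3 left(ins)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qa = q[i - 1]
        for j in range(1, n + 1):
            sb = s[j - 1]
            if qa == sb and qa < 4:
                sub = match
            elif qa >= MASK_CODE or sb >= MASK_CODE:
                sub = _NEG
            else:
                sub = mismatch
            e = max(H[i, j - 1] - gox - gex, E[i, j - 1] - gex)
            f = max(H[i - 1, j] - gox - gex, F[i - 1, j] - gex)
            h = H[i - 1, j - 1] + sub
            p = 1
            if e > h:
                h = e
                p = 3
            if f > h:
                h = f
                p = 2
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr


_WINDOW_CELL_LIMIT = 64_000_000  # pointer-matrix window cap (int8 ~ 64 MB)


def _dp_one_segment(qc: np.ndarray, sc: np.ndarray, scheme: ScoringScheme):
    """One optimal local alignment: linear-memory end/start passes + windowed traceback."""
    best, bi, bj = _sw_end(qc, sc, scheme.match, scheme.mismatch,
                           scheme.gap_open, scheme.gap_extend)
    if best <= 0:
        return None
    # reverse pass on the reversed prefixes locates the alignment start
    rbest, ri, rj = _sw_end(qc[:bi][::-1].copy(), sc[:bj][::-1].copy(),
                            scheme.match, scheme.mismatch,
                            scheme.gap_open, scheme.gap_extend)
    i0, j0 = bi - ri, bj - rj
    if (bi - i0 + 1) * (bj - j0 + 1) > _WINDOW_CELL_LIMIT:
        raise MemoryError("alignment window too large for traceback")
    wbest, wi, wj, ptr = _sw_window(qc[i0:bi], sc[j0:bj], scheme.match,
                                    scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    # trace back from the window optimum
    i, j = wi, wj
    matches = mismatches = gap_opens = aln_len = 0
    prev_gap = False
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if qc[i0 + i - 1] == sc[j0 + j - 1] and qc[i0 + i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
            prev_gap = False
        elif p == 2:
            if not prev_gap:
                gap_opens += 1
            i -= 1
            prev_gap = True
        else:
            if not prev_gap:
                gap_opens += 1
            j -= 1
            prev_gap = True
        aln_len += 1
    return (int(wbest), i0 + i, i0 + wi, j0 + j, j0 + wj,
            matches, mismatches, gap_opens, aln_len)


def _dp_segments(qc: np.ndarray, sc: np.ndarray, scheme: ScoringScheme,
                 floor: int, max_segments: int):
    qc = qc.copy()
    sc = sc.copy()
    out = []
    for _ in range(max_segments):
        res = _dp_one_segment(qc, sc, scheme)
        if res is None or res[0] < floor:
            break
        out.append(res)
        _, qs, qe, ss, se, *_ = res
        qc[qs:qe] = MASK_CODE
        sc[ss:se] = MASK_CODE
    return out


# ---------------------------------------------------------------------------
# seed-and-extend engine


def _words(codes: np.ndarray, w: int) -> np.ndarray:
    """Rolling exact-word hashes; positions containing N/mask hash to −1."""
    n = codes.shape[0]
    if n < w:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    ok = np.ones(n - w + 1, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(~valid)))
    ok = (csum[w:] - csum[:-w]) == 0
    h = np.zeros(n - w + 1, dtype=np.int64)
    c = codes.astype(np.int64)
    for k in range(w):
        h = h * 4 + c[k: n - w + 1 + k]
    h[~ok] = -1
    return h


def _seed_diagonals(qc: np.ndarray, sc: np.ndarray, w: int,
                    max_diagonals: int = 5000) -> np.ndarray:
    qw = _words(qc, w)
    sw = _words(sc, w)
    if qw.size == 0 or sw.size == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(sw, kind="stable")
    sw_sorted = sw[order]
    lo = np.searchsorted(sw_sorted, qw, side="left")
    hi = np.searchsorted(sw_sorted, qw, side="right")
    counts = hi - lo
    counts[qw < 0] = 0  # words containing N never seed
    hit_q = np.repeat(np.arange(qw.size), counts)
    if hit_q.size == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.concatenate([np.arange(a, a + c) for a, c in zip(lo, counts) if c])
    hit_s = order[idx]
    diags = hit_s - hit_q
    if diags.size == 0:
        return np.empty(0, dtype=np.int64)
    uniq, cnt = np.unique(diags, return_counts=True)
    if uniq.size > max_diagonals:
        keep = np.argsort(-cnt)[:max_diagonals]
        uniq = uniq[keep]
    return np.sort(uniq)


def _diagonal_segments(qc: np.ndarray, sc: np.ndarray, d: int,
                       scheme: ScoringScheme, floor: int, max_segs: int = 10):
    m, n = qc.shape[0], sc.shape[0]
    qlo = max(0, -d)
    qhi = min(m, n - d)
    if qhi - qlo < 1:
        return []
    qseg = qc[qlo:qhi]
    sseg = sc[qlo + d: qhi + d]
    eq = (qseg == sseg) & (qseg < 4)
    bad = (qseg >= MASK_CODE) | (sseg >= MASK_CODE)
    scores = np.where(eq, float(scheme.match), float(scheme.mismatch))
    scores[bad] = -1.0e9
    starts = np.zeros(max_segs, dtype=np.int64)
    ends = np.zeros(max_segs, dtype=np.int64)
    totals = np.zeros(max_segs, dtype=np.float64)
    k = _kadane_multi(scores, float(floor), max_segs, starts, ends, totals)
    out = []
    for t in range(k):
        a, b = int(starts[t]), int(ends[t])
        nmatch = int(eq[a:b].sum())
        out.append((int(totals[t]), qlo + a, qlo + b, qlo + d + a, qlo + d + b,
                    nmatch, (b - a) - nmatch, 0, b - a))
    return out


# ---------------------------------------------------------------------------
# public alignment interface

DP_AUTO_CELLS = 4_000_000


def local_align(query: SequenceRecord, subject: SequenceRecord,
                scheme: ScoringScheme | None = None, method: str = "auto",
                min_raw_score: int = 24, max_segments: int = 50,
                both_strands: bool = True) -> list[HomologySegment]:
    """Locally align ``query`` against ``subject`` on both strands.

    Returns non-overlapping segments above ``min_raw_score``, highest score
    first (ties by leftmost query start). ``method`` is one of ``auto``
    (exact DP for small inputs, seed-and-extend otherwise), ``dp`` or
    ``seed``.
    """
    if not query.residues or not subject.residues:
        return []
    scheme = (scheme or ScoringScheme()).calibrated()
    qc_fwd = encode(query.residues)
    sc = encode(subject.residues)
    m, n = len(qc_fwd), len(sc)
    if method == "auto":
        method = "dp" if m * n <= DP_AUTO_CELLS else "seed"

    raw: list[tuple] = []  # (score, qs, qe, ss, se, match, mism, gapo, alen, strand)
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        qc = qc_fwd if strand == "+" else encode(revcomp(query.residues))
        if method == "dp":
            hits = _dp_segments(qc, sc, scheme, min_raw_score, max_segments)
        elif method == "seed":
            hits = []
            for d in _seed_diagonals(qc, sc, scheme.word_size):
                hits.extend(_diagonal_segments(qc, sc, int(d), scheme, min_raw_score))
        else:
            raise ValueError(f"unknown method {method!r}")
        for (score, qs, qe, ss, se, nm, mm, go, alen) in hits:
            if strand == "-":
                qs, qe = m - qe, m - qs
            raw.append((score, qs, qe, ss, se, nm, mm, go, alen, strand))

    raw.sort(key=lambda r: (-r[0], r[1], r[3]))
    kept: list[tuple] = []
    for r in raw:
        clash = False
        for k in kept:
            if r[1] < k[2] and k[1] < r[2] and r[3] < k[4] and k[3] < r[4]:
                clash = True
                break
        if not clash:
            kept.append(r)
        if len(kept) >= max_segments:
            break

    segments = []
    for (score, qs, qe, ss, se, nm, mm, go, alen, strand) in kept:
        segments.append(HomologySegment(
            query_id=query.id, subject_id=subject.id,
            q_start=qs, q_end=qe, s_start=ss, s_end=se, strand=strand,
            score=int(score), length=int(alen),
            identity=nm / alen if alen else 0.0,
            evalue=evalue_of(score, m, n, scheme),
            mismatches=mm, gap_opens=go))
    return segments
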