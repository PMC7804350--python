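"""Repeat detection: interspersed repeats by seeded self-alignment, tandem
repeats by period search, and shared fragments across sequence sets.

The interspersed-repeat engine is a purpose-built seed-and-extend local
aligner (it is deliberately not a BLAST wrapper): exact 11-mer seeds on the
same and the opposite strand, banded X-drop extension, rescoring of the
final interval pair with an affine-gap alignment (match +2, mismatch -3,
gap open -5, extend -2), and a Karlin–Altschul-style e-value

    E = K * m * n * exp(-lambda * S)

with lambda solved from the scoring scheme at equal base frequencies and a
fixed K = 0.41.  Circular genomes are searched on the doubled sequence so
origin-spanning repeats are found, and hits are de-duplicated modulo genome
length.  Counts on real accessions therefore approximate, but need not
equal, BLASTN output at the same threshold.

Tandem repeats are found by period search: for each candidate unit length p
the sequence is compared with itself shifted by p; maximal runs of matches
(merging across isolated mismatches while per-base identity stays >= 80%)
of total span >= 2 units are reported with their consensus unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_model import Mitogenome, revcomp
from .pairalign import AlignParams, align_global

__all__ = [
    "RepeatHit", "TandemRepeat",
    "self_repeats", "cross_repeats", "tandem_repeats", "total_aligned_bp",
]

SEED_K = 11
MATCH, MISMATCH = 2, -3
GAP_OPEN, GAP_EXTEND = -5, -2
_GAP_LINEAR = -7          # boundary-finding approximation of open+extend
KA_K = 0.41
_BAND = 6
_XDROP = 20
_MAX_SEED_OCC = 50        # skip ultra-low-complexity seeds
_MAX_HIT_LEN = 20000      # sanity cap on a single hit's span

REPEAT_ALN_PARAMS = AlignParams(match=MATCH, mismatch=MISMATCH,
                                gap_open=GAP_OPEN, gap_extend=GAP_EXTEND)


def _karlin_lambda(match: float = MATCH, mismatch: float = MISMATCH) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 at equal base frequencies."""
    lo, hi = 1e-6, 5.0
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


KA_LAMBDA = _karlin_lambda()


@dataclass
class RepeatHit:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    length: int               # alignment span (columns)
    identity: float           # percent
    score: float
    evalue_like: float
    strand: int = 1           # +1 direct/direct, -1 direct/reverse


@dataclass
class TandemRepeat:
    start: int
    unit_length: int
    copies: float
    consensus: str
    span: int


def _evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


# ---------------------------------------------------------------------------
# seed and extend
# ---------------------------------------------------------------------------

def _kmer_index(s: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        idx.setdefault(s[i:i + k], []).append(i)
    return idx


def _xdrop_dir(a: str, b: str, ai: int, bi: int, step: int) -> tuple[int, int]:
    """Banded X-drop extension; returns consumed lengths (along a, along b).

    ``step`` +1 extends right starting at (ai, bi); -1 extends left from
    (ai-1, bi-1).  Linear gap penalty; the caller rescores with affine gaps.
    """
    if step == 1:
        amax, bmax = len(a) - ai, len(b) - bi
        ach = lambda u: a[ai + u - 1]
        bch = lambda v: b[bi + v - 1]
    else:
        amax, bmax = ai, bi
        ach = lambda u: a[ai - u]
        bch = lambda v: b[bi - v]
    best = 0.0
    best_uv = (0, 0)
    NEG = -1e18
    prev = {0: 0.0}
    u = 0
    while prev and u < amax:
        u += 1
        cur: dict[int, float] = {}
        for d in range(-_BAND, _BAND + 1):
            v = u + d
            if v < 0 or v > bmax:
                continue
            s = NEG
            if v > 0:
                p = prev.get(d)
                if p is not None:
                    s = max(s, p + (MATCH if ach(u) == bch(v) else MISMATCH))
            p = prev.get(d + 1)
            if p is not None:          # gap in b: consume a only
                s = max(s, p + _GAP_LINEAR)
            q = cur.get(d - 1)
            if q is not None:          # gap in a: consume b only
                s = max(s, q + _GAP_LINEAR)
            if s > NEG / 2:
                cur[d] = s
                if s > best:
                    best = s
                    best_uv = (u, v)
        cur = {d: s for d, s in cur.items() if s > best - _XDROP}
        prev = cur
    return best_uv


def _extend_seed(a: str, b: str, i: int, j: int, k: int) -> tuple[int, int, int, int]:
    """Extend an exact k-mer seed at (i, j); returns (ai, ae, bi, be)."""
    ru, rv = _xdrop_dir(a, b, i + k, j + k, +1)
    lu, lv = _xdrop_dir(a, b, i, j, -1)
    return i - lu, i + k + ru, j - lv, j + k + rv


def _rescore(a: str, b: str) -> tuple[float, float, int]:
    """Affine-gap global alignment stats of a hit pair: (score, identity%, span)."""
    if a == b:
        return MATCH * len(a), 100.0, len(a)
    aln = align_global(a, b, REPEAT_ALN_PARAMS)
    same = sum(1 for x, y in aln.columns() if x == y and x != "-")
    return aln.score, 100.0 * same / len(aln), len(aln)


def _cluster_seeds(pairs: list[tuple[int, int]], gap: int = 90) -> list[tuple[int, int]]:
    """One representative seed per diagonal run of nearby seeds."""
    by_diag: dict[int, list[int]] = {}
    for i, j in pairs:
        by_diag.setdefault(j - i, []).append(i)
    reps: list[tuple[int, int]] = []
    for d, starts in by_diag.items():
        starts.sort()
        run = [starts[0]]
        for s in starts[1:]:
            if s - run[-1] <= gap:
                run.append(s)
            else:
                reps.append((run[0], run[0] + d))
                run = [s]
        reps.append((run[0], run[0] + d))
    return reps


def _overlaps(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] < y[1] and y[0] < x[1]


def _dedupe(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits whose both intervals overlap a better hit's intervals."""
    hits = sorted(hits, key=lambda h: -h.score)
    kept: list[RepeatHit] = []
    for h in hits:
        dup = any(
            h.strand == g.strand
            and _overlaps(h.interval_a, g.interval_a)
            and _overlaps(h.interval_b, g.interval_b)
            for g in kept)
        if not dup:
            kept.append(h)
    return kept


def _search(a: str, b: str, min_len: int, threshold: float,
            strand: int, m_eff: int, n_eff: int, self_mode: bool,
            wrap_len: int | None) -> list[RepeatHit]:
    """Seed-and-extend search of a against b (already strand-adjusted)."""
    idx_b = _kmer_index(b, SEED_K)
    pairs: list[tuple[int, int]] = []
    limit_a = (wrap_len if self_mode and wrap_len else len(a)) - SEED_K + 1
    seen_kmer_a: set[int] = set()
    for i in range(max(limit_a, 0)):
        kmer = a[i:i + SEED_K]
        occ = idx_b.get(kmer)
        if not occ or len(occ) > _MAX_SEED_OCC:
            continue
        for j in occ:
            if self_mode:
                d = j - i
                # the self-diagonal (and its copy at the doubling offset) is
                # excluded with a +-band margin so the banded extension
                # cannot slide onto a perfect self-match
                if abs(d) <= _BAND:
                    continue
                if wrap_len and abs(abs(d) - wrap_len) <= _BAND:
                    continue
                if strand == 1 and d < 0:
                    continue  # reciprocal duplicate
            pairs.append((i, j))
    hits: list[RepeatHit] = []
    for i, j in _cluster_seeds(pairs):
        ai, ae, bi, be = _extend_seed(a, b, i, j, SEED_K)
        if ae - ai < min_len and be - bi < min_len:
            continue
        if ae - ai > _MAX_HIT_LEN or be - bi > _MAX_HIT_LEN:
            continue  # degenerate runaway (e.g. long-period self-similarity)
        score, ident, span = _rescore(a[ai:ae], b[bi:be])
        if span < min_len:
            continue
        ev = _evalue(score, m_eff, n_eff)
        if ev > threshold:
            continue
        if strand == -1:
            bi, be = len(b) - be, len(b) - bi
        iv_a, iv_b = (ai, ae), (bi, be)
        if wrap_len:
            iv_a = _mod_interval(iv_a, wrap_len)
            iv_b = _mod_interval(iv_b, wrap_len)
        if self_mode:
            if iv_a == iv_b or (strand == -1 and _overlaps(iv_a, iv_b)):
                continue
            if iv_b < iv_a:
                iv_a, iv_b = iv_b, iv_a
        hits.append(RepeatHit(iv_a, iv_b, span, ident, score, ev, strand))
    return _dedupe(hits)


def _mod_interval(iv: tuple[int, int], L: int) -> tuple[int, int]:
    s, e = iv
    if s >= L:
        s, e = s - L, e - L
    return (s, min(e, 2 * L))


def self_repeats(m: Mitogenome, min_len: int = 30,
                 threshold: float = 1e-10) -> list[RepeatHit]:
    """Intra-genomic interspersed repeats (both strands).

    Exact 11-mer seeds, X-drop extension, affine rescoring and an e-value
    cutoff; the diagonal and reciprocal duplicates are excluded, and circular
    genomes are searched on the doubled sequence with hits reported modulo
    genome length.
    """
    L = len(m)
    if L < 2 * min_len:
        return []
    s = m.sequence + m.sequence if m.circular else m.sequence
    n_eff = L
    fwd = _search(s, s, min_len, threshold, strand=1,
                  m_eff=n_eff, n_eff=n_eff, self_mode=True,
                  wrap_len=L if m.circular else None)
    rev = _search(s, revcomp(s), min_len, threshold, strand=-1,
                  m_eff=n_eff, n_eff=n_eff, self_mode=True,
                  wrap_len=L if m.circular else None)
    return _dedupe(fwd + rev)


def cross_repeats(a: Mitogenome, b_seqs: dict[str, str] | Sequence[str],
                  min_len: int = 30, threshold: float = 1e-10) -> list[RepeatHit]:
    """Shared fragments between a mitogenome and another sequence set
    (e.g. nuclear scaffolds or another mitogenome), both strands."""
    if isinstance(b_seqs, dict):
        seqs = list(b_seqs.values())
    else:
        seqs = list(b_seqs)
    L = len(a)
    s = a.sequence + a.sequence if a.circular else a.sequence
    n_total = sum(len(x) for x in seqs)
    hits: list[RepeatHit] = []
    offset = 0
    for bs in seqs:
        bs = bs.upper()
        for strand, target in ((1, bs), (-1, revcomp(bs))):
            found = _search(s, target, min_len, threshold, strand=strand,
                            m_eff=L, n_eff=max(n_total, 1), self_mode=False,
                            wrap_len=None)
            for h in found:
                iv_a = _mod_interval(h.interval_a, L) if a.circular else h.interval_a
                hits.append(RepeatHit(iv_a,
                                      (h.interval_b[0] + offset,
                                       h.interval_b[1] + offset),
                                      h.length, h.identity, h.score,
                                      h.evalue_like, strand))
        offset += len(bs)
    return _dedupe(hits)


def total_aligned_bp(hits: Iterable[RepeatHit], genome_length: int) -> int:
    """Union of a-side hit intervals (bp), modulo genome length."""
    ivs: list[tuple[int, int]] = []
    for h in hits:
        s, e = h.interval_a
        if s >= genome_length:
            s, e = s - genome_length, e - genome_length
        if e <= genome_length:
            ivs.append((s, e))
        else:
            ivs.append((s, genome_length))
            ivs.append((0, e - genome_length))
    ivs.sort()
    total = 0
    cur_s, cur_e = -1, -1
    for s, e in ivs:
        if s > cur_e:
            total += cur_e - cur_s if cur_e > cur_s else 0
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s if cur_e > cur_s else 0
    return total


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def tandem_repeats(m: Mitogenome, max_unit: int = 100, min_copies: float = 2.0,
                   min_identity: float = 0.8, min_span: int = 12,
                   include_homopolymers: bool = True) -> list[TandemRepeat]:
    """Tandem repeats by period search.

    For each unit length p <= max_unit, positions where the sequence equals
    itself shifted by p are found; maximal match runs (merged across isolated
    mismatches while overall identity stays >= ``min_identity``) of span
    >= ``min_copies`` units are reported.  Overlapping calls with different
    periods keep the smallest period.  Homopolymer runs (p = 1) are reported
    by default and can be filtered out.
    """
    seq = m.sequence
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(arr)
    candidates: list[TandemRepeat] = []
    for p in range(1, min(max_unit, L - 1) + 1):
        eq = arr[p:] == arr[:-p]
        runs = _match_runs(eq, min_identity)
        for s, e in runs:
            span = (e - s) + p
            copies = span / p
            if copies + 1e-9 < min_copies or span < min_span:
                continue
            unit = _consensus_unit(seq[s:s + span], p)
            # a composite unit (e.g. AAAAA) collapses to its minimal period
            mp = _minimal_period(unit)
            if mp < p:
                unit = unit[:mp]
                copies = span / mp
                p_eff = mp
            else:
                p_eff = p
            candidates.append(TandemRepeat(start=s, unit_length=p_eff,
                                           copies=round(copies, 2),
                                           consensus=unit, span=span))
    # among overlapping calls prefer the longest span, then smallest period
    candidates.sort(key=lambda t: (-t.span, t.unit_length, t.start))
    kept: list[TandemRepeat] = []
    for t in candidates:
        if not include_homopolymers and t.unit_length == 1:
            continue
        if not any(_overlaps((t.start, t.start + t.span),
                             (k.start, k.start + k.span)) for k in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


def _match_runs(eq: np.ndarray, min_identity: float) -> list[tuple[int, int]]:
    """Maximal intervals of eq that are mostly True.

    Exact True runs are found first, then adjacent runs separated by short
    mismatch gaps are merged while the merged interval's match fraction stays
    >= ``min_identity``.
    """
    if eq.size == 0:
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
    runs = [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]
    merged: list[tuple[int, int, int]] = []   # (start, end, true matches)
    for s, e in runs:
        if merged:
            ps, pe, pm = merged[-1]
            span = e - ps
            matches = pm + (e - s)
            if span > 0 and matches / span >= min_identity:
                merged[-1] = (ps, e, matches)
                continue
        merged.append((s, e, e - s))
    return [(s, e) for s, e, _ in merged]


def _consensus_unit(span_seq: str, p: int) -> str:
    """Majority base at each unit position over all full copies."""
    n_full = len(span_seq) // p
    if n_full <= 1:
        return span_seq[:p]
    unit = []
    for i in range(p):
        col = [span_seq[j * p + i] for j in range(n_full)]
        unit.append(max(set(col), key=col.count))
    return "".join(unit)


def _minimal_period(u: str) -> int:
    for p in range(1, len(u)):
        if len(u) % p == 0 and u == u[:p] * (len(u) // p):
            return p
    return len(u)
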