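"""Base composition, strand skews and genome-region fractions.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), both computed on
the deposited (direct) strand; GC content is (G + C) over counted bases.
N bases are excluded from every count.  Region fractions partition the genome
into protein-coding, rRNA, tRNA, intronic and intergenic bases (priority in
that order when annotations overlap), plus the fraction covered by repeats
(union of hit intervals, both copies of each pair counted once per base).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_model import Mitogenome, MitogenomeError

__all__ = ["CompositionReport", "composition", "region_fractions", "composition_table"]


@dataclass
class CompositionReport:
    id: str
    length: int
    counts: dict[str, int]
    gc_content: float  # fraction in [0, 1]
    at_skew: float
    gc_skew: float

    @property
    def gc_percent(self) -> float:
        return 100.0 * self.gc_content


def composition(m: Mitogenome) -> CompositionReport:
    """Base counts, GC content and strand skews of the direct strand."""
    seq = m.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    total = a + c + g + t
    if total == 0:
        raise MitogenomeError(f"{m.id}: no unambiguous bases, composition undefined")
    at_skew = (a - t) / (a + t) if a + t else 0.0
    gc_skew = (g - c) / (g + c) if g + c else 0.0
    return CompositionReport(id=m.id, length=len(m), counts=counts,
                             gc_content=(g + c) / total,
                             at_skew=at_skew, gc_skew=gc_skew)


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(i for i in intervals if i[1] > i[0])
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _covered(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge(intervals))


def region_fractions(m: Mitogenome, repeats: Sequence | None = None) -> dict[str, float]:
    """Fractions of the genome in each annotation class (percent).

    ``protein_coding + rrna + trna + intronic + intergenic == 100``.  The
    repeat fraction is reported separately (repeat-covered bases overlap the
    other classes).  ``repeats`` is a sequence of RepeatHit objects from
    :mod:`mitocomp.repeats`; intervals are taken mod genome length.
    """
    L = len(m)
    owner = bytearray(b"\x00" * L)  # 0 intergenic 1 intron 2 trna 3 rrna 4 coding
    rank = {"intronic": 1, "trna": 2, "rrna": 3, "coding": 4}

    def paint(interval: tuple[int, int], klass: str) -> None:
        r = rank[klass]
        for pos in range(interval[0], interval[1]):
            p = pos % L
            if owner[p] < r:
                owner[p] = r

    for f in m.features:
        klass = {"rrna": "rrna", "trna": "trna"}.get(f.gclass, "coding")
        for e in f.exons:
            paint(e, klass)
        for intr in f.introns:
            paint(intr.genomic_interval, "intronic")
    n_coding = owner.count(4)
    n_rrna = owner.count(3)
    n_trna = owner.count(2)
    n_intron = owner.count(1)
    n_inter = L - n_coding - n_rrna - n_trna - n_intron

    rep_ivs: list[tuple[int, int]] = []
    for hit in repeats or ():
        for s, e in (hit.interval_a, hit.interval_b):
            # hits may carry doubled-sequence coordinates for circular genomes
            if s >= L:
                s, e = s - L, e - L
            if e <= L:
                rep_ivs.append((s, e))
            else:  # wraps the origin
                rep_ivs.append((s, L))
                rep_ivs.append((0, e - L))
    frac = {
        "protein_coding": 100.0 * n_coding / L,
        "rrna": 100.0 * n_rrna / L,
        "trna": 100.0 * n_trna / L,
        "intronic": 100.0 * n_intron / L,
        "intergenic": 100.0 * n_inter / L,
        "repeat": 100.0 * _covered(rep_ivs) / L,
    }
    return frac


def composition_table(genomes: Sequence[Mitogenome],
                      repeats_by_id: dict[str, Sequence] | None = None) -> pd.DataFrame:
    """One row per genome: length, GC%, skews, region fractions (TSV-ready)."""
    rows = []
    for m in genomes:
        rep = composition(m)
        fr = region_fractions(m, (repeats_by_id or {}).get(m.id))
        rows.append({
            "id": m.id, "length": rep.length, "gc_percent": rep.gc_percent,
            "at_skew": rep.at_skew, "gc_skew": rep.gc_skew, **fr,
        })
    return pd.DataFrame(rows).set_index("id")
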