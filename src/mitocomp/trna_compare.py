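"""Pair shared tRNA genes between two mitogenomes and count variable sites.

tRNAs are matched by isotype + anticodon (the part of the name after
``trn``, e.g. ``trnS-gct``); duplicated copies are matched by their copy
index in reading order from position 0 (suffix ``-1``, ``-2``).  Each matched
pair is globally aligned and every aligned column with a mismatch or a gap
counts as one variable site, reported in the coordinates of the first
genome's sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import Mitogenome, gene_sequence
from .pairalign import align_global, identity

__all__ = ["TrnaPair", "TrnaPairReport", "shared_trnas", "variable_sites", "compare_trnas"]


@dataclass
class TrnaPair:
    gene_a: str
    gene_b: str
    seq_a: str = ""
    seq_b: str = ""


@dataclass
class TrnaPairReport:
    pairs: list[dict] = field(default_factory=list)
    unique_to_a: list[str] = field(default_factory=list)
    unique_to_b: list[str] = field(default_factory=list)

    @property
    def shared_count(self) -> int:
        return len(self.pairs)

    @property
    def total_variable_sites(self) -> int:
        return sum(p["variable_sites"] for p in self.pairs)


def _trna_key(name: str) -> tuple[str, str]:
    """(isotype+anticodon, copy index) from names like trnS-gct-2."""
    parts = name.split("-")
    base = parts[0]
    anticodon = ""
    copy = ""
    for p in parts[1:]:
        if p.isdigit():
            copy = p
        else:
            anticodon = p
    return (base + ("-" + anticodon if anticodon else ""), copy)


def _trnas_in_reading_order(m: Mitogenome) -> list:
    feats = [f for f in m.features if f.gclass == "trna"]
    feats.sort(key=lambda f: f.start)
    return feats


def shared_trnas(a: Mitogenome, b: Mitogenome) -> TrnaPairReport:
    """Match tRNA genes of two genomes by isotype + anticodon.

    Duplicate copies of the same isotype/anticodon are paired by copy index
    in reading order; surplus copies end up in the unique lists.
    """
    report = TrnaPairReport()

    def grouped(m: Mitogenome) -> dict[str, list]:
        groups: dict[str, list] = {}
        for f in _trnas_in_reading_order(m):
            key, _ = _trna_key(f.name)
            groups.setdefault(key, []).append(f)
        return groups

    ga, gb = grouped(a), grouped(b)
    for key in sorted(set(ga) | set(gb)):
        fa = ga.get(key, [])
        fb = gb.get(key, [])
        for i in range(min(len(fa), len(fb))):
            report.pairs.append({
                "gene_a": fa[i].name, "gene_b": fb[i].name,
                "seq_a": gene_sequence(a, fa[i].name),
                "seq_b": gene_sequence(b, fb[i].name),
            })
        report.unique_to_a.extend(f.name for f in fa[min(len(fa), len(fb)):])
        report.unique_to_b.extend(f.name for f in fb[min(len(fa), len(fb)):])
    return report


def variable_sites(seq_a: str, seq_b: str) -> tuple[int, list[int]]:
    """Count variable columns between two tRNA sequences.

    Returns ``(count, positions)`` with positions 1-based in ``seq_a``
    coordinates (a gap in ``seq_a`` reports the position of the last
    consumed ``seq_a`` base).  Emits a mispairing warning below 50%
    alignment identity.
    """
    if seq_a == seq_b:
        return 0, []
    aln = align_global(seq_a, seq_b)
    if identity(aln) < 0.5:
        import warnings
        warnings.warn("tRNA pair aligns below 50% identity; possible mispairing")
    count = 0
    positions: list[int] = []
    pos_a = 0
    for x, y in aln.columns():
        if x != "-":
            pos_a += 1
        if x != y:
            count += 1
            positions.append(max(pos_a, 1))
    return count, positions


def compare_trnas(a: Mitogenome, b: Mitogenome) -> TrnaPairReport:
    """Full shared-tRNA report: pairing plus per-pair variable sites."""
    report = shared_trnas(a, b)
    for p in report.pairs:
        n, pos = variable_sites(p["seq_a"], p["seq_b"])
        p["aligned_length"] = max(len(p["seq_a"]), len(p["seq_b"]))
        p["variable_sites"] = n
        p["variant_positions"] = pos
    return report
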