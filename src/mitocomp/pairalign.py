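"""Global pairwise alignment: nucleotide Needleman–Wunsch and protein-guided
codon alignment.

Every downstream divergence statistic (K2P, Ka/Ks) and the intron
position-class mapping consumes alignments from this module, so the contract
is strict: removing gaps recovers the inputs exactly, no column is gap in
both rows, and the traceback is deterministic (the first optimal alignment in
Biopython's fixed enumeration order is always taken).

Scoring defaults: nucleotide match +1 / mismatch -1, gap open -2 / extend -2
(linear); protein BLOSUM62 with gap open -11 / extend -1, the conventional
pairing for coding-gene guidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import substitution_matrices

from .core_model import GENETIC_CODE_4, GeneticCode4, translate

__all__ = [
    "AlignParams", "Alignment", "CodonAlignment",
    "align_global", "align_protein", "codon_align",
    "identity", "write_fasta", "read_fasta",
]


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -2.0


DEFAULT_NT_PARAMS = AlignParams()
#: BLOSUM62-style protein scoring with affine -11/-1 gaps.
PROTEIN_GAP_OPEN = -11.0
PROTEIN_GAP_EXTEND = -1.0


@dataclass
class Alignment:
    """A global alignment of two sequences as equal-length gapped strings."""

    a: str
    b: str
    score: float
    params: AlignParams | None = None

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned rows differ in length")

    def __len__(self) -> int:
        return len(self.a)

    def columns(self):
        return zip(self.a, self.b)

    def ungapped(self) -> tuple[str, str]:
        return self.a.replace("-", ""), self.b.replace("-", "")


@dataclass
class CodonAlignment(Alignment):
    """A nucleotide alignment whose gaps are whole codons (lengths % 3 == 0)."""

    def codon_columns(self):
        for i in range(0, len(self.a), 3):
            yield self.a[i:i + 3], self.b[i:i + 3]

    @property
    def n_codon_columns(self) -> int:
        return len(self.a) // 3


def _nt_aligner(params: AlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    return al


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aa_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = PROTEIN_GAP_OPEN
    al.extend_gap_score = PROTEIN_GAP_EXTEND
    return al


def _first_alignment(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[str, str, float]:
    res = aligner.align(a, b)
    best = res[0]  # deterministic: first optimal traceback
    ga, gb = _gapped_from_aligned(a, b, best.aligned)
    return ga, gb, float(best.score)


def _gapped_from_aligned(a: str, b: str, aligned) -> tuple[str, str]:
    seg_a, seg_b = aligned
    ga: list[str] = []
    gb: list[str] = []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(seg_a, seg_b):
        if sa > pa:
            ga.append(a[pa:sa])
            gb.append("-" * (sa - pa))
        if sb > pb:
            ga.append("-" * (sb - pb))
            gb.append(b[pb:sb])
        ga.append(a[sa:ea])
        gb.append(b[sb:eb])
        pa, pb = ea, eb
    if pa < len(a):
        ga.append(a[pa:])
        gb.append("-" * (len(a) - pa))
    if pb < len(b):
        ga.append("-" * (len(b) - pb))
        gb.append(b[pb:])
    return "".join(ga), "".join(gb)


def align_global(a: str, b: str, params: AlignParams = DEFAULT_NT_PARAMS) -> Alignment:
    """Optimal global (Needleman–Wunsch, affine-gap) nucleotide alignment."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    ga, gb, score = _first_alignment(_nt_aligner(params), a.upper(), b.upper())
    return Alignment(ga, gb, score, params)


def align_protein(a: str, b: str) -> Alignment:
    """Global protein alignment under BLOSUM62 (-11/-1 affine gaps)."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    ga, gb, score = _first_alignment(_aa_aligner(), a, b)
    return Alignment(ga, gb, score, None)


def identity(aln: Alignment) -> float:
    """Fraction of identical columns over all alignment columns (gaps count
    as differences)."""
    same = sum(1 for x, y in aln.columns() if x == y and x != "-")
    return same / len(aln) if len(aln) else 0.0


def codon_align(cds_a: str, cds_b: str,
                code: GeneticCode4 = GENETIC_CODE_4) -> CodonAlignment:
    """Protein-guided codon alignment of two in-frame CDS.

    The translated proteins are globally aligned and the protein gaps are
    back-threaded as 3-nt gaps into nucleotide space, so every gap run length
    is a multiple of 3 and each gap boundary falls on a codon boundary.
    Trailing stop codons are trimmed and excluded from the codon alignment.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    pa = translate(cds_a, code)
    pb = translate(cds_b, code)
    # drop trailing stops from the nucleotide sequences to mirror translate()
    na = cds_a[: 3 * len(pa)]
    nb = cds_b[: 3 * len(pb)]
    paln = align_protein(pa, pb)
    ga: list[str] = []
    gb: list[str] = []
    ia = ib = 0
    for x, y in paln.columns():
        if x == "-":
            ga.append("---")
        else:
            ga.append(na[3 * ia: 3 * ia + 3])
            ia += 1
        if y == "-":
            gb.append("---")
        else:
            gb.append(nb[3 * ib: 3 * ib + 3])
            ib += 1
    return CodonAlignment("".join(ga), "".join(gb), paln.score, None)


# ---------------------------------------------------------------------------
# FASTA I/O for aligned (or plain) sequences
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
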