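"""Nucleotide and codon-level divergence statistics.

Implements the Kimura two-parameter (K2P) distance with pairwise deletion of
gapped/ambiguous columns, the Nei–Gojobori (1986) counting method for
synonymous and nonsynonymous substitution rates (Ka, Ks) under the mold
mitochondrial genetic code (table 4, TGA = Trp), selection-class calls from
the Ka/Ks ratio, per-gene distance matrices across a set of genomes, and a
neighbor-joining tree from a distance matrix.

K2P separates transition (P) and transversion (Q) proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Nei–Gojobori counts fractional synonymous sites per codon by single-base
neighbor enumeration (mutations creating stop codons are excluded from the
neighbor set), averages pathway orderings for multi-site codon differences
(pathways through stops are dropped and the rest reweighted equally), and
applies the Jukes–Cantor correction K = -3/4 * ln(1 - 4/3 * p) to each of
pS and pN.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import GENETIC_CODE_4, GeneticCode4, Mitogenome, MitogenomeError, spliced_cds, gene_sequence
from .pairalign import Alignment, CodonAlignment, align_global, codon_align

__all__ = [
    "K2PResult", "KaKsResult", "SaturationError",
    "k2p", "k2p_from_counts", "nei_gojobori", "selection_class",
    "gene_distance_matrix", "nj_tree", "concatenated_distance_matrix",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


class SaturationError(MitogenomeError):
    """Distance undefined: substitution proportions beyond the model's range."""


@dataclass
class K2PResult:
    P: float        # transition proportion
    Q: float        # transversion proportion
    d: float        # K2P distance
    sites: int      # compared (ungapped, unambiguous) sites


@dataclass
class KaKsResult:
    S: float        # synonymous sites (average of the two sequences)
    N: float        # nonsynonymous sites
    Sd: float       # synonymous differences (pathway-averaged)
    Nd: float       # nonsynonymous differences
    pS: float
    pN: float
    Ka: float
    Ks: float
    ratio: float | None   # Ka/Ks, None when Ks == 0


def _is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def k2p_from_counts(transitions: int, transversions: int, sites: int) -> K2PResult:
    """K2P distance from raw difference counts over ``sites`` compared sites."""
    if sites <= 0:
        raise SaturationError("no comparable sites")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P=P, Q=Q, d=d, sites=sites)


def k2p(aln: Alignment) -> K2PResult:
    """K2P distance on a nucleotide alignment with pairwise deletion.

    Columns containing a gap or an N in either row are excluded.
    """
    ts = tv = n = 0
    for x, y in aln.columns():
        if x in BASES and y in BASES:
            n += 1
            if x != y:
                if _is_transition(x, y):
                    ts += 1
                else:
                    tv += 1
    return k2p_from_counts(ts, tv, n)


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986)
# ---------------------------------------------------------------------------

def _neighbors(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1:])
    return out


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of a codon (0..3) under table 4.

    Neighbors that are stop codons are excluded; the synonymous fraction is
    taken over the remaining single-base neighbors and scaled to 3 sites, so
    synonymous + nonsynonymous sites always total 3 per codon.
    """
    code = GENETIC_CODE_4
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} in coding sequence")
    aa = code.aa(codon)
    nbrs = [nb for nb in _neighbors(codon) if not code.is_stop(nb)]
    if not nbrs:
        return 0.0
    syn = sum(1 for nb in nbrs if code.aa(nb) == aa)
    return 3.0 * syn / len(nbrs)


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions; any pathway that
    passes through a stop codon is discarded and the remaining pathways are
    reweighted equally.  If every pathway hits a stop, steps through stops are
    tolerated (counted as nonsynonymous) so the difference count is defined.
    """
    code = GENETIC_CODE_4
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        sd = nd = 0.0
        cur = c1
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt) and nxt != c2:
                ok = False
            if code.aa(cur) == code.aa(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (results if ok else fallback).append((sd, nd))
    pool = results or fallback
    sd = sum(x for x, _ in pool) / len(pool)
    nd = sum(y for _, y in pool) / len(pool)
    return sd, nd


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4, correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(caln: CodonAlignment,
                 code: GeneticCode4 = GENETIC_CODE_4) -> KaKsResult:
    """Nei–Gojobori Ka/Ks on a codon alignment (gap-free columns only)."""
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for ca, cb in caln.codon_columns():
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue  # trailing stops are trimmed upstream; be tolerant here
        n_codons += 1
        s_a += _syn_sites(ca)
        s_b += _syn_sites(cb)
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise MitogenomeError("no comparable codon columns")
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = _jc(pS) if S > 0 else 0.0
    Ka = _jc(pN) if N > 0 else 0.0
    ratio = (Ka / Ks) if Ks > 0 else None
    return KaKsResult(S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, Ka=Ka, Ks=Ks,
                      ratio=ratio)


def selection_class(r: KaKsResult, tol: float = 1e-9) -> str:
    """Classify selection from Ka/Ks: purifying (<1), neutral (=1), positive (>1)."""
    if r.ratio is None:
        return "undefined"
    if abs(r.ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if r.ratio > 1.0 else "purifying"


# ---------------------------------------------------------------------------
# distance matrices and neighbor joining
# ---------------------------------------------------------------------------

def gene_distance_matrix(genomes: Sequence[Mitogenome], gene: str) -> pd.DataFrame:
    """Pairwise K2P distances for one gene across genomes.

    Spliced CDS (rRNA: spliced gene sequence) are globally aligned per pair.
    Genomes lacking the gene get NaN rows/columns; a gene absent everywhere
    is an error.
    """
    seqs: dict[str, str | None] = {}
    for m in genomes:
        try:
            f = m.feature(gene)
        except KeyError:
            seqs[m.id] = None
            continue
        seqs[m.id] = (spliced_cds(m, gene) if f.gclass not in ("rrna", "trna")
                      else gene_sequence(m, gene))
    if all(v is None for v in seqs.values()):
        raise MitogenomeError(f"gene {gene} absent from all genomes")
    ids = list(seqs)
    mat = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if seqs[a] is None or seqs[b] is None:
                d = np.nan
            elif seqs[a] == seqs[b]:
                d = 0.0
            else:
                d = k2p(align_global(seqs[a], seqs[b])).d
            mat.loc[a, b] = mat.loc[b, a] = d
        if seqs[a] is None:
            mat.loc[a, a] = np.nan
    return mat


def concatenated_distance_matrix(genomes: Sequence[Mitogenome],
                                 genes: Sequence[str]) -> pd.DataFrame:
    """K2P distances on the concatenation of per-gene pairwise alignments.

    Transitions, transversions and compared sites are pooled over genes
    (genes missing from either member of a pair are skipped for that pair).
    """
    gene_seqs: dict[str, dict[str, str]] = {}
    for g in genes:
        gene_seqs[g] = {}
        for m in genomes:
            try:
                f = m.feature(g)
            except KeyError:
                continue
            gene_seqs[g][m.id] = (spliced_cds(m, g)
                                  if f.gclass not in ("rrna", "trna")
                                  else gene_sequence(m, g))
    ids = [m.id for m in genomes]
    mat = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ts = tv = n = 0
            for g in genes:
                sa, sb = gene_seqs[g].get(a), gene_seqs[g].get(b)
                if sa is None or sb is None:
                    continue
                aln = align_global(sa, sb) if sa != sb else Alignment(sa, sb, 0.0)
                for x, y in aln.columns():
                    if x in BASES and y in BASES:
                        n += 1
                        if x != y:
                            if _is_transition(x, y):
                                ts += 1
                            else:
                                tv += 1
            mat.loc[a, b] = mat.loc[b, a] = k2p_from_counts(ts, tv, n).d
    return mat


def nj_tree(dm: pd.DataFrame) -> str:
    """Neighbor-joining tree from a symmetric distance matrix, as Newick.

    Negative branch lengths produced by the agglomeration are clamped to 0
    with a warning.  Masked (NaN) entries are an error: reduce the gene set
    until every pair is comparable.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if dm.isna().any().any():
        raise MitogenomeError(
            "distance matrix has masked entries; reduce the gene set so every "
            "pair of taxa is comparable")
    if len(dm) < 3:
        raise MitogenomeError("neighbor joining needs at least 3 taxa")
    sk = DistanceMatrix(dm.values, ids=list(dm.index))
    tree = nj(sk)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return str(tree).strip()
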