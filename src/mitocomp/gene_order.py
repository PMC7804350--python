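"""Circular signed gene orders and their comparison.

The unit of comparison is the signed order of the 17-gene set (15 core
protein-coding genes + 2 rRNAs) around the circle.  Orders are normalised to
start at cox1 on the + strand: the list of genes is sorted by position,
rotated so cox1 comes first, and — when cox1 sits on the - strand — the
whole order is reflected with all signs flipped.  This makes the
representation invariant under genome rotation and whole-genome reverse
complement, so two taxa share an arrangement iff their normalised orders are
equal.  Rearrangement extent between two orders is quantified by the
breakpoint distance: the number of signed circular adjacencies of one order
absent from the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core_model import CORE_PCGS, RRNAS, Mitogenome, MitogenomeError

__all__ = [
    "ORDER_GENE_SET", "GeneOrder", "extract_order", "order_equal",
    "breakpoint_distance", "order_groups",
]

#: 15 core PCGs + 2 rRNA genes, the set compared across taxa.
ORDER_GENE_SET: frozenset[str] = frozenset(CORE_PCGS) | frozenset(RRNAS)


class OrderError(MitogenomeError):
    pass


@dataclass
class GeneOrder:
    """Signed circular permutation of (a subset of) the 17-gene core set."""

    taxon: str
    genes: list[str]          # canonical names, cox1 first after normalisation
    signs: list[int]          # +1 / -1 parallel to genes
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene in order")

    def signed(self) -> list[tuple[str, int]]:
        return list(zip(self.genes, self.signs))

    def __str__(self) -> str:
        return " ".join(("+" if s == 1 else "-") + g
                        for g, s in zip(self.genes, self.signs))


def normalize(order: GeneOrder) -> GeneOrder:
    """Rotate so cox1 is first; reflect (and flip signs) if cox1 is on -."""
    if "cox1" not in order.genes:
        raise OrderError(f"{order.taxon}: cox1 absent, cannot normalise")
    i = order.genes.index("cox1")
    genes = order.genes[i:] + order.genes[:i]
    signs = order.signs[i:] + order.signs[:i]
    if signs[0] == -1:
        # reflect: reverse the tail, keep cox1 first, flip every sign
        genes = [genes[0]] + genes[1:][::-1]
        signs = [-s for s in ([signs[0]] + signs[1:][::-1])]
    return GeneOrder(order.taxon, genes, signs, order.circular)


def extract_order(m: Mitogenome) -> GeneOrder:
    """Signed order of the 17-gene set around the circle, normalised.

    Genes are sorted by their leftmost genomic coordinate; duplicated tRNAs
    and non-core genes are excluded.  A missing cox1 is an error; other
    missing core genes shorten the order with a warning.
    """
    feats = [f for f in m.features if f.name in ORDER_GENE_SET]
    missing = ORDER_GENE_SET - {f.name for f in feats}
    if "cox1" in missing:
        raise OrderError(f"{m.id}: cox1 not annotated")
    if missing:
        warnings.warn(f"{m.id}: core genes missing from order: {sorted(missing)}")
    feats.sort(key=lambda f: f.start)
    order = GeneOrder(m.id, [f.name for f in feats], [f.strand for f in feats],
                      m.circular)
    return normalize(order)


def order_equal(a: GeneOrder, b: GeneOrder, signed: bool = True) -> bool:
    """Equality of normalised orders (optionally ignoring strand signs)."""
    na, nb = normalize(a), normalize(b)
    if na.genes != nb.genes:
        return False
    return na.signs == nb.signs if signed else True


def _adjacencies(order: GeneOrder) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Signed circular adjacencies, canonicalised for reading direction.

    The adjacency (+a,+b) read forwards equals (-b,-a) read backwards; each
    adjacency is stored under the lexicographically smaller of the two forms.
    """
    items = list(zip(order.genes, order.signs))
    adj = set()
    n = len(items)
    for i in range(n):
        g1, s1 = items[i]
        g2, s2 = items[(i + 1) % n] if order.circular or i + 1 < n else (None, None)
        if g2 is None:
            continue
        fwd = ((g1, s1), (g2, s2))
        rev = ((g2, -s2), (g1, -s1))
        adj.add(min(fwd, rev))
    return adj


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Signed circular breakpoint distance on the shared gene set.

    Orders with unequal gene sets are reduced to the intersection first
    (with a warning); fewer than 3 shared genes is an error.
    """
    shared = set(a.genes) & set(b.genes)
    if len(shared) < 3:
        raise OrderError("fewer than 3 shared genes; breakpoint distance undefined")
    if shared != set(a.genes) or shared != set(b.genes):
        warnings.warn("gene sets differ; reducing to %d shared genes" % len(shared))
        a = _restrict(a, shared)
        b = _restrict(b, shared)
    return len(_adjacencies(a) - _adjacencies(b))


def _restrict(order: GeneOrder, keep: set[str]) -> GeneOrder:
    pairs = [(g, s) for g, s in order.signed() if g in keep]
    return GeneOrder(order.taxon, [g for g, _ in pairs], [s for _, s in pairs],
                     order.circular)


def order_groups(orders: list[GeneOrder], signed: bool = True) -> list[list[str]]:
    """Partition taxa by identical (normalised) gene order.

    Clusters are returned largest first (ties broken by first taxon name);
    the largest cluster is the candidate ancestral arrangement.
    """
    if not orders:
        raise OrderError("no orders given")
    clusters: list[tuple[GeneOrder, list[str]]] = []
    for o in sorted(orders, key=lambda x: x.taxon):
        for rep, members in clusters:
            if order_equal(rep, o, signed=signed):
                members.append(o.taxon)
                break
        else:
            clusters.append((o, [o.taxon]))
    clusters.sort(key=lambda c: (-len(c[1]), c[1][0]))
    return [members for _, members in clusters]
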