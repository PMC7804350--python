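"""Circular signed gene orders: normalisation, equality, breakpoints."""

import itertools

import numpy as np
import pytest

from mitocomp.core_model import GeneFeature, revcomp
from mitocomp.gene_order import (GeneOrder, breakpoint_distance, extract_order,
                                 normalize, order_equal, order_groups)
from conftest import make_genome


def _genome_from_order(pairs, gid="g", gene_len=30, spacer=10):
    """Lay genes around a circle in the given signed order."""
    feats, seq, cursor = [], [], 0
    for name, sign in pairs:
        seq.append("A" * spacer)
        cursor += spacer
        feats.append(GeneFeature(name=name, gclass="core_pcg" if not
                                 name.startswith("rn") else "rrna",
                                 strand=sign, exons=[(cursor, cursor + gene_len)]))
        seq.append("ACG" * (gene_len // 3))
        cursor += gene_len
    seq.append("A" * spacer)
    return make_genome("".join(seq), feats, gid=gid)


BASIC = [("cox1", 1), ("nad4", 1), ("rnl", -1)]


def test_extract_order_identity():
    o = extract_order(_genome_from_order(BASIC))
    assert o.genes == ["cox1", "nad4", "rnl"]
    assert o.signs == [1, 1, -1]


def test_rotation_invariance():
    rotated = BASIC[1:] + BASIC[:1]
    a = extract_order(_genome_from_order(BASIC))
    b = extract_order(_genome_from_order(rotated))
    assert order_equal(a, b)


def test_reverse_complement_invariance():
    """Reverse-complementing the whole genome leaves the normalised order
    unchanged."""
    m = _genome_from_order(BASIC)
    L = len(m)
    flipped = []
    for f in m.features:
        s, e = f.exons[0]
        flipped.append(GeneFeature(name=f.name, gclass=f.gclass,
                                   strand=-f.strand, exons=[(L - e, L - s)]))
    m_rc = make_genome(revcomp(m.sequence), flipped, gid="rc")
    assert order_equal(extract_order(m), extract_order(m_rc))


def test_normalize_idempotent():
    o = normalize(GeneOrder("t", ["nad4", "rnl", "cox1"], [1, -1, -1]))
    assert o.genes[0] == "cox1" and o.signs[0] == 1
    assert normalize(o).genes == o.genes and normalize(o).signs == o.signs


def test_order_equal_detects_transposition():
    a = GeneOrder("a", ["cox1", "nad1", "nad2", "nad3"], [1, 1, 1, 1])
    b = GeneOrder("b", ["cox1", "nad2", "nad1", "nad3"], [1, 1, 1, 1])
    assert order_equal(a, a)
    assert not order_equal(a, b)


def _invert(order, start, length):
    genes = [g for g, _ in order]
    signs = [s for _, s in order]
    n = len(order)
    idx = [(start + i) % n for i in range(length)]
    block = [(genes[i], signs[i]) for i in idx]
    for i, (g, s) in zip(idx, reversed([(g, -s) for g, s in block])):
        genes[i], signs[i] = g, s
    return list(zip(genes, signs))


SIX = [("cox1", 1), ("nad1", 1), ("nad2", 1), ("nad3", 1), ("nad4", 1), ("nad5", 1)]


def test_breakpoint_identity_and_single_inversion():
    a = GeneOrder("a", [g for g, _ in SIX], [s for _, s in SIX])
    assert breakpoint_distance(a, a) == 0
    inv = _invert(SIX, 1, 2)
    b = GeneOrder("b", [g for g, _ in inv], [s for _, s in inv])
    assert breakpoint_distance(a, b) == 2
    assert breakpoint_distance(b, a) == 2


def _random_signed_order(rng, genes):
    perm = list(rng.permutation(genes))
    signs = [1 if rng.random() < 0.5 else -1 for _ in perm]
    if "cox1" in perm:
        pass
    return GeneOrder("r", perm, signs)


def test_breakpoint_is_metric_on_random_orders():
    """Identity, symmetry and triangle inequality over random signed
    permutations of 8 genes."""
    genes = ["cox1", "nad1", "nad2", "nad3", "nad4", "nad5", "rnl", "rns"]
    rng = np.random.default_rng(17)
    orders = [_random_signed_order(rng, genes) for _ in range(6)]
    for a in orders:
        assert breakpoint_distance(a, a) == 0
    for a, b in itertools.combinations(orders, 2):
        assert breakpoint_distance(a, b) == breakpoint_distance(b, a)
    for a, b, c in itertools.combinations(orders, 3):
        assert (breakpoint_distance(a, c)
                <= breakpoint_distance(a, b) + breakpoint_distance(b, c))


@pytest.mark.parametrize("k", [1, 2, 3])
def test_k_inversions_bound_breakpoint_distance(k):
    """k non-overlapping inversions give distance in [k, 2k]."""
    genes = [f"g{i}" for i in range(12)]
    genes[0] = "cox1"
    rng = np.random.default_rng(40 + k)
    for _ in range(10):
        anc = list(zip(genes, [1] * 12))
        cur = anc
        starts = rng.choice(range(1, 9), size=k, replace=False)
        used = set()
        applied = 0
        for s in sorted(starts):
            if {s, s + 1} & used:
                continue
            cur = _invert(cur, int(s), 2)
            used |= {int(s), int(s) + 1}
            applied += 1
        a = GeneOrder("anc", [g for g, _ in anc], [s for _, s in anc])
        b = GeneOrder("der", [g for g, _ in cur], [s for _, s in cur])
        d = breakpoint_distance(a, b)
        assert applied <= d <= 2 * applied


def test_order_groups_cluster_sizes(small_clade):
    genomes, truth = small_clade
    orders = [extract_order(m) for m in genomes]
    groups = order_groups(orders)
    # T3 was rearranged; T1, T2, T4 share the ancestral arrangement
    assert sorted(len(g) for g in groups) == [1, 3]
    assert ["T3"] in groups


def test_order_groups_permutation_invariant(small_clade):
    genomes, _ = small_clade
    orders = [extract_order(m) for m in genomes]
    g1 = order_groups(orders)
    g2 = order_groups(orders[::-1])
    assert g1 == g2


def test_extract_order_matches_simulator_truth(small_clade):
    genomes, truth = small_clade
    for m in genomes:
        o = extract_order(m)
        full = truth.gene_orders[m.id]
        core = [(g, s) for g, s in full if g in set(o.genes)]
        want = normalize(GeneOrder(m.id, [g for g, _ in core],
                                   [s for _, s in core]))
        assert o.genes == want.genes and o.signs == want.signs
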