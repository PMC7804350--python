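"""K2P, Nei–Gojobori, selection classes, distance matrices, NJ."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from mitocomp.core_model import GENETIC_CODE_4
from mitocomp.moldist import (KaKsResult, SaturationError, gene_distance_matrix,
                              k2p, k2p_from_counts, nei_gojobori, nj_tree,
                              selection_class)
from mitocomp.pairalign import Alignment, CodonAlignment, codon_align
from mitocomp.synth_clade import SimConfig, simulate_clade


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

def test_k2p_identity_zero():
    r = k2p(Alignment("ACGT" * 10, "ACGT" * 10, 0.0))
    assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)


def test_k2p_planted_counts_match_closed_form():
    """20 transitions + 10 transversions over 200 sites give the closed form
    d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    base = "A" * 200
    other = "G" * 20 + "C" * 10 + "A" * 170  # A->G transition, A->C transversion
    r = k2p(Alignment(base, other, 0.0))
    assert r.P == pytest.approx(0.1)
    assert r.Q == pytest.approx(0.05)
    want = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
    assert r.d == pytest.approx(want, abs=1e-12)
    assert r.d == pytest.approx(0.17018, abs=5e-6)


def test_k2p_pairwise_deletion_of_gaps_and_ns():
    aln = Alignment("ACGTN-", "ACCT-A", 0.0)
    r = k2p(aln)
    assert r.sites == 4
    assert r.Q == pytest.approx(0.25)  # G/C transversion


def test_k2p_saturation_error():
    with pytest.raises(SaturationError):
        k2p_from_counts(transitions=120, transversions=0, sites=200)


# ---------------------------------------------------------------------------
# Nei–Gojobori
# ---------------------------------------------------------------------------

BASES = "ACGT"


def oracle_syn_sites(codon):
    """Independent neighbor-enumeration oracle for synonymous sites."""
    code = GENETIC_CODE_4
    nbrs = []
    for pos, b in itertools.product(range(3), BASES):
        nb = codon[:pos] + b + codon[pos + 1:]
        if nb != codon and not code.is_stop(nb):
            nbrs.append(nb)
    syn = [nb for nb in nbrs if code.aa(nb) == code.aa(codon)]
    return 3.0 * len(syn) / len(nbrs) if nbrs else 0.0


def oracle_pathway_diffs(c1, c2):
    """Independent exhaustive pathway enumeration for (Sd, Nd)."""
    code = GENETIC_CODE_4
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    ok_paths, all_paths = [], []
    for order in itertools.permutations(pos):
        sd = nd = 0
        cur = c1
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if code.is_stop(nxt) and nxt != c2:
                through_stop = True
            if code.aa(cur) == code.aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            ok_paths.append((sd, nd))
    pool = ok_paths or all_paths
    return (sum(p[0] for p in pool) / len(pool),
            sum(p[1] for p in pool) / len(pool))


def _non_stop_codons():
    return [a + b + c for a, b, c in itertools.product(BASES, repeat=3)
            if a + b + c not in ("TAA", "TAG")]


def test_ttt_synonymous_sites_one_third():
    """Phe TTT: only TTT->TTC is synonymous among 9 neighbors."""
    caln = CodonAlignment("TTT", "TTT", 0.0)
    r = nei_gojobori(caln)
    assert r.S == pytest.approx(1 / 3)
    assert r.N == pytest.approx(3 - 1 / 3)


def test_site_fractions_match_enumeration_oracle():
    from mitocomp.moldist import _syn_sites
    for codon in _non_stop_codons():
        assert _syn_sites(codon) == pytest.approx(oracle_syn_sites(codon)), codon


def test_pathway_diffs_match_enumeration_oracle():
    """Pathway-averaged difference counts agree with exhaustive enumeration
    on every ordered codon pair."""
    from mitocomp.moldist import _pathway_diffs
    codons = _non_stop_codons()
    for c1 in codons:
        for c2 in codons:
            got = _pathway_diffs(c1, c2)
            want = oracle_pathway_diffs(c1, c2)
            assert got == pytest.approx(want), (c1, c2)


def test_sites_sum_to_three_per_codon():
    rng = np.random.default_rng(3)
    codons = _non_stop_codons()
    a_codons = [codons[i] for i in rng.integers(0, len(codons), 120)]
    b_codons = list(a_codons)
    # sprinkle a few single-base changes so the comparison stays unsaturated
    changed = 0
    while changed < 12:
        ci = int(rng.integers(0, 120))
        pos = int(rng.integers(0, 3))
        nb = "ACGT"[int(rng.integers(0, 4))]
        cand = b_codons[ci][:pos] + nb + b_codons[ci][pos + 1:]
        if cand != b_codons[ci] and cand not in ("TAA", "TAG"):
            b_codons[ci] = cand
            changed += 1
    r = nei_gojobori(CodonAlignment("".join(a_codons), "".join(b_codons), 0.0))
    assert r.S + r.N == pytest.approx(3 * 120, abs=1e-9)
    assert r.Sd <= r.S and r.Nd <= r.N
    assert r.Sd + r.Nd == pytest.approx(12, abs=1e-9)


def test_identical_pair_zero_rates():
    rng = np.random.default_rng(1)
    codons = _non_stop_codons()
    a = "".join(codons[i] for i in rng.integers(0, len(codons), 50))
    r = nei_gojobori(CodonAlignment(a, a, 0.0))
    assert (r.Sd, r.Nd, r.Ka, r.Ks) == (0.0, 0.0, 0.0, 0.0)
    assert r.ratio is None


def test_two_pathway_codon_pair():
    """A codon pair differing at positions 1 and 3 averages both orderings."""
    pad = "GGA" * 60  # identical 4-fold-site background avoids saturation
    got = nei_gojobori(CodonAlignment("TTT" + pad, "CTC" + pad, 0.0))
    sd, nd = oracle_pathway_diffs("TTT", "CTC")
    assert got.Sd == pytest.approx(sd)
    assert got.Nd == pytest.approx(nd)
    assert sd + nd == pytest.approx(2.0)


@pytest.mark.parametrize("ratio,want", [
    (0.2, "purifying"), (1.4, "positive"), (1.0, "neutral"), (None, "undefined"),
])
def test_selection_class(ratio, want):
    r = KaKsResult(S=100, N=200, Sd=1, Nd=1, pS=0, pN=0, Ka=0.1,
                   Ks=0.5 if ratio else 0.0, ratio=ratio)
    assert selection_class(r) == want


def test_mean_kaks_near_one_under_neutral_evolution():
    """Neutral simulation (omega = 1) at total divergence ~0.2 estimates
    Ka/Ks near 1 on average."""
    from mitocomp.synth_clade import _random_cds, _rng, evolve_cds
    est = []
    for rep in range(15):
        anc = _random_cds(_rng(rep, 21), 502)
        a, _, _ = evolve_cds(anc, 0.1, 1.0, _rng(rep, 22))
        b, _, _ = evolve_cds(anc, 0.1, 1.0, _rng(rep, 23))
        est.append(nei_gojobori(codon_align(a, b)).ratio)
    assert 0.85 <= float(np.mean(est)) <= 1.15


# ---------------------------------------------------------------------------
# distance matrices and NJ
# ---------------------------------------------------------------------------

def test_gene_distance_matrix_identical_genomes(small_clade):
    genomes, _ = small_clade
    dm = gene_distance_matrix([genomes[0], genomes[0]], "cox1")
    assert np.allclose(dm.values, 0.0)


def test_gene_distance_matrix_symmetry(small_clade):
    genomes, _ = small_clade
    dm = gene_distance_matrix(genomes, "nad5")
    assert np.allclose(dm.values, dm.values.T)
    assert np.allclose(np.diag(dm.values), 0.0)
    off = dm.values[~np.eye(len(dm), dtype=bool)]
    assert (off > 0).all()


def random_additive_matrix(rng, n_taxa):
    """Random additive (tree) metric via random binary tree, with pairwise
    distances accumulated explicitly."""
    clusters = [{f"L{i}": 0.0} for i in range(n_taxa)]
    dmat = {(f"L{i}", f"L{j}"): 0.0 for i in range(n_taxa) for j in range(n_taxa)}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0))
        ca, cb = clusters[int(i)], clusters[int(j)]
        for leaf in ca:
            ca[leaf] += la
        for leaf in cb:
            cb[leaf] += lb
        for x in ca:
            for y in cb:
                dmat[(x, y)] = dmat[(y, x)] = ca[x] + cb[y]
        merged = {**ca, **cb}
        clusters = [c for k, c in enumerate(clusters) if k not in (int(i), int(j))]
        clusters.append(merged)
    leaves = sorted(l for c in [clusters[0]] for l in c)
    df = pd.DataFrame([[dmat[(x, y)] for y in leaves] for x in leaves],
                      index=leaves, columns=leaves)
    return df


def _patristic(nwk):
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


@pytest.mark.parametrize("n_taxa", [4, 5, 8])
def test_nj_recovers_additive_matrices_exactly(n_taxa):
    """NJ on an additive matrix returns a tree whose path metric equals the
    input distances."""
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(5):
        dm = random_additive_matrix(rng, n_taxa)
        nwk = nj_tree(dm)
        pat = _patristic(nwk)
        for x in dm.index:
            for y in dm.columns:
                if x != y:
                    assert pat[(x, y)] == pytest.approx(dm.loc[x, y], abs=1e-9)


def test_nj_three_taxa_closed_form():
    dm = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0.0]],
                      index=list("abc"), columns=list("abc"))
    pat = _patristic(nj_tree(dm))
    assert pat[("a", "b")] == pytest.approx(4)
    assert pat[("a", "c")] == pytest.approx(6)
    assert pat[("b", "c")] == pytest.approx(8)


def test_nj_rejects_masked_and_tiny():
    import mitocomp.moldist as md
    dm = pd.DataFrame([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]],
                      index=list("abc"), columns=list("abc"))
    with pytest.raises(md.MitogenomeError):
        nj_tree(dm)
    with pytest.raises(md.MitogenomeError):
        nj_tree(dm.iloc[:2, :2].fillna(1.0))
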