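"""Domain model: GenBank round trips, splice arithmetic, translation."""

import io

import pytest
from Bio.Seq import Seq

from mitocomp.core_model import (GENETIC_CODE_4, FrameError, GeneFeature,
                                 Mitogenome, TranslationError, canonical_name,
                                 read_genbank, revcomp, spliced_cds, translate,
                                 write_genbank)
from conftest import make_genome

import numpy as np


GB_JOIN = """LOCUS       toy                  700 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  toy record.
FEATURES             Location/Qualifiers
     CDS             join(1..300,401..600)
                     /gene="cox1"
ORIGIN
{origin}
//
"""


def _origin_block(seq):
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        parts = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return "\n".join(lines)


def test_join_becomes_exons_and_intron(tmp_path):
    """join(1..300,401..600) gives 2 exons and an intron inserted after
    spliced position 300."""
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 700))
    # make the spliced CDS a clean frame: 500 nt is not /3; content unused here
    text = GB_JOIN.format(origin=_origin_block(seq.lower()))
    p = tmp_path / "toy.gb"
    p.write_text(text)
    m = read_genbank(p)
    assert m.circular
    f = m.feature("cox1")
    assert f.exons == [(0, 300), (400, 600)]
    assert len(f.introns) == 1
    intr = f.introns[0]
    assert intr.genomic_interval == (300, 400)
    assert intr.spliced_insertion_point == 300


@pytest.mark.parametrize("strand,exons,wrap", [
    (1, [(10, 40)], False),
    (1, [(10, 40), (60, 81)], False),
    (-1, [(60, 81), (10, 40)], False),
    (1, [(90, 100), (0, 20)], True),
    (-1, [(0, 21), (90, 100)], True),
])
def test_genbank_round_trip(tmp_path, strand, exons, wrap):
    """read(write(m)) reproduces features, strands, wraps and spliced seqs."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    f = GeneFeature(name="nad2", gclass="core_pcg", strand=strand,
                    exons=exons, wraps_origin=wrap)
    m = make_genome(seq, [f], gid="rt")
    p = tmp_path / "rt.gb"
    write_genbank(m, p)
    m2 = read_genbank(p)
    assert m2.sequence == m.sequence
    assert m2.circular == m.circular
    f2 = m2.feature("nad2")
    assert (f2.exons, f2.strand, f2.wraps_origin) == (exons, strand, wrap)
    assert (spliced_cds(m2, "nad2", require_frame=False)
            == spliced_cds(m, "nad2", require_frame=False))


def test_round_trip_empty_features(tmp_path):
    m = make_genome("ACGT" * 25, [], gid="bare")
    p = tmp_path / "bare.gb"
    write_genbank(m, p)
    m2 = read_genbank(p)
    assert m2.sequence == m.sequence and m2.features == []


def test_spliced_cds_against_per_base_oracle():
    """Multi-exon extraction equals brute-force per-base extraction."""
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    for trial in range(20):
        n_ex = int(rng.integers(1, 4))
        bounds = sorted(rng.choice(np.arange(1, 499), size=2 * n_ex, replace=False))
        exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
        strand = 1 if rng.random() < 0.5 else -1
        coding = exons if strand == 1 else exons[::-1]
        f = GeneFeature(name="g", gclass="core_pcg", strand=strand, exons=coding)
        m = make_genome(seq, [f])
        got = spliced_cds(m, "g", require_frame=False)
        # oracle: per-base walk
        plus = "".join(seq[s:e] for s, e in exons)
        want = plus if strand == 1 else revcomp(plus)
        assert got == want


def test_spliced_cds_minus_strand_is_revcomp_of_plus():
    seq = "ATGAAATAGC" + "A" * 20
    plus = make_genome(seq, [GeneFeature("g", "core_pcg", 1, [(0, 9)])])
    minus = make_genome(seq, [GeneFeature("g", "core_pcg", -1, [(0, 9)])])
    assert spliced_cds(plus, "g") == "ATGAAATAG"
    assert spliced_cds(minus, "g") == revcomp("ATGAAATAG")


def test_spliced_cds_frame_error():
    m = make_genome("ATGAAAT" + "A" * 13,
                    [GeneFeature("g", "core_pcg", 1, [(0, 7)])])
    with pytest.raises(FrameError):
        spliced_cds(m, "g")


def test_translate_table4():
    """TGA is tryptophan under the mold mitochondrial code."""
    assert translate("ATGTGAAAATAA") == "MWK"
    assert translate("ATGTAA") == "M"
    with pytest.raises(TranslationError):
        translate("ATGTAAAAATAA")  # internal TAA
    assert translate("ATGTAAAAATAA", allow_internal_stops=True) == "M*K"


def test_translate_matches_biopython_table4():
    """Random CDS translation agrees with an independent table-4 oracle."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        codons = []
        while len(codons) < 300:
            c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
            if c not in ("TAA", "TAG"):
                codons.append(c)
        cds = "".join(codons)
        assert translate(cds) == str(Seq(cds).translate(table=4))


def test_canonical_name_synonyms():
    assert canonical_name("rrnL") == "rnl"
    assert canonical_name("NAD4L") == "nad4L"
    assert canonical_name("cox1") == "cox1"
    assert canonical_name("trnS-2") == "trnS-2"


def test_genetic_code4_shape():
    assert len(GENETIC_CODE_4.codon_map) == 64
    assert GENETIC_CODE_4.stop_codons == frozenset({"TAA", "TAG"})
    assert GENETIC_CODE_4.aa("TGA") == "W"
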