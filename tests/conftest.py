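import pytest

from mitocomp.core_model import GeneFeature, Mitogenome
from mitocomp.synth_clade import SimConfig, simulate_clade


def make_genome(seq: str, feats=None, gid: str = "toy", circular: bool = True) -> Mitogenome:
    return Mitogenome(id=gid, sequence=seq, circular=circular,
                      features=list(feats or []))


def simple_gene(name, start, end, strand=1, gclass="core_pcg"):
    return GeneFeature(name=name, gclass=gclass, strand=strand,
                       exons=[(start, end)])


@pytest.fixture(scope="session")
def small_clade():
    """A 4-taxon clade with introns, a rearrangement and planted repeats."""
    cfg = SimConfig(
        seed=42, n_taxa=4, divergence=0.08,
        groups=[{"taxa": ["T1", "T2"], "shared_fraction": 0.6}],
        intron_plan=[
            {"ref_position": 209, "taxa": ["T1", "T2"], "has_orf": True,
             "orf_family": "LAGLIDADG"},
            {"ref_position": 706, "taxa": ["T3"]},
        ],
        rearrangement_plan=[{"taxon": "T3", "op": "inversion",
                             "start": 5, "length": 4}],
        repeat_plan=[{"taxon": "T1", "length": 400, "identity": 0.9},
                     {"taxon": "T2", "tandem": True, "unit_length": 74,
                      "copies": 2}],
        trna_mutations={"T2": 5},
    )
    return simulate_clade(cfg)
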