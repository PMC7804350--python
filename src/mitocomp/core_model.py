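"""Domain model for annotated circular fungal mitochondrial genomes.

A mitogenome is represented as a circular DNA sequence plus a list of gene
features.  Protein-coding genes (the 15 conserved core genes, free-standing
ORFs, plasmid-derived DNA-polymerase genes), the two rRNAs and the tRNAs all
share one feature type; exon structure is explicit, and the gaps between
consecutive exons are materialised as :class:`Intron` records whose
``spliced_insertion_point`` counts the spliced coding nucleotides upstream of
the intron.  All internal coordinates are 0-based half-open on the deposited
(direct) strand; GenBank 1-based inclusive coordinates exist only at the I/O
boundary.

Translation uses NCBI genetic code 4 (the mold mitochondrial code, TGA = Trp),
the code under which these genomes are annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CORE_PCGS",
    "GCLASSES",
    "GeneticCode4",
    "GENETIC_CODE_4",
    "Intron",
    "GeneFeature",
    "Mitogenome",
    "MitogenomeError",
    "ParseError",
    "FrameError",
    "TranslationError",
    "canonical_name",
    "read_genbank",
    "write_genbank",
    "spliced_cds",
    "translate",
    "revcomp",
]

#: The 15 conserved mitochondrial protein-coding genes used for all
#: cross-species comparisons.
CORE_PCGS: tuple[str, ...] = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)

RRNAS: tuple[str, ...] = ("rnl", "rns")

GCLASSES: tuple[str, ...] = (
    "core_pcg", "rrna", "trna", "free_orf", "plasmid_derived", "intronic_orf",
)

ORF_FAMILIES: tuple[str, ...] = ("LAGLIDADG", "GIY_YIG", "other", "none")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class MitogenomeError(Exception):
    """Base class for domain errors."""


class ParseError(MitogenomeError):
    """Malformed GenBank record or feature table."""


class FrameError(MitogenomeError):
    """Spliced CDS length is not compatible with a codon reading frame."""


class TranslationError(MitogenomeError):
    """Internal stop codon (or bad length) during translation."""


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genetic code 4
# ---------------------------------------------------------------------------

class GeneticCode4:
    """NCBI translation table 4 (mold mitochondrial): TGA = Trp.

    Exposes a 64-entry ``codon_map`` (stops map to ``*``) and the stop set
    ``{TAA, TAG}``.
    """

    def __init__(self) -> None:
        tbl = CodonTable.unambiguous_dna_by_id[4]
        self.codon_map: dict[str, str] = dict(tbl.forward_table)
        self.stop_codons: frozenset[str] = frozenset(tbl.stop_codons)
        for stop in self.stop_codons:
            self.codon_map[stop] = "*"
        if len(self.codon_map) != 64 or len(self.stop_codons) != 2:
            raise AssertionError("genetic code 4 table malformed")

    def aa(self, codon: str) -> str:
        return self.codon_map[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


#: Module-level singleton; the table is immutable.
GENETIC_CODE_4 = GeneticCode4()


def translate(cds: str, code: GeneticCode4 = GENETIC_CODE_4,
              allow_internal_stops: bool = False) -> str:
    """Translate an in-frame CDS under the mold mitochondrial code.

    The terminal stop codon, if present, is dropped.  Internal stops raise
    :class:`TranslationError` unless ``allow_internal_stops`` (then they
    appear as ``*``).  Codons containing N translate to ``X``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not a multiple of 3")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if "N" in codon:
            aas.append("X")
            continue
        aa = code.aa(codon)
        if aa == "*":
            if i == n_codons - 1:
                break  # trailing stop dropped
            if not allow_internal_stops:
                raise TranslationError(f"internal stop codon {codon} at codon {i}")
        aas.append(aa)
    return "".join(aas)


# ---------------------------------------------------------------------------
# canonical gene names
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    text = (resources.files("mitocomp") / "data" / "gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canon = line.split("\t")
        table[alias.lower()] = canon
    return table


_SYNONYMS: dict[str, str] | None = None


def canonical_name(name: str) -> str:
    """Map a gene-name alias to its canonical form (e.g. ``rrnL`` -> ``rnl``).

    Names that are not in the synonym table are returned with their original
    casing except that canonical core-gene casing is enforced
    (``NAD4l``/``nad4l`` -> ``nad4L``).
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    base, sep, suffix = name.partition("-")
    mapped = _SYNONYMS.get(base.lower(), base)
    return mapped + sep + suffix


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------

@dataclass
class Intron:
    """An intron of a host gene.

    ``spliced_insertion_point`` is the number of spliced coding nucleotides
    5' of the intron (0-based count), i.e. the intron sits between spliced
    positions ``p`` and ``p + 1`` in 1-based coding coordinates.
    """

    host_gene: str
    ordinal: int
    genomic_interval: tuple[int, int]
    spliced_insertion_point: int
    has_orf: bool = False
    orf_family: str = "none"


@dataclass
class GeneFeature:
    """A gene with explicit exon structure.

    ``exons`` are half-open 0-based intervals on the direct strand, listed in
    coding (5'->3' transcript) order: ascending genomic coordinates for
    ``strand == +1``, descending for ``strand == -1``.  A feature that spans
    the replication origin of a circular genome carries ``wraps_origin`` and
    stores the wrap as an interval reaching the sequence end followed by one
    starting at 0 (in coding order).
    """

    name: str
    gclass: str
    strand: int
    exons: list[tuple[int, int]]
    product: str = ""
    introns: list[Intron] = field(default_factory=list)
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.gclass not in GCLASSES:
            raise ValueError(f"unknown gclass {self.gclass!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (for ordering around the circle)."""
        return min(e[0] for e in self.exons)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Mitogenome:
    """A circular (usually) annotated mitochondrial genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"gene {name!r} not annotated in {self.id}")

    def features_of_class(self, *gclasses: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gclass in gclasses]

    def introns(self, host: str | None = None) -> list[Intron]:
        out: list[Intron] = []
        for f in self.features:
            if host is None or f.name == host:
                out.extend(f.introns)
        return out


# ---------------------------------------------------------------------------
# spliced CDS extraction
# ---------------------------------------------------------------------------

def _exon_seq(seq: str, exon: tuple[int, int], strand: int) -> str:
    s = seq[exon[0]:exon[1]]
    return s if strand == 1 else revcomp(s)


def spliced_cds(m: Mitogenome, gene: str, require_frame: bool = True) -> str:
    """Concatenated exon sequence of ``gene`` in coding orientation.

    For protein-coding classes the result must be a multiple of 3 (a trailing
    stop is kept); otherwise :class:`FrameError` is raised unless
    ``require_frame`` is disabled (used for rRNA/tRNA extraction).
    """
    f = m.feature(gene)
    seq = "".join(_exon_seq(m.sequence, e, f.strand) for e in f.exons)
    coding = f.gclass in ("core_pcg", "free_orf", "plasmid_derived", "intronic_orf")
    if require_frame and coding and len(seq) % 3 != 0:
        raise FrameError(
            f"{gene} in {m.id}: spliced length {len(seq)} is not a multiple of 3"
        )
    return seq


def gene_sequence(m: Mitogenome, gene: str) -> str:
    """Spliced sequence of any feature class (no frame check)."""
    return spliced_cds(m, gene, require_frame=False)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_CLASS_TO_TYPE = {
    "core_pcg": "CDS", "free_orf": "CDS", "plasmid_derived": "CDS",
    "intronic_orf": "CDS", "rrna": "rRNA", "trna": "tRNA",
}


def _infer_gclass(name: str, ftype: str, qualifiers: dict) -> str:
    notes = " ".join(qualifiers.get("note", []))
    for gc in GCLASSES:
        if f"gclass:{gc}" in notes:
            return gc
    base = name.split("-")[0]
    if ftype == "rRNA" or base in RRNAS:
        return "rrna"
    if ftype == "tRNA" or base.startswith("trn"):
        return "trna"
    if base in CORE_PCGS:
        return "core_pcg"
    if base == "dpo" or "polymerase" in " ".join(qualifiers.get("product", [])).lower():
        return "plasmid_derived"
    return "free_orf"


def _coding_order_parts(loc) -> list[tuple[int, int]]:
    """Location parts as 0-based half-open intervals in coding order.

    Biopython already reverses ``complement(join(...))`` parts into
    transcript order on parsing, so the part order can be used directly.
    """
    return [(int(p.start), int(p.end)) for p in loc.parts]


def _derive_introns(f: GeneFeature, genome_length: int) -> list[Intron]:
    introns: list[Intron] = []
    cum = 0
    ordinal = 1
    for prev, nxt in zip(f.exons, f.exons[1:]):
        cum += prev[1] - prev[0]
        if f.strand == 1:
            gap = (prev[1], nxt[0])
        else:
            gap = (nxt[1], prev[0])
        if f.wraps_origin and gap[0] % genome_length == gap[1] % genome_length:
            continue  # origin junction, not an intron
        if gap[1] <= gap[0]:
            continue  # abutting exons (shouldn't normally happen)
        introns.append(Intron(
            host_gene=f.name, ordinal=ordinal, genomic_interval=gap,
            spliced_insertion_point=cum,
        ))
        ordinal += 1
    return introns


def _interval_contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def read_genbank(path: str | Path) -> Mitogenome:
    """Read one annotated mitogenome from a GenBank flat file.

    ``join()`` segments become exons; gaps between consecutive exons become
    :class:`Intron` records; strand comes from ``complement()``; the circular
    flag from the LOCUS topology token.  Intronic ORF features (CDS inside an
    intron of another gene) are kept as features and also flagged on the
    intron record.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    circular = record.annotations.get("topology", "linear") == "circular"
    length = len(record.seq)
    feats: list[GeneFeature] = []
    for sf in record.features:
        if sf.type not in ("CDS", "rRNA", "tRNA"):
            continue
        quals = sf.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
        name = canonical_name(name)
        strand = -1 if sf.location.strand == -1 else 1
        parts = _coding_order_parts(sf.location)
        for s, e in parts:
            if e > length and not circular:
                raise ParseError(
                    f"{path}: feature {name} extends beyond sequence on linear topology"
                )
        gclass = _infer_gclass(name, sf.type, quals)
        wraps = _detect_wrap(parts, strand, length)
        notes = " ".join(quals.get("note", []))
        product = (quals.get("product") or [""])[0]
        gf = GeneFeature(name=name, gclass=gclass, strand=strand, exons=parts,
                         product=product, wraps_origin=wraps)
        gf.introns = _derive_introns(gf, length)
        # ORF family tag written by write_genbank for intronic ORFs
        if gclass == "intronic_orf":
            for fam in ORF_FAMILIES:
                if f"orf_family:{fam}" in notes:
                    gf.product = gf.product or fam
        feats.append(gf)
    # flag introns that contain an intronic ORF
    orf_feats = [f for f in feats if f.gclass == "intronic_orf"]
    for f in feats:
        for intr in f.introns:
            for orf in orf_feats:
                span = (min(e[0] for e in orf.exons), max(e[1] for e in orf.exons))
                if _interval_contains(intr.genomic_interval, span):
                    intr.has_orf = True
                    fam = next((x for x in ORF_FAMILIES if x in (orf.product or "")), "other")
                    intr.orf_family = fam
    return Mitogenome(id=record.id or record.name, sequence=str(record.seq),
                      circular=circular, features=feats)


def _detect_wrap(parts: list[tuple[int, int]], strand: int, length: int) -> bool:
    for a, b in zip(parts, parts[1:]):
        if strand == 1 and a[1] == length and b[0] == 0:
            return True
        if strand == -1 and a[0] == 0 and b[1] == length:
            return True
    return False


def write_genbank(m: Mitogenome, path: str | Path) -> None:
    """Write a Mitogenome as a GenBank flat file (inverse of read_genbank)."""
    record = SeqRecord(Seq(m.sequence), id=m.id, name=m.id[:16].replace(" ", "_"),
                       description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if m.circular else "linear"
    record.annotations["data_file_division"] = "PLN"
    for f in m.features:
        # parts are given in coding order; Biopython renders the GenBank
        # complement(join(...)) dialect from them on writing
        locs = [SimpleLocation(s, e, strand=f.strand) for s, e in f.exons]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = _CLASS_TO_TYPE[f.gclass]
        quals: dict[str, list[str]] = {"gene": [f.name], "note": [f"gclass:{f.gclass}"]}
        if f.product:
            quals["product"] = [f.product]
        if f.gclass == "intronic_orf":
            fam = next((x for x in ORF_FAMILIES if x in (f.product or "")), "other")
            quals["note"].append(f"orf_family:{fam}")
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")
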