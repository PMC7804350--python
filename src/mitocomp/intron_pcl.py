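"""Intron position classes (Pcls) on a reference coding coordinate system.

Mobile group-I introns recur at homologous insertion sites of host genes
(classically cox1) across distant fungi.  Introns from different species are
grouped into a position class when their insertion sites map to the same
nucleotide of a shared reference CDS: the host CDS is codon-aligned to the
reference (protein-guided), and the intron's spliced insertion point is
carried through the alignment columns onto the reference coordinate
(1-based from the reference ATG).  Pcl "P383" is an intron inserted after
reference nucleotide 383.  A Pcl present in more than 1/5 of the species
surveyed is labelled common, otherwise rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core_model import Mitogenome, MitogenomeError, spliced_cds
from .pairalign import codon_align, identity, align_protein
from .core_model import translate

__all__ = [
    "Pcl", "PclMatrix", "HomologyError",
    "map_insertion_site", "classify_pcls", "transfer_candidates",
]

#: Prevalence threshold above which a Pcl counts as common.
COMMON_PREVALENCE = 1.0 / 5.0
#: Minimum host/reference protein identity for a trustworthy mapping.
MIN_PROTEIN_IDENTITY = 0.30


class HomologyError(MitogenomeError):
    """Host gene too diverged from the reference for coordinate mapping."""


@dataclass
class Pcl:
    name: str                      # "P" + 1-based reference position
    ref_position: int
    members: list[tuple[str, str]] = field(default_factory=list)  # (species, intron id)


@dataclass
class PclMatrix:
    """Species x Pcl presence/absence with prevalence labels."""

    matrix: pd.DataFrame           # bool, species rows, Pcl columns
    pcls: list[Pcl]
    unmappable: list[tuple[str, str, str]] = field(default_factory=list)
    # (species, intron id, reason)

    @property
    def prevalence(self) -> pd.Series:
        return self.matrix.sum(axis=0) / len(self.matrix)

    @property
    def labels(self) -> pd.Series:
        return self.prevalence.map(
            lambda p: "common" if p > COMMON_PREVALENCE else "rare")


def map_insertion_site(host_cds: str, ref_cds: str, insertion_point: int) -> int | None:
    """Map a spliced insertion point of the host CDS onto the reference CDS.

    ``insertion_point`` counts spliced coding nucleotides 5' of the intron;
    the returned reference position is 1-based (the intron sits after that
    reference nucleotide).  Returns None when the site falls opposite a
    reference gap (unmappable).  Raises :class:`HomologyError` below the
    protein-identity floor.
    """
    if host_cds == ref_cds:
        return insertion_point
    caln = codon_align(host_cds, ref_cds)
    paln_id = identity(align_protein(translate(host_cds), translate(ref_cds)))
    if paln_id < MIN_PROTEIN_IDENTITY:
        raise HomologyError(
            f"host/reference protein identity {paln_id:.2f} below "
            f"{MIN_PROTEIN_IDENTITY:.2f}")
    return _map_site(list(caln.columns()), insertion_point)


def _map_site(caln_cols: list[tuple[str, str]], insertion_point: int) -> int | None:
    """Carry a host spliced coordinate through alignment columns."""
    host = 0
    ref = 0
    for x, y in caln_cols:
        if x != "-":
            host += 1
        if y != "-":
            ref += 1
        if host == insertion_point and x != "-":
            # intron sits right after this host base; mapped iff this column
            # has a reference base (otherwise we are inside a reference gap)
            return ref if y != "-" else None
    return None


def classify_pcls(genomes: Sequence[Mitogenome], host_gene: str,
                  reference_cds: str) -> PclMatrix:
    """Build the species x Pcl presence/absence matrix for one host gene.

    Every intron of ``host_gene`` in every genome is mapped onto
    ``reference_cds``; introns with identical mapped positions merge into a
    Pcl named P<position>.  Species without the gene or without introns give
    all-false rows; unmappable introns go to a side list, never a column.
    """
    by_pos: dict[int, Pcl] = {}
    unmappable: list[tuple[str, str, str]] = []
    species = [m.id for m in genomes]
    for m in genomes:
        try:
            host_cds = spliced_cds(m, host_gene)
        except KeyError:
            continue
        introns = m.introns(host_gene)
        if not introns:
            continue
        cols = None
        if host_cds != reference_cds:
            caln = codon_align(host_cds, reference_cds)
            pid = identity(align_protein(translate(host_cds), translate(reference_cds)))
            if pid < MIN_PROTEIN_IDENTITY:
                for intr in introns:
                    unmappable.append(
                        (m.id, f"{host_gene}.i{intr.ordinal}",
                         f"protein identity {pid:.2f} below floor"))
                continue
            cols = list(caln.columns())
        for intr in introns:
            iid = f"{host_gene}.i{intr.ordinal}"
            if cols is None:
                pos: int | None = intr.spliced_insertion_point
            else:
                pos = _map_site(cols, intr.spliced_insertion_point)
            if pos is None or pos <= 0:
                unmappable.append((m.id, iid, "site opposite reference gap"))
                continue
            pcl = by_pos.setdefault(pos, Pcl(name=f"P{pos}", ref_position=pos))
            pcl.members.append((m.id, iid))
    pcls = [by_pos[p] for p in sorted(by_pos)]
    mat = pd.DataFrame(False, index=species, columns=[p.name for p in pcls])
    for p in pcls:
        for sp, _ in p.members:
            mat.loc[sp, p.name] = True
    return PclMatrix(matrix=mat, pcls=pcls, unmappable=unmappable)


def transfer_candidates(pm: PclMatrix, groups: dict[str, str]
                        ) -> tuple[list[str], list[str]]:
    """Flag Pcls whose distribution suggests horizontal intron transfer.

    ``groups`` maps species -> clade label.  A Pcl present in exactly one
    species of some clade and also in at least one species outside that clade
    is a transfer candidate.  A Pcl private to a single species overall is
    novel (reported separately), not a transfer.  Returns
    ``(transfer_candidates, novel)`` as Pcl-name lists.
    """
    missing = [sp for sp in pm.matrix.index if sp not in groups]
    if missing:
        raise MitogenomeError(f"species missing from clade map: {missing}")
    transfers: list[str] = []
    novel: list[str] = []
    for name in pm.matrix.columns:
        present = [sp for sp in pm.matrix.index if pm.matrix.loc[sp, name]]
        if len(present) == 1:
            novel.append(name)
            continue
        by_clade: dict[str, int] = {}
        for sp in present:
            by_clade[groups[sp]] = by_clade.get(groups[sp], 0) + 1
        for clade, count in by_clade.items():
            outside = len(present) - count
            if count == 1 and outside >= 1 and len(by_clade) > 1:
                transfers.append(name)
                break
    return transfers, novel
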