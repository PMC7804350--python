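"""Synthetic mitogenome clades with fully known ground truth.

The generator builds an ancestral circular genome (15 core protein-coding
genes, 2 rRNAs, a tRNA set, optional free-standing ORFs and plasmid-derived
DNA-polymerase genes, random intergenic spacers) and derives each taxon from
it by:

1. codon-level substitution with controlled divergence d and selection
   intensity omega (proposals are random single-base changes; changes that
   create stops are rejected; synonymous changes are accepted with
   probability min(1, 1/omega) and nonsynonymous ones with min(1, omega),
   which realises a nonsynonymous/synonymous rate ratio of omega in both the
   purifying and the positive-selection regime);
2. intron insertion at planned reference coding positions (orthologous
   introns share a per-position master sequence, lightly mutated per taxon,
   and may carry an embedded homing-endonuclease-style ORF);
3. inversion / transposition events on the circular gene order;
4. planting of interspersed and tandem repeats into reserved intergenic
   spacers (overwriting spacer bases, so no other coordinate moves);
5. tRNA point mutations.

Every random draw flows through numpy Generators seeded from
``(seed, purpose, indices)``, so a config replays bit-identically and the
event log is exact ground truth for every downstream analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .core_model import (GENETIC_CODE_4, GeneFeature, Intron, Mitogenome,
                         revcomp, write_genbank)

__all__ = ["SimConfig", "SimTruth", "simulate_clade", "replay",
           "DEFAULT_GENE_LENGTHS", "ConfigError", "evolve_cds"]

SCHEMA_TAG = "mitocomp-sim-1"

#: Core gene lengths (codons for PCGs, bp for rRNAs) typical of fungal
#: mitogenomes; cox1 is long enough to host every classic intron site.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp6": 250, "atp8": 48, "atp9": 74, "cob": 380, "cox1": 520,
    "cox2": 250, "cox3": 270, "nad1": 320, "nad2": 480, "nad3": 135,
    "nad4": 450, "nad4L": 89, "nad5": 600, "nad6": 200, "rps3": 470,
    "rnl": 3150, "rns": 1629,
}

DEFAULT_TRNAS: tuple[str, ...] = tuple(
    f"trn{x}" for x in "ACDEFGHIKLMNPQRSTVWY"
)

BASES = "ACGT"


class ConfigError(ValueError):
    """Infeasible or malformed simulation plan."""


@dataclass
class SimConfig:
    seed: int = 0
    n_taxa: int = 6
    taxon_names: list[str] = field(default_factory=list)
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    n_free_orfs: int = 3
    n_dpo: int = 2
    orf_codons: int = 300
    spacer_len: int = 400
    divergence: float = 0.1          # per-taxon substitutions/site from ancestor
    omega: float = 0.2               # default Ka/Ks intensity for PCGs
    gene_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    # e.g. {"rps3": {"divergence": 0.15, "omega": 1.2}}
    groups: list[dict[str, Any]] = field(default_factory=list)
    # e.g. [{"taxa": ["T1","T2"], "shared_fraction": 0.6}]
    intron_plan: list[dict[str, Any]] = field(default_factory=list)
    # e.g. [{"ref_position": 383, "taxa": ["T1"], "has_orf": True,
    #        "orf_family": "LAGLIDADG", "host_gene": "cox1", "length": 360}]
    rearrangement_plan: list[dict[str, Any]] = field(default_factory=list)
    # e.g. [{"taxon": "T3", "op": "inversion", "start": 4, "length": 3}]
    repeat_plan: list[dict[str, Any]] = field(default_factory=list)
    # e.g. [{"taxon": "T1", "length": 300, "identity": 0.9, "tandem": False}]
    trna_mutations: dict[str, int] = field(default_factory=dict)

    def taxa(self) -> list[str]:
        if self.taxon_names:
            if len(self.taxon_names) != self.n_taxa:
                raise ConfigError("taxon_names length != n_taxa")
            return list(self.taxon_names)
        return [f"T{i + 1}" for i in range(self.n_taxa)]

    def gene_param(self, gene: str, key: str, default: float) -> float:
        return float(self.gene_overrides.get(gene, {}).get(key, default))

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "SimConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        return cls(**data)


@dataclass
class SimTruth:
    schema: str
    config: dict[str, Any]
    ancestor_id: str
    gene_orders: dict[str, list[list]]           # taxon -> [[name, sign], ...]
    intron_matrix: dict[str, list[str]]          # "P383" -> taxa carrying it
    planted_repeats: dict[str, list[dict]]       # taxon -> hit/tandem coords
    substitutions: dict[str, dict[str, dict]]    # taxon -> gene -> counts
    trna_mutation_sites: dict[str, dict[str, list[int]]]
    ancestral_sequences: dict[str, str]

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "SimTruth":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        if data.get("schema") != SCHEMA_TAG:
            raise ConfigError(f"truth schema {data.get('schema')!r} != {SCHEMA_TAG!r}")
        return cls(**data)


# ---------------------------------------------------------------------------
# random sequence building blocks
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *key])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA (n_codons includes start and stop)."""
    code = GENETIC_CODE_4
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if not code.is_stop(c):
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def evolve_cds(cds: str, d: float, omega: float,
               rng: np.random.Generator) -> tuple[str, int, int]:
    """Evolve a CDS to ~d accepted substitutions/site under intensity omega.

    Returns (sequence, synonymous count, nonsynonymous count).  The start and
    stop codons are frozen; proposals creating stops are rejected.
    """
    code = GENETIC_CODE_4
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    n_sites = len(cds)
    target = d * n_sites
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    syn = non = 0
    guard = 0
    while syn + non < target and guard < 200 * n_sites:
        guard += 1
        ci = int(rng.integers(1, len(codons) - 1))   # keep start/stop frozen
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        nb = BASES[int(rng.integers(0, 4))]
        if nb == old[pos]:
            continue
        new = old[:pos] + nb + old[pos + 1:]
        if code.is_stop(new):
            continue
        synonymous = code.aa(new) == code.aa(old)
        p = p_syn if synonymous else p_non
        if p < 1.0 and rng.random() >= p:
            continue
        codons[ci] = new
        if synonymous:
            syn += 1
        else:
            non += 1
    return "".join(codons), syn, non


def _evolve_dna(seq: str, d: float, rng: np.random.Generator) -> str:
    """Neutral nucleotide substitution at expected density d (multiple hits
    allowed)."""
    n = int(round(d * len(seq)))
    arr = list(seq)
    for _ in range(n):
        i = int(rng.integers(0, len(arr)))
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _mutate_to_identity(seq: str, identity: float,
                        rng: np.random.Generator) -> str:
    n = int(round((1.0 - identity) * len(seq)))
    arr = list(seq)
    if n == 0:
        return seq
    for i in rng.choice(len(arr), size=min(n, len(arr)), replace=False):
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_PCG_CLASSES = {"core_pcg", "free_orf", "plasmid_derived"}


def _build_roster(cfg: SimConfig) -> list[tuple[str, str]]:
    """(name, gclass) for every ancestral gene."""
    roster: list[tuple[str, str]] = []
    for name in DEFAULT_GENE_LENGTHS:
        if name not in cfg.gene_lengths:
            continue
        roster.append((name, "rrna" if name in ("rnl", "rns") else "core_pcg"))
    for i in range(cfg.n_free_orfs):
        roster.append((f"orf{300 + i}", "free_orf"))
    for i in range(cfg.n_dpo):
        roster.append((f"dpo-{i + 1}", "plasmid_derived"))
    for t in DEFAULT_TRNAS:
        roster.append((t, "trna"))
    return roster


def _validate(cfg: SimConfig) -> None:
    taxa = set(cfg.taxa())
    order_len = sum(1 for n, _ in _build_roster(cfg))
    for plan in cfg.intron_plan:
        host = plan.get("host_gene", "cox1")
        n_codons = cfg.gene_lengths.get(host)
        if n_codons is None:
            raise ConfigError(f"intron plan host {host} not in roster")
        cds_len = 3 * n_codons
        pos = int(plan["ref_position"])
        if not 1 <= pos <= cds_len - 4:
            raise ConfigError(f"intron position {pos} outside host CDS")
        unknown = set(plan.get("taxa", [])) - taxa
        if unknown:
            raise ConfigError(f"intron plan names unknown taxa {sorted(unknown)}")
    for plan in cfg.rearrangement_plan:
        if plan["taxon"] not in taxa:
            raise ConfigError(f"rearrangement taxon {plan['taxon']} unknown")
        if plan.get("op", "inversion") not in ("inversion", "transposition"):
            raise ConfigError(f"unknown rearrangement op {plan.get('op')}")
    per_taxon_windows: dict[str, int] = {}
    for plan in cfg.repeat_plan:
        if plan["taxon"] not in taxa:
            raise ConfigError(f"repeat plan taxon {plan['taxon']} unknown")
        per_taxon_windows[plan["taxon"]] = (
            per_taxon_windows.get(plan["taxon"], 0)
            + (1 if plan.get("tandem") else 2))
    n_spacers = order_len
    for t, w in per_taxon_windows.items():
        if w > n_spacers - 2:
            raise ConfigError(f"too many repeat plantings for taxon {t}")


def _ancestral_genes(cfg: SimConfig) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for gi, (name, gclass) in enumerate(_build_roster(cfg)):
        rng = _rng(cfg.seed, 0, gi)
        if gclass in _PCG_CLASSES:
            n_codons = cfg.gene_lengths.get(name, cfg.orf_codons)
            seqs[name] = _random_cds(rng, n_codons)
        elif gclass == "rrna":
            seqs[name] = _random_dna(rng, cfg.gene_lengths[name])
        else:  # trna
            seqs[name] = _random_dna(rng, int(rng.integers(70, 91)))
    return seqs


def _apply_rearrangements(order: list[tuple[str, int]], plans: list[dict],
                          taxon: str) -> list[tuple[str, int]]:
    order = list(order)
    for plan in plans:
        if plan["taxon"] != taxon:
            continue
        start = int(plan["start"]) % len(order)
        length = int(plan["length"])
        if length < 1 or length >= len(order):
            raise ConfigError("rearrangement block length out of range")
        idx = [(start + i) % len(order) for i in range(length)]
        block = [order[i] for i in idx]
        if plan.get("op", "inversion") == "inversion":
            inverted = [(g, -s) for g, s in reversed(block)]
            for i, item in zip(idx, inverted):
                order[i] = item
        else:  # transposition
            dest = int(plan.get("dest", (start + length + 2))) % len(order)
            remaining = [order[i] for i in range(len(order)) if i not in idx]
            # renumber destination in the reduced list
            dest = dest % (len(remaining) + 1)
            order = remaining[:dest] + block + remaining[dest:]
    return order


def _intron_master(cfg: SimConfig, plan: dict) -> tuple[str, int | None]:
    """Master intron sequence for one planned position; ORF offset if any."""
    pos = int(plan["ref_position"])
    rng = _rng(cfg.seed, 3, pos)
    length = int(plan.get("length", 360))
    seq = _random_dna(rng, length)
    if plan.get("has_orf"):
        orf_codons = max(20, (length - 60) // 3)
        orf = _random_cds(rng, orf_codons)
        off = 30
        seq = seq[:off] + orf + seq[off + len(orf):]
        if len(seq) < length:
            seq = seq + _random_dna(rng, length - len(seq))
        return seq, off
    return seq, None


def simulate_clade(cfg: SimConfig) -> tuple[list[Mitogenome], SimTruth]:
    """Generate a clade of annotated mitogenomes plus exact ground truth."""
    _validate(cfg)
    taxa = cfg.taxa()
    roster = _build_roster(cfg)
    anc = _ancestral_genes(cfg)
    anc_spacers = {i: _random_dna(_rng(cfg.seed, 6, i), cfg.spacer_len)
                   for i in range(len(roster) + 1)}

    # ancestral order and strands
    rng_layout = _rng(cfg.seed, 7)
    perm = list(rng_layout.permutation(len(roster)))
    strands = [1 if rng_layout.random() < 0.8 else -1 for _ in roster]
    anc_order = [(roster[i][0], strands[j]) for j, i in enumerate(perm)]
    gclass_of = dict(roster)

    group_of: dict[str, tuple[int, float]] = {}
    for g_idx, grp in enumerate(cfg.groups):
        for t in grp.get("taxa", []):
            group_of[t] = (g_idx, float(grp.get("shared_fraction", 0.5)))

    intron_masters = {int(p["ref_position"]): _intron_master(cfg, p)
                      for p in cfg.intron_plan}

    genomes: list[Mitogenome] = []
    truth_orders: dict[str, list[list]] = {}
    truth_introns: dict[str, list[str]] = {}
    truth_repeats: dict[str, list[dict]] = {}
    truth_subs: dict[str, dict[str, dict]] = {}
    truth_trna: dict[str, dict[str, list[int]]] = {}
    group_cache: dict[tuple[int, str], tuple[str, int, int]] = {}

    gene_index = {name: i for i, (name, _) in enumerate(roster)}

    for t_idx, taxon in enumerate(taxa):
        # --- 1. sequence evolution -------------------------------------
        gene_seqs: dict[str, str] = {}
        subs: dict[str, dict] = {}
        for name, gclass in roster:
            gi = gene_index[name]
            d = cfg.gene_param(name, "divergence", cfg.divergence)
            omega = cfg.gene_param(name, "omega", cfg.omega)
            if gclass in _PCG_CLASSES:
                base, syn0, non0 = anc[name], 0, 0
                if taxon in group_of:
                    g_idx, f = group_of[taxon]
                    key = (g_idx, name)
                    if key not in group_cache:
                        group_cache[key] = evolve_cds(
                            anc[name], f * d, omega, _rng(cfg.seed, 2, g_idx, gi))
                    base, syn0, non0 = group_cache[key]
                    d = (1.0 - f) * d
                seq, syn, non = evolve_cds(base, d, omega,
                                           _rng(cfg.seed, 1, t_idx, gi))
                subs[name] = {"syn": syn + syn0, "nonsyn": non + non0,
                              "omega": omega}
                gene_seqs[name] = seq
            elif gclass == "rrna":
                if taxon in group_of:
                    g_idx, f = group_of[taxon]
                    key = (g_idx, name)
                    if key not in group_cache:
                        group_cache[key] = (
                            _evolve_dna(anc[name], f * d,
                                        _rng(cfg.seed, 2, g_idx, gi)), 0, 0)
                    base = group_cache[key][0]
                    seq = _evolve_dna(base, (1.0 - f) * d,
                                      _rng(cfg.seed, 1, t_idx, gi))
                else:
                    seq = _evolve_dna(anc[name], d, _rng(cfg.seed, 1, t_idx, gi))
                gene_seqs[name] = seq
            else:
                gene_seqs[name] = anc[name]   # tRNAs mutate via the tRNA plan

        # --- tRNA point mutations ---------------------------------------
        trna_sites: dict[str, list[int]] = {}
        n_mut = int(cfg.trna_mutations.get(taxon, 0))
        if n_mut:
            rng_t = _rng(cfg.seed, 5, t_idx)
            trna_names = [n for n, gc in roster if gc == "trna"]
            for _ in range(n_mut):
                tn = trna_names[int(rng_t.integers(0, len(trna_names)))]
                seq = gene_seqs[tn]
                pos = int(rng_t.integers(0, len(seq)))
                choices = [b for b in BASES if b != seq[pos]]
                gene_seqs[tn] = (seq[:pos] + choices[int(rng_t.integers(0, 3))]
                                 + seq[pos + 1:])
                trna_sites.setdefault(tn, []).append(pos + 1)
        truth_trna[taxon] = trna_sites

        # --- 2. intron plan for this taxon -------------------------------
        introns_by_host: dict[str, list[dict]] = {}
        for plan in cfg.intron_plan:
            if taxon not in plan.get("taxa", []):
                continue
            pos = int(plan["ref_position"])
            master, orf_off = intron_masters[pos]
            rng_i = _rng(cfg.seed, 8, t_idx, pos)
            seq = _mutate_to_identity(master, 0.98, rng_i) if orf_off is None \
                else master  # keep ORF frames intact for carriers
            introns_by_host.setdefault(plan.get("host_gene", "cox1"), []).append({
                "position": pos, "seq": seq, "orf_offset": orf_off,
                "orf_family": plan.get("orf_family", "LAGLIDADG"),
                "has_orf": bool(plan.get("has_orf")),
            })
            truth_introns.setdefault(f"P{pos}", []).append(taxon)

        # --- 3. gene order ------------------------------------------------
        order = _apply_rearrangements(anc_order, cfg.rearrangement_plan, taxon)
        truth_orders[taxon] = [[g, s] for g, s in order]

        # --- 4. spacer sizing for repeat plan ----------------------------
        my_repeats = [p for p in cfg.repeat_plan if p["taxon"] == taxon]
        windows_needed: list[int] = []
        for p in my_repeats:
            if p.get("tandem"):
                unit = int(p.get("unit_length", p.get("length", 30)))
                copies = float(p.get("copies", 2))
                windows_needed.append(int(unit * copies) + 20)
            else:
                windows_needed.extend([int(p["length"]) + 20] * 2)

        # --- 5. layout ----------------------------------------------------
        genome, features, spacer_spans = _layout(
            cfg, taxon, order, gene_seqs, gclass_of, introns_by_host,
            anc_spacers, windows_needed)

        # --- 6. plant repeats ----------------------------------------------
        planted = _plant_repeats(cfg, t_idx, genome, spacer_spans, my_repeats)
        truth_repeats[taxon] = planted["log"]
        genome = planted["sequence"]

        truth_subs[taxon] = subs
        genomes.append(Mitogenome(id=taxon, sequence=genome, circular=True,
                                  features=features))

    truth = SimTruth(
        schema=SCHEMA_TAG,
        config=dataclasses.asdict(cfg),
        ancestor_id="ancestor",
        gene_orders=truth_orders,
        intron_matrix={k: sorted(set(v)) for k, v in truth_introns.items()},
        planted_repeats=truth_repeats,
        substitutions=truth_subs,
        trna_mutation_sites=truth_trna,
        ancestral_sequences=anc,
    )
    return genomes, truth


def _layout(cfg, taxon, order, gene_seqs, gclass_of, introns_by_host,
            anc_spacers, windows_needed):
    """Assemble the genome string and features; return spacer spans too."""
    parts: list[str] = []
    features: list[GeneFeature] = []
    spacer_spans: list[tuple[int, int]] = []
    cursor = 0
    windows = list(windows_needed)
    copy_counter: dict[str, int] = {}
    for slot, (name, strand) in enumerate(order):
        # spacer before each gene; enlarge while repeat windows remain
        base_spacer = anc_spacers[slot]
        if windows:
            need = windows.pop(0)
            if need > len(base_spacer):
                base_spacer = base_spacer + _random_dna(
                    _rng(cfg.seed, 9, slot), need - len(base_spacer))
        parts.append(base_spacer)
        spacer_spans.append((cursor, cursor + len(base_spacer)))
        cursor += len(base_spacer)

        gclass = gclass_of[name]
        seq = gene_seqs[name]
        plan = sorted(introns_by_host.get(name, []), key=lambda p: p["position"])
        seg, exon_offsets, intron_records, orf_feats = _gene_segment(
            name, seq, strand, plan, cursor)
        parts.append(seg)
        feat = GeneFeature(name=name, gclass=gclass, strand=strand,
                           exons=exon_offsets)
        feat.introns = intron_records
        features.append(feat)
        features.extend(orf_feats)
        cursor += len(seg)
    parts.append(anc_spacers[len(order)])
    spacer_spans.append((cursor, cursor + len(anc_spacers[len(order)])))
    return "".join(parts), features, spacer_spans


def _gene_segment(name, cds, strand, intron_plan, offset):
    """Build the genomic segment of one gene with introns inserted.

    Returns (segment, exons in coding order with genomic coords, introns,
    intronic ORF features).
    """
    cuts = [0] + [p["position"] for p in intron_plan] + [len(cds)]
    exon_seqs = [cds[a:b] for a, b in zip(cuts, cuts[1:])]
    # coding-orientation layout: exon1 intron1 exon2 ...
    coding_parts: list[tuple[str, str, dict | None]] = []
    for i, es in enumerate(exon_seqs):
        coding_parts.append(("exon", es, None))
        if i < len(intron_plan):
            coding_parts.append(("intron", intron_plan[i]["seq"], intron_plan[i]))
    pre = "".join(s for _, s, _ in coding_parts)
    seg = pre if strand == 1 else revcomp(pre)
    L = len(pre)

    def genomic(a: int, b: int) -> tuple[int, int]:
        # map coding-orientation [a,b) within the segment to genomic coords
        if strand == 1:
            return offset + a, offset + b
        return offset + (L - b), offset + (L - a)

    exons: list[tuple[int, int]] = []
    introns: list[Intron] = []
    orf_feats: list[GeneFeature] = []
    pos = 0
    spliced = 0
    ordinal = 1
    for kind, s, plan in coding_parts:
        start, end = pos, pos + len(s)
        if kind == "exon":
            exons.append(genomic(start, end))
            spliced += len(s)
        else:
            intr = Intron(host_gene=name, ordinal=ordinal,
                          genomic_interval=genomic(start, end),
                          spliced_insertion_point=spliced,
                          has_orf=bool(plan["has_orf"]),
                          orf_family=plan["orf_family"] if plan["has_orf"] else "none")
            introns.append(intr)
            if plan["orf_offset"] is not None:
                orf_cod_start = start + plan["orf_offset"]
                orf_len = _orf_len_in(plan["seq"], plan["orf_offset"])
                g = genomic(orf_cod_start, orf_cod_start + orf_len)
                orf_feats.append(GeneFeature(
                    name=f"{name}-i{ordinal}-orf", gclass="intronic_orf",
                    strand=strand, exons=[g],
                    product=plan["orf_family"]))
            ordinal += 1
        pos = end
    return seg, exons, introns, orf_feats


def _orf_len_in(intron_seq: str, offset: int) -> int:
    """Length of the embedded ORF (ATG..stop) starting at offset."""
    code = GENETIC_CODE_4
    i = offset
    while i + 3 <= len(intron_seq):
        if code.is_stop(intron_seq[i:i + 3]):
            return i + 3 - offset
        i += 3
    return len(intron_seq) - offset


def _plant_repeats(cfg, t_idx, genome, spacer_spans, plans):
    """Overwrite reserved spacer windows with planted repeats."""
    arr = list(genome)
    log: list[dict] = []
    free = [list(s) for s in spacer_spans if s[1] - s[0] >= 40]
    widx = 0
    for p_idx, p in enumerate(plans):
        rng = _rng(cfg.seed, 4, t_idx, p_idx)
        if p.get("tandem"):
            unit_len = int(p.get("unit_length", p.get("length", 30)))
            copies = float(p.get("copies", 2))
            span = int(unit_len * copies)
            unit = _random_dna(rng, unit_len)
            s0 = _take_window(free, widx, span)
            widx += 1
            rep = (unit * (int(copies) + 1))[:span]
            arr[s0:s0 + span] = list(rep)
            log.append({"kind": "tandem", "start": s0, "unit_length": unit_len,
                        "copies": copies, "span": span})
        else:
            length = int(p["length"])
            ident = float(p.get("identity", 1.0))
            copy_a = _random_dna(rng, length)
            copy_b = _mutate_to_identity(copy_a, ident, rng)
            s0 = _take_window(free, widx, length)
            widx += 1
            s1 = _take_window(free, widx, length)
            widx += 1
            arr[s0:s0 + length] = list(copy_a)
            arr[s1:s1 + length] = list(copy_b)
            log.append({"kind": "interspersed", "interval_a": [s0, s0 + length],
                        "interval_b": [s1, s1 + length], "identity": ident})
    return {"sequence": "".join(arr), "log": log}


def _take_window(free: list[list[int]], widx: int, span: int) -> int:
    for w in free:
        if w[1] - w[0] >= span + 10:
            start = w[0] + 5
            w[0] = start + span + 5
            return start
    raise ConfigError("no spacer window large enough for planted repeat")


def replay(truth: SimTruth) -> list[Mitogenome]:
    """Regenerate the clade bit-identically from the truth's config."""
    cfg = SimConfig(**truth.config)
    genomes, _ = simulate_clade(cfg)
    return genomes


def write_clade(genomes: Sequence[Mitogenome], truth: SimTruth,
                out_dir: str | Path) -> list[Path]:
    """Write GenBank files plus truth JSON; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in genomes:
        p = out / f"{m.id}.gb"
        write_genbank(m, p)
        paths.append(p)
    tp = out / "truth.json"
    truth.to_json(tp)
    paths.append(tp)
    return paths
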