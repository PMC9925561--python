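"""Seeded generator of synthetic host assemblies with planted plasmids.

Every feature the detection pipeline looks for can be planted with known
coordinates: invertron and non-invertron linear plasmids (TIR-capped,
polymerase ORF pairs back-translated from a reference protein panel),
recent mitochondrial insertions (plasmid plus mtDNA-derived flanks,
optionally degraded by substitutions, forced stop codons and
fragmentation), captured tRNA genes with mtDNA-derived flanks from a
donor genome, mitochondrial tRNA loss (gene plus 300 nt of flank deleted),
decoy contigs stressing the size filter, and controllable codon-family
usage of the 14 principal genes. The ground truth is returned as a
machine-readable manifest keyed by the seed; identical config + seed give
byte-identical output.

Plasmid polymerases are evolved along a known plasmid phylogeny so that
the distance-based tree stand-in can recover the true topology and
transfer events can be counted against a designed truth: in the default
dataset the captures are placed so that every capture-bearing leaf has a
capture-free sister, forcing six independent transfer events (three of
tRNA-Arg(TCG), two of tRNA-Cys, one of tRNA-Trp), with two mitochondrial
losses — the configuration reported for the real Lyophyllaceae data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import load_family_map
from .seqs import (ANNOTATION_COLUMNS, GeneticCode, MOLD_MITO, SequenceRecord,
                   revcomp, translate, write_annotations, write_fasta)
from .trna import TrnaGene

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# amino-acid lengths typical of fungal mitochondrial proteins
GENE_LENGTHS_AA = {
    "atp6": 250, "atp8": 48, "atp9": 74, "cob": 385, "cox1": 530,
    "cox2": 250, "cox3": 270, "nad1": 355, "nad2": 490, "nad3": 120,
    "nad4": 490, "nad4L": 90, "nad5": 670, "nad6": 200,
}

# relative codon-family usage; the two captured-in-Lyophyllaceae families
# (Arg-TCG and Cys-GCA) carry the smallest weights, as observed in real
# fungal mitochondrial genomes
DEFAULT_FAMILY_WEIGHTS = {
    "Ala-TGC": 4.0, "Arg-TCG": 0.25, "Arg-TCT": 2.0, "Asn-GTT": 5.0,
    "Asp-GTC": 3.0, "Cys-GCA": 0.35, "Gln-TTG": 2.0, "Glu-TTC": 3.0,
    "Gly-TCC": 4.5, "His-GTG": 1.5, "Ile-GAT": 7.0, "Ile-TAT": 1.5,
    "Leu-TAA": 8.0, "Leu-TAG": 2.0, "Lys-TTT": 4.5, "Met-CAT": 2.2,
    "Phe-GAA": 6.0, "Pro-TGG": 3.0, "Ser-TGA": 4.0, "Ser-GCT": 2.2,
    "Thr-TGT": 3.5, "Trp-TCA": 1.8, "Tyr-GTA": 3.5, "Val-TAC": 4.5,
}


@dataclass
class Degradation:
    substitution_rate: float = 0.02
    stop_codons: int = 0  # forced in-frame stops per polymerase ORF
    fragments: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")


@dataclass
class CaptureScenario:
    trna_name: str  # isotype-anticodon, e.g. "Arg-TCG"
    flank_nt: int = 300
    trna_divergence: float = 0.0
    flank_divergence: float = 0.05
    loss: bool = False  # delete the mitochondrial copy from the host
    donor_host: int | None = None  # mtDNA providing the flanks; None = host itself


@dataclass
class PlasmidScenario:
    host: int
    structure: str = "invertron"  # invertron | non_invertron_linear
    inserted: bool = False
    split: bool = False  # emit as two contigs broken at the midpoint
    capture: CaptureScenario | None = None
    degradation: Degradation | None = None
    homology_blocks: tuple[int, ...] = ()  # extra mtDNA-derived blocks (nt)


def default_plasmid_scenarios() -> list[PlasmidScenario]:
    return [
        PlasmidScenario(host=0),
        PlasmidScenario(host=1, capture=CaptureScenario("Arg-TCG")),
        PlasmidScenario(host=2, capture=CaptureScenario("Arg-TCG", loss=True, donor_host=1)),
        PlasmidScenario(host=3, capture=CaptureScenario("Cys-GCA")),
        PlasmidScenario(host=4, capture=CaptureScenario("Cys-GCA", loss=True, donor_host=3)),
        PlasmidScenario(host=5, structure="non_invertron_linear"),
        PlasmidScenario(host=6, structure="non_invertron_linear",
                        capture=CaptureScenario("Trp-TCA")),
        PlasmidScenario(host=7, inserted=True, degradation=Degradation()),
        PlasmidScenario(host=8, inserted=True, degradation=Degradation()),
        PlasmidScenario(host=9, inserted=True, degradation=Degradation()),
        PlasmidScenario(host=10),
        PlasmidScenario(host=10, capture=CaptureScenario("Arg-TCG")),
    ]


# the default plasmid phylogeny: three quartets off the root, every
# capture-bearing leaf (scenario indices 1,2,3,4,6,11) paired with a
# capture-free sister, so each capture is an independent origin
DEFAULT_TREE_SHAPE = "(((1,0),(3,5)),((2,7),(4,8)),((11,10),(6,9)));"


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_hosts: int = 20
    mtdna_length: int = 24000
    gene_lengths_aa: dict[str, int] = field(default_factory=lambda: dict(GENE_LENGTHS_AA))
    family_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS))
    trna_length: int = 72
    anticodon_offset: int = 33
    n_decoys: int = 50
    decoy_inwindow_fraction: float = 0.2
    plasmid_size_range: tuple[int, int] = (5000, 15000)
    tir_length: int = 300
    dnapol_aa: int = 900
    rnapol_aa: int = 800
    root_divergence: float = 0.08  # panel -> plasmid-tree root, aa
    edge_divergence: tuple[float, float] = (0.015, 0.03)  # per-edge aa range
    intergenic_nt: int = 1200  # plasmid ORF1-ORF2 spacer budget
    pad_nt: int = 150  # TIR-to-ORF pads
    insertion_flank_nt: int = 1000
    plasmids: list[PlasmidScenario] = field(default_factory=default_plasmid_scenarios)
    tree_shape: str | None = DEFAULT_TREE_SHAPE

    def __post_init__(self) -> None:
        for sc in self.plasmids:
            if sc.host >= self.n_hosts:
                raise ValueError(f"plasmid scenario host {sc.host} >= n_hosts")


@dataclass
class HostAssembly:
    host_id: str
    contigs: list[SequenceRecord]
    mtdna: SequenceRecord
    annotations: pd.DataFrame
    plasmid_ids: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    config: GeneratorConfig
    hosts: list[HostAssembly]
    trna_refs: list[TrnaGene]
    panel: list[SequenceRecord]
    manifest: dict


# ---------------------------------------------------------------------------
# low-level helpers

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def random_protein(rng: np.random.Generator, n: int) -> str:
    aa = np.array(list(AA20))
    return "".join(aa[rng.integers(0, len(aa), size=n)])


def mutate_dna(seq: str, rate: float, rng: np.random.Generator,
               transition_bias: float = 2.0) -> str:
    """Independent per-site substitution with a transition:transversion bias."""
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hit = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hit:
        base = chars[i]
        if base not in _TRANSITION:
            continue
        ts = _TRANSITION[base]
        tv = [b for b in "ACGT" if b not in (base, ts)]
        weights = np.array([transition_bias, 1.0, 1.0])
        probs = weights / weights.sum()
        chars[i] = str(rng.choice([ts] + tv, p=probs))
    return "".join(chars)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hit = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hit:
        options = [a for a in AA20 if a != chars[i]]
        chars[i] = str(rng.choice(options))
    return "".join(chars)


def _aa_to_codons(code: GeneticCode) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in sorted(code.codon_to_aa.items()):
        if aa == "*":
            continue
        table.setdefault(aa, []).append(codon)
    return table


def back_translate(protein: str, rng: np.random.Generator,
                   code: GeneticCode = MOLD_MITO) -> str:
    """Encode a protein with uniformly chosen sense codons (never a stop)."""
    table = _aa_to_codons(code)
    return "".join(table[aa][rng.integers(0, len(table[aa]))] for aa in protein)


def repair_orf_stops(seq: str, spans: Sequence[tuple[int, int, str]],
                     rng: np.random.Generator, code: GeneticCode = MOLD_MITO) -> str:
    """Replace any in-frame stop codon inside the given ORF spans."""
    stops = code.stop_codons
    chars = list(seq)
    table = _aa_to_codons(code)
    sense = sorted(c for cs in table.values() for c in cs)
    for start, end, strand in spans:
        sub = "".join(chars[start:end])
        if strand == "-":
            sub = revcomp(sub)
        codons = [sub[i:i + 3] for i in range(0, len(sub), 3)]
        for k, codon in enumerate(codons):
            if codon in stops:
                codons[k] = sense[rng.integers(0, len(sense))]
        fixed = "".join(codons)
        if strand == "-":
            fixed = revcomp(fixed)
        chars[start:end] = list(fixed)
    return "".join(chars)


def restore_orf_bounds(seq: str, spans: Sequence[tuple[int, int, str]]) -> str:
    """Re-plant the stop codons bounding each ORF span.

    Degradation substitutions may erase a boundary stop, which would let
    the reading frame run into the neighbouring sequence and shift the
    apparent ORF; a near-intact insertion keeps its gene boundaries.
    """
    chars = list(seq)
    for start, end, strand in spans:
        stop = "TAA" if strand == "+" else revcomp("TAA")
        if start >= 3:
            chars[start - 3:start] = list(stop)
        if end + 3 <= len(chars):
            chars[end:end + 3] = list(stop)
    return "".join(chars)


def force_orf_stops(seq: str, spans: Sequence[tuple[int, int, str]],
                    n_stops: int, rng: np.random.Generator) -> str:
    """Overwrite ``n_stops`` codons of each ORF span with TAA.

    Placement is stratified (one stop per equal-width bin) so the longest
    surviving stop-free stretch is at most ~2/(n_stops+1) of the ORF —
    with five or more stops a 2.7 kb polymerase can no longer present a
    1 kb open frame.
    """
    chars = list(seq)
    for start, end, strand in spans:
        n_codons = (end - start) // 3
        n = min(n_stops, max(1, n_codons - 2))
        edges = np.linspace(1, n_codons - 1, n + 1)
        picks = []
        for i in range(n):
            w = edges[i + 1] - edges[i]
            lo = int(edges[i] + 0.25 * w)  # middle half of each bin: the
            hi = int(edges[i] + 0.75 * w)  # longest gap stays < 1.5 bins
            picks.append(int(rng.integers(lo, max(lo + 1, hi))))
        for k in picks:
            codon = "TAA" if strand == "+" else revcomp("TAA")
            pos = start + 3 * int(k)
            chars[pos:pos + 3] = list(codon)
    return "".join(chars)


# ---------------------------------------------------------------------------
# tRNA reference set


def generate_trna_refs(config: GeneratorConfig, rng: np.random.Generator) -> list[TrnaGene]:
    """One random gene per entry of the shipped 24-tRNA family map."""
    fam_map = load_family_map()
    refs = []
    for fam in fam_map:
        n = config.trna_length
        seq = list(random_dna(rng, n))
        off = config.anticodon_offset
        seq[off:off + 3] = list(fam.anticodon)
        refs.append(TrnaGene(isotype=fam.isotype, anticodon=fam.anticodon,
                             residues="".join(seq), source_id="reference",
                             anticodon_offset=off))
    return refs


# ---------------------------------------------------------------------------
# mtDNA


def _codon_distribution(config: GeneratorConfig, code: GeneticCode):
    fam_map = load_family_map(code=code)
    codons, probs = [], []
    for fam in fam_map:
        w = config.family_weights.get(fam.name, 1.0)
        for c in fam.codons:
            codons.append(c)
            probs.append(w / len(fam.codons))
    probs = np.array(probs)
    return codons, probs / probs.sum()


def generate_mtdna(config: GeneratorConfig, rng: np.random.Generator,
                   host_id: str, trna_refs: Sequence[TrnaGene] | None = None,
                   capturable: Sequence[str] = (),
                   reserve_insertion_site: bool = False,
                   code: GeneticCode = MOLD_MITO,
                   ) -> tuple[SequenceRecord, pd.DataFrame, int | None]:
    """A mitochondrial genome: 14 principal CDSs, 24 tRNAs, random spacers.

    Codons of the CDSs are drawn from the configured family weights. The
    tRNA gene sequences come from ``trna_refs`` (shared across hosts —
    mitochondrial tRNAs are conserved; derived from the config seed when
    not supplied). tRNAs named in ``capturable`` get >= 450 nt of
    tRNA-free spacer on each side so a 300 nt capture flank never swallows
    a neighbouring gene. With ``reserve_insertion_site`` a wide spacer
    between two protein genes is reserved and its centre returned as a
    safe insertion point.
    """
    codons, probs = _codon_distribution(config, code)
    if trna_refs is None:
        trna_refs = generate_trna_refs(config, np.random.default_rng(config.seed + 10**6))
    genes = list(config.gene_lengths_aa)
    # layout: alternate genes and tRNA runs; capturable tRNAs placed
    # immediately after a protein gene with wide spacers
    capturable = set(capturable)
    cap_trnas = [t for t in trna_refs if t.name in capturable]
    other_trnas = [t for t in trna_refs if t.name not in capturable]
    features: list[tuple[str, object]] = []
    gi, ti = 0, 0
    for k, gene in enumerate(genes):
        features.append(("gene", gene))
        if k < len(cap_trnas):
            features.append(("cap_trna", cap_trnas[k]))
        if reserve_insertion_site and k == len(genes) // 2:
            features.append(("insertion_site", None))
        run = other_trnas[ti: ti + 2]
        ti += 2
        for t in run:
            features.append(("trna", t))
    features.extend(("trna", t) for t in other_trnas[ti:])

    wide = 450
    insert_width = 2 * config.insertion_flank_nt + 200
    fixed = sum(3 * config.gene_lengths_aa[g] + 6 for g in genes) \
        + len(trna_refs) * config.trna_length \
        + (insert_width if reserve_insertion_site else 0) \
        + len(cap_trnas) * 2 * wide
    n_spacers = len(features) + 1
    budget = config.mtdna_length - fixed
    if budget < n_spacers * 40:
        raise ValueError("mtdna_length too small for the configured gene set")
    cuts = rng.multinomial(budget - n_spacers * 40, np.ones(n_spacers) / n_spacers)
    spacer_lens = [40 + int(c) for c in cuts]

    parts: list[str] = []
    rows = []
    pos = 0
    safe_point: int | None = None

    def add(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    for k, (kind, payload) in enumerate(features):
        spacer = spacer_lens[k]
        if kind == "cap_trna":
            add(random_dna(rng, wide))
        else:
            add(random_dna(rng, spacer))
        if kind == "gene":
            gene = payload
            n_aa = config.gene_lengths_aa[gene]
            body = "ATG" + "".join(
                np.array(codons)[rng.choice(len(codons), size=n_aa - 1, p=probs)]) + "TAA"
            rows.append({"seq_id": host_id + "_mtDNA", "feature": "CDS",
                         "start": pos, "end": pos + len(body), "strand": "+",
                         "label": gene})
            add(body)
        elif kind in ("trna", "cap_trna"):
            t = payload
            rows.append({"seq_id": host_id + "_mtDNA", "feature": "tRNA",
                         "start": pos, "end": pos + len(t.residues), "strand": "+",
                         "label": t.name})
            add(t.residues)
            if kind == "cap_trna":
                add(random_dna(rng, wide))
        elif kind == "insertion_site":
            add(random_dna(rng, config.insertion_flank_nt + 100))
            safe_point = pos
            add(random_dna(rng, config.insertion_flank_nt + 100))
    add(random_dna(rng, spacer_lens[-1]))

    seq = "".join(parts)
    record = SequenceRecord(id=host_id + "_mtDNA", residues=seq,
                            description="synthetic mitochondrial genome")
    return record, pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), safe_point


def delete_trna_locus(mtdna: SequenceRecord, annotations: pd.DataFrame,
                      trna_name: str, margin: int = 300,
                      ) -> tuple[SequenceRecord, pd.DataFrame, tuple[int, int]]:
    """Remove a tRNA gene plus ``margin`` nt of flank on each side."""
    hits = annotations[(annotations.feature == "tRNA")
                       & (annotations.label == trna_name)]
    if hits.empty:
        raise ValueError(f"{mtdna.id}: no tRNA feature {trna_name!r}")
    row = hits.iloc[0]
    lo = max(0, int(row.start) - margin)
    hi = min(len(mtdna.residues), int(row.end) + margin)
    seq = mtdna.residues[:lo] + mtdna.residues[hi:]
    out_rows = []
    for _, r in annotations.iterrows():
        if r.start >= lo and r.end <= hi:
            continue  # deleted (the tRNA itself; neighbours never overlap)
        shift = (hi - lo) if r.start >= hi else 0
        rr = dict(r)
        rr["start"] = int(r.start) - shift
        rr["end"] = int(r.end) - shift
        out_rows.append(rr)
    rec = SequenceRecord(id=mtdna.id, residues=seq, description=mtdna.description)
    return rec, pd.DataFrame(out_rows, columns=ANNOTATION_COLUMNS), (lo, hi)


# ---------------------------------------------------------------------------
# plasmids


@dataclass
class _PlasmidBuild:
    seq: str
    tir: tuple[int, int, int, int]  # left_start, left_end, right_start, right_end
    orfs: list[tuple[int, int, str]]
    capture: dict | None
    homology_blocks: list[dict]


def _build_plasmid_sequence(config: GeneratorConfig, rng: np.random.Generator,
                            dnapol_nt: str, rnapol_nt: str, structure: str,
                            capture_block: str | None,
                            homology_blocks: Sequence[str] = ()) -> _PlasmidBuild:
    tir = random_dna(rng, config.tir_length)
    pad1 = random_dna(rng, config.pad_nt)
    pad2 = random_dna(rng, config.pad_nt)
    # mismatch collars just inside each TIR: an A at both inner boundaries
    # can never pair with itself, so seed-and-extend stops exactly at the
    # planted repeat
    pad1 = "AA" + pad1[2:]
    pad2 = pad2[:-2] + "AA"

    extras = list(homology_blocks)
    ig_budget = config.intergenic_nt
    blocks: list[str] = []
    if capture_block is not None:
        blocks.append(capture_block)
    blocks.extend(extras)
    gap = max(60, (ig_budget) // (len(blocks) + 1)) if blocks else ig_budget

    parts: list[str] = []
    pos = 0
    orfs: list[tuple[int, int, str]] = []
    capture_coords = None
    block_coords: list[dict] = []

    def add(s: str) -> int:
        nonlocal pos
        parts.append(s)
        start = pos
        pos += len(s)
        return start

    add(tir)
    add(pad1)
    add("TAA")
    s0 = add(dnapol_nt)
    orfs.append((s0, s0 + len(dnapol_nt), "+"))
    add("TAA")
    # intergenic with optional capture and homology blocks
    add(random_dna(rng, gap))
    for bi, block in enumerate(blocks):
        start = add(block)
        if capture_block is not None and bi == 0:
            capture_coords = (start, start + len(block))
        else:
            block_coords.append({"start": start, "end": start + len(block),
                                 "length": len(block)})
        add(random_dna(rng, gap))
    if structure == "invertron":
        body = revcomp("TAA" + rnapol_nt + "TAA")
        s1 = add(body)
        orfs.append((s1 + 3, s1 + 3 + len(rnapol_nt), "-"))
    else:
        add("TAA")
        s1 = add(rnapol_nt)
        orfs.append((s1, s1 + len(rnapol_nt), "+"))
        add("TAA")
    add(pad2)
    r0 = add(revcomp(tir))
    seq = "".join(parts)
    lo, hi = config.plasmid_size_range
    if not lo <= len(seq) <= hi:
        raise ValueError(f"plasmid length {len(seq)} outside the configured "
                         f"window {config.plasmid_size_range}")
    build = _PlasmidBuild(
        seq=seq,
        tir=(0, config.tir_length, r0, r0 + config.tir_length),
        orfs=orfs,
        capture={"start": capture_coords[0], "end": capture_coords[1]}
        if capture_coords else None,
        homology_blocks=block_coords)
    return build


def _tree_from_shape(shape: str, n_leaves: int, rng: np.random.Generator):
    import dendropy

    if shape is None:
        # random caterpillar over leaf indices
        leaves = list(rng.permutation(n_leaves))
        newick = str(leaves[0])
        for l in leaves[1:]:
            newick = f"({newick},{l})"
        shape = newick + ";"
    tree = dendropy.Tree.get(data=shape, schema="newick",
                             suppress_internal_node_taxa=True)
    labels = {int(t.label) for t in tree.taxon_namespace}
    if labels != set(range(n_leaves)):
        raise ValueError("tree_shape leaves must be 0..n_plasmids-1")
    return tree


def _evolve_polymerases(config: GeneratorConfig, rng: np.random.Generator,
                        panel: Sequence[SequenceRecord], n_leaves: int,
                        ) -> tuple[dict[int, tuple[str, str]], str]:
    """Evolve the two panel proteins down the plasmid tree; return leaf seqs."""
    tree = _tree_from_shape(config.tree_shape, n_leaves, rng)
    lo, hi = config.edge_divergence
    root_prot = (mutate_protein(panel[0].residues, config.root_divergence, rng),
                 mutate_protein(panel[1].residues, config.root_divergence, rng))
    states: dict = {tree.seed_node: root_prot}
    leaf_seqs: dict[int, tuple[str, str]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            rate = float(rng.uniform(lo, hi))
            parent = states[node.parent_node]
            states[node] = (mutate_protein(parent[0], rate, rng),
                            mutate_protein(parent[1], rate, rng))
        if node.is_leaf():
            leaf_seqs[int(node.taxon.label)] = states[node]
    return leaf_seqs, tree.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# degraded insertion into an mtDNA sequence


def insert_degraded_copy(mtdna: SequenceRecord, plasmid_seq: str,
                         orf_spans: Sequence[tuple[int, int, str]],
                         degradation: Degradation, rng: np.random.Generator,
                         position: int | None = None,
                         ) -> tuple[SequenceRecord, list[dict]]:
    """Insert a (possibly fragmented, degraded) plasmid copy into an mtDNA.

    Substitutions are applied first, then ``stop_codons`` forced TAAs per
    polymerase ORF; the copy is split into ``fragments`` pieces inserted in
    tandem with short random spacers. Returns the mutated record plus one
    manifest entry per fragment.
    """
    seq = mutate_dna(plasmid_seq, degradation.substitution_rate, rng)
    if degradation.stop_codons:
        seq = force_orf_stops(seq, orf_spans, degradation.stop_codons, rng)
    if position is None:
        position = int(rng.integers(0, len(mtdna.residues)))
    k = max(1, degradation.fragments)
    bounds = np.linspace(0, len(seq), k + 1).astype(int)
    pieces = [seq[bounds[i]: bounds[i + 1]] for i in range(k)]
    entries = []
    insert_parts = []
    offset = position
    for i, piece in enumerate(pieces):
        if i > 0:
            spacer = random_dna(rng, int(rng.integers(50, 150)))
            insert_parts.append(spacer)
            offset += len(spacer)
        insert_parts.append(piece)
        entries.append({"mtdna_id": mtdna.id, "start": offset,
                        "end": offset + len(piece),
                        "source_span": [int(bounds[i]), int(bounds[i + 1])],
                        "substitution_rate": degradation.substitution_rate,
                        "stop_codons": degradation.stop_codons})
        offset += len(piece)
    insert = "".join(insert_parts)
    new_seq = mtdna.residues[:position] + insert + mtdna.residues[position:]
    return SequenceRecord(id=mtdna.id, residues=new_seq,
                          description=mtdna.description), entries


# ---------------------------------------------------------------------------
# dataset assembly


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Compose hosts, plasmids, captures, losses and decoys with a manifest."""
    rng = np.random.default_rng(config.seed)
    trna_refs = generate_trna_refs(config, np.random.default_rng(config.seed + 10**6))
    panel = [
        SequenceRecord(id="DNA_polymerase_ref", residues=random_protein(rng, config.dnapol_aa),
                       moltype="protein"),
        SequenceRecord(id="RNA_polymerase_ref", residues=random_protein(rng, config.rnapol_aa),
                       moltype="protein"),
    ]
    scenarios = config.plasmids
    leaf_prots, true_tree = ({}, None)
    if scenarios:
        # plasmid contig ids, per-host counters
        counters: dict[int, int] = {}
        plasmid_ids = []
        for sc in scenarios:
            j = counters.get(sc.host, 0)
            counters[sc.host] = j + 1
            plasmid_ids.append(f"host{sc.host}_plasmid{j}")
        leaf_prots, true_tree = _evolve_polymerases(config, rng, panel, len(scenarios))
        true_tree = _relabel_tree(true_tree, plasmid_ids)
    else:
        plasmid_ids = []

    capturable = sorted({sc.capture.trna_name for sc in scenarios if sc.capture})
    hosts_with_insert = {sc.host for sc in scenarios if sc.inserted}

    # 1. mtDNAs (all hosts, all tRNAs present; losses applied later)
    mtdnas: list[SequenceRecord] = []
    annos: list[pd.DataFrame] = []
    safe_points: dict[int, int] = {}
    for h in range(config.n_hosts):
        rec, anno, safe = generate_mtdna(
            config, rng, f"host{h}", trna_refs=trna_refs, capturable=capturable,
            reserve_insertion_site=(h in hosts_with_insert))
        mtdnas.append(rec)
        annos.append(anno)
        if safe is not None:
            safe_points[h] = safe

    trna_by_name = {t.name: t for t in trna_refs}
    manifest_plasmids = []
    manifest_fragments = []
    host_contig_extra: dict[int, list[SequenceRecord]] = {h: [] for h in range(config.n_hosts)}
    host_plasmid_contigs: dict[int, list[str]] = {h: [] for h in range(config.n_hosts)}

    # 2. plasmids
    for idx, sc in enumerate(scenarios):
        pid = plasmid_ids[idx]
        dna_aa, rna_aa = leaf_prots[idx]
        dnapol_nt = back_translate(dna_aa, rng)
        rnapol_nt = back_translate(rna_aa, rng)

        capture_block = None
        capture_entry = None
        if sc.capture:
            cap = sc.capture
            donor = cap.donor_host if cap.donor_host is not None else sc.host
            d_anno = annos[donor]
            row = d_anno[(d_anno.feature == "tRNA") & (d_anno.label == cap.trna_name)].iloc[0]
            d_seq = mtdnas[donor].residues
            lo = int(row.start) - cap.flank_nt
            hi = int(row.end) + cap.flank_nt
            up = mutate_dna(d_seq[lo:int(row.start)], cap.flank_divergence, rng)
            core = mutate_dna(d_seq[int(row.start):int(row.end)], cap.trna_divergence, rng)
            down = mutate_dna(d_seq[int(row.end):hi], cap.flank_divergence, rng)
            capture_block = up + core + down
            capture_entry = {
                "trna": cap.trna_name, "donor_host": donor,
                "flank_nt": cap.flank_nt, "trna_divergence": cap.trna_divergence,
                "flank_divergence": cap.flank_divergence, "loss": cap.loss,
            }

        hom_blocks = []
        for blen in sc.homology_blocks:
            src = mtdnas[sc.host].residues
            anno = annos[sc.host]
            trna_spans = [(int(r.start), int(r.end))
                          for _, r in anno[anno.feature == "tRNA"].iterrows()]
            # tRNA genes are conserved across hosts; keep planted blocks
            # host-specific by sampling from tRNA-free sequence
            for _ in range(200):
                start = int(rng.integers(0, len(src) - blen))
                if not any(start < e and s < start + blen for s, e in trna_spans):
                    break
            hom_blocks.append(src[start:start + blen])

        build = _build_plasmid_sequence(config, rng, dnapol_nt, rnapol_nt,
                                        sc.structure, capture_block, hom_blocks)
        if capture_entry is not None:
            cb = build.capture
            flank = sc.capture.flank_nt
            capture_entry.update({
                "plasmid_start": cb["start"] + flank,
                "plasmid_end": cb["end"] - flank,
                "region_start": cb["start"], "region_end": cb["end"],
            })

        entry = {
            "contig_id": pid, "host": sc.host, "structure": sc.structure,
            "autonomy": "inserted" if sc.inserted else "autonomous",
            "length": len(build.seq),
            "tir": {"left_start": build.tir[0], "left_end": build.tir[1],
                    "right_start": build.tir[2], "right_end": build.tir[3],
                    "length": config.tir_length},
            "orfs": [list(o) for o in build.orfs],
            "capture": capture_entry,
            "insertion": None,
            "homology_blocks": build.homology_blocks,
            "split": sc.split,
        }

        if sc.inserted:
            flank = config.insertion_flank_nt
            p = safe_points[sc.host]
            seq = build.seq
            if sc.degradation:
                seq = mutate_dna(seq, sc.degradation.substitution_rate, rng)
                if sc.degradation.stop_codons:
                    seq = force_orf_stops(seq, build.orfs,
                                          sc.degradation.stop_codons, rng)
                else:
                    # near-intact insertion: frames and boundaries survive
                    seq = repair_orf_stops(seq, build.orfs, rng)
                    seq = restore_orf_bounds(seq, build.orfs)
            contig_seq = (mtdnas[sc.host].residues[p - flank: p] + seq
                          + mtdnas[sc.host].residues[p: p + flank])
            entry["insertion"] = {
                "mtdna_position": p, "flank_nt": flank,
                "degradation": dataclasses.asdict(sc.degradation) if sc.degradation else None,
            }
            entry["tir"] = {k: v + flank for k, v in entry["tir"].items()
                            if k != "length"} | {"length": config.tir_length}
            entry["orfs"] = [[s + flank, e + flank, st] for s, e, st in build.orfs]
            if capture_entry:
                for k in ("plasmid_start", "plasmid_end", "region_start", "region_end"):
                    capture_entry[k] += flank
            contig = SequenceRecord(id=pid, residues=contig_seq,
                                    description="inserted plasmid with mtDNA flanks")
            host_contig_extra[sc.host].append(contig)
            host_plasmid_contigs[sc.host].append(pid)
        elif sc.split:
            mid = len(build.seq) // 2
            a = SequenceRecord(id=pid + "_frag1", residues=build.seq[:mid])
            b = SequenceRecord(id=pid + "_frag2", residues=build.seq[mid:])
            host_contig_extra[sc.host].extend([a, b])
            host_plasmid_contigs[sc.host].extend([a.id, b.id])
            entry["fragment_ids"] = [a.id, b.id]
            entry["full_sequence"] = build.seq
            manifest_fragments.append({"plasmid_id": pid,
                                       "contig_ids": [a.id, b.id]})
        else:
            contig = SequenceRecord(id=pid, residues=build.seq,
                                    description=f"autonomous {sc.structure} plasmid")
            host_contig_extra[sc.host].append(contig)
            host_plasmid_contigs[sc.host].append(pid)
        manifest_plasmids.append(entry)

    # 3. tRNA losses
    losses: dict[int, list[str]] = {}
    for sc in scenarios:
        if sc.capture and sc.capture.loss:
            h = sc.host
            mtdnas[h], annos[h], span = delete_trna_locus(
                mtdnas[h], annos[h], sc.capture.trna_name)
            losses.setdefault(h, []).append(sc.capture.trna_name)

    # 4. decoys and final assemblies
    hosts: list[HostAssembly] = []
    manifest_hosts = []
    lo, hi = config.plasmid_size_range
    for h in range(config.n_hosts):
        contigs = [mtdnas[h]] + host_contig_extra[h]
        n_in = round(config.n_decoys * config.decoy_inwindow_fraction)
        for d in range(config.n_decoys):
            if d < n_in:
                n = int(rng.integers(lo, hi + 1))
            else:
                n = int(rng.integers(600, 4800))
            contigs.append(SequenceRecord(id=f"host{h}_decoy{d}",
                                          residues=random_dna(rng, n)))
        hosts.append(HostAssembly(
            host_id=f"host{h}", contigs=contigs, mtdna=mtdnas[h],
            annotations=annos[h], plasmid_ids=host_plasmid_contigs[h]))
        manifest_hosts.append({
            "host_id": f"host{h}", "mtdna_id": mtdnas[h].id,
            "contig_ids": [c.id for c in contigs],
            "plasmid_contig_ids": host_plasmid_contigs[h],
            "losses": losses.get(h, []),
        })

    manifest = {
        "seed": config.seed,
        "n_hosts": config.n_hosts,
        "true_tree": true_tree,
        "plasmids": manifest_plasmids,
        "fragments": manifest_fragments,
        "hosts": manifest_hosts,
        "family_weights": dict(config.family_weights),
        "trna_refs": [{"isotype": t.isotype, "anticodon": t.anticodon,
                       "residues": t.residues,
                       "anticodon_offset": t.anticodon_offset}
                      for t in trna_refs],
    }
    return Dataset(config=config, hosts=hosts, trna_refs=trna_refs,
                   panel=panel, manifest=manifest)


def _relabel_tree(newick: str, plasmid_ids: Sequence[str]) -> str:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    for taxon in tree.taxon_namespace:
        taxon.label = plasmid_ids[int(taxon.label)]
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    """Write per-host contig FASTAs, references and the manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for host in dataset.hosts:
        write_fasta(host.contigs, outdir / f"{host.host_id}.contigs.fasta")
        write_annotations(host.annotations, outdir / f"{host.host_id}.annotations.tsv")
    write_fasta([SequenceRecord(id=f"{t.name}", residues=t.residues)
                 for t in dataset.trna_refs], outdir / "trna_refs.fasta")
    write_fasta(dataset.panel, outdir / "polymerase_panel.faa")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dataset.manifest, fh, indent=1, sort_keys=True, default=int)
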