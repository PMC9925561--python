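"""End-to-end orchestration: detect → homology → capture/loss → events → codons.

``run_analysis`` drives the full analysis over in-memory inputs and
returns a :class:`ReportBundle` of tables; ``run_pipeline`` wraps it with
file loading from a dataset directory (as written by
:func:`mitoplasmid.simulate.write_dataset`, or assembled by hand in the
same layout), and ``write_report`` emits TSV/JSON outputs with every
threshold logged. All stages are deterministic given the inputs, so a
rerun reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import ScoringScheme
from .codons import (average_family_fractions, count_codons, load_family_map,
                     rank_families)
from .events import TransferEventSet, count_transfer_events
from .homology import homology_matrix
from .phylo import (Alignment, concat_alignments, midpoint_root,
                    neighbor_joining, protein_distance, read_newick)
from .plasmids import FragmentRecord, PlasmidCall, screen_assembly
from .seqs import (SequenceRecord, extract_feature, read_annotations,
                   read_fasta)
from .trna import TrnaGene, find_trna_captures

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every tunable of the analysis, at the published defaults."""

    size_range: tuple[int, int] = (5000, 15000)  # plasmid contig window, nt
    min_orf_nt: int = 1000
    min_segment_len: int = 50  # kept only if strictly longer
    max_evalue: float = 1e-3  # kept only if strictly smaller
    capture_min_identity: float = 0.9
    capture_min_cov: float = 0.9
    loss_min_identity: float = 0.7
    loss_min_cov: float = 0.5
    collapse_support: float = 95.0
    flank_profile_nt: int = 300
    strict_polymerase: bool = False
    min_polymerase_score: float = 100.0


@dataclass
class PipelineConfig:
    dataset_dir: str | Path | None = None
    tree_path: str | Path | None = None  # externally inferred newick, optional
    thresholds: Thresholds = field(default_factory=Thresholds)
    output_dir: str | Path = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        if "size_range" in raw:
            thr.size_range = tuple(raw.pop("size_range"))
        return cls(thresholds=thr, **raw)


@dataclass
class HostInput:
    host_id: str
    contigs: list[SequenceRecord]
    mtdna_id: str | None = None
    annotations: pd.DataFrame | None = None


@dataclass
class ReportBundle:
    calls: pd.DataFrame
    fragments: pd.DataFrame
    homology: pd.DataFrame
    captures: pd.DataFrame
    events: TransferEventSet | None
    tree_newick: str | None
    codon_families: pd.DataFrame
    thresholds: Thresholds
    plasmid_calls: list[PlasmidCall] = field(default_factory=list)


def load_dataset_dir(path: str | Path) -> tuple[list[HostInput], list[TrnaGene],
                                                list[SequenceRecord]]:
    """Load ``host*.contigs.fasta`` + annotations, tRNA refs and panel."""
    path = Path(path)
    hosts = []
    for fa in sorted(path.glob("*.contigs.fasta"),
                     key=lambda p: _host_sort_key(p.stem.split(".")[0])):
        host_id = fa.stem.split(".")[0]
        contigs = read_fasta(fa)
        anno_path = path / f"{host_id}.annotations.tsv"
        anno = read_annotations(anno_path) if anno_path.exists() else None
        mtdna_id = None
        if anno is not None and len(anno):
            mtdna_id = str(anno.seq_id.iloc[0])
        hosts.append(HostInput(host_id=host_id, contigs=contigs,
                               mtdna_id=mtdna_id, annotations=anno))
    if not hosts:
        raise FileNotFoundError(f"{path}: no *.contigs.fasta host files")
    trna_refs = []
    trna_fa = path / "trna_refs.fasta"
    if trna_fa.exists():
        for rec in read_fasta(trna_fa):
            isotype, _, anticodon = rec.id.partition("-")
            trna_refs.append(TrnaGene(isotype=isotype, anticodon=anticodon,
                                      residues=rec.residues, source_id=rec.id))
    panel_fa = path / "polymerase_panel.faa"
    panel = read_fasta(panel_fa, moltype="protein") if panel_fa.exists() else []
    return hosts, trna_refs, panel


def _host_sort_key(stem: str):
    import re

    m = re.match(r"(\D+)(\d+)$", stem)
    return (m.group(1), int(m.group(2))) if m else (stem, -1)


# ---------------------------------------------------------------------------


def run_analysis(hosts: Sequence[HostInput], trna_refs: Sequence[TrnaGene],
                 panel: Sequence[SequenceRecord] = (),
                 thresholds: Thresholds | None = None,
                 tree_newick: str | None = None,
                 known_plasmids: Sequence[SequenceRecord] = (),
                 scheme: ScoringScheme | None = None) -> ReportBundle:
    """The full analysis over in-memory hosts; see the module docstring."""
    thr = thresholds or Thresholds()
    scheme = (scheme or ScoringScheme()).calibrated()
    log.info("thresholds: %s", dataclasses.asdict(thr))

    mtdnas = []
    for h in hosts:
        if h.mtdna_id:
            rec = next((c for c in h.contigs if c.id == h.mtdna_id), None)
            if rec is not None:
                mtdnas.append(rec)

    # 1. plasmid detection per host
    all_calls: list[tuple[HostInput, PlasmidCall]] = []
    all_frags: list[tuple[HostInput, FragmentRecord]] = []
    contig_by_id: dict[str, SequenceRecord] = {}
    for h in hosts:
        contig_by_id.update({c.id: c for c in h.contigs})
        calls, frags = screen_assembly(
            h.contigs, panel=panel, mtdna_set=mtdnas,
            known_plasmids=known_plasmids, size_range=thr.size_range,
            min_orf_nt=thr.min_orf_nt, strict=thr.strict_polymerase,
            min_polymerase_score=thr.min_polymerase_score, scheme=scheme)
        all_calls.extend((h, c) for c in calls)
        all_frags.extend((h, f) for f in frags)

    call_rows = []
    for h, c in all_calls:
        row = {"contig_id": c.contig_id, "host_id": h.host_id,
               "structure": c.structure, "autonomy": c.autonomy,
               "arrangement": c.arrangement,
               "length": len(contig_by_id[c.contig_id].residues)}
        if c.tir:
            row.update(tir_length=c.tir.length, tir_identity=round(c.tir.identity, 4))
        if c.orf_pair:
            row.update(orf1=f"{c.orf_pair[0].start}-{c.orf_pair[0].end}({c.orf_pair[0].strand})",
                       orf2=f"{c.orf_pair[1].start}-{c.orf_pair[1].end}({c.orf_pair[1].strand})")
        call_rows.append(row)
    calls_df = pd.DataFrame(call_rows)
    frag_rows = [{"contig_id": f.contig_id, "matches_plasmid": f.plasmid_id,
                  "host_id": h.host_id, "cumulative_nt": f.cumulative_nt}
                 for h, f in all_frags]
    frags_df = pd.DataFrame(frag_rows, columns=["contig_id", "matches_plasmid",
                                                "host_id", "cumulative_nt"])

    # 2. plasmid × mtDNA cumulative-homology matrix
    plasmid_recs = [contig_by_id[c.contig_id] for _, c in all_calls]
    hom = (homology_matrix(plasmid_recs, mtdnas, scheme,
                           min_len=thr.min_segment_len, max_e=thr.max_evalue,
                           method="seed")
           if plasmid_recs and mtdnas else pd.DataFrame())

    # 3. captures, loss, dependency (red/blue coding)
    cap_rows = []
    presence: dict[str, dict[str, bool]] = {}
    for h, c in all_calls:
        plasmid = contig_by_id[c.contig_id]
        plasmid_ids = [cc.contig_id for hh, cc in all_calls if hh is h]
        caps = find_trna_captures(
            plasmid, trna_refs, min_identity=thr.capture_min_identity,
            min_cov=thr.capture_min_cov, host_assembly=h.contigs,
            host_plasmid_ids=plasmid_ids, scheme=scheme) if trna_refs else []
        for cap in caps:
            cap_rows.append({
                "plasmid_id": c.contig_id, "host_id": h.host_id,
                "trna": cap.trna.name, "start": cap.q_start, "end": cap.q_end,
                "strand": cap.strand, "identity": round(cap.identity, 4),
                "mutations": cap.mutation_count, "dependency": cap.dependency,
                "color": {"adopted_lost": "red", "retained": "blue"}.get(
                    cap.dependency, "none")})
            presence.setdefault(cap.trna.name, {})[c.contig_id] = True
    captures_df = pd.DataFrame(
        cap_rows, columns=["plasmid_id", "host_id", "trna", "start", "end",
                           "strand", "identity", "mutations", "dependency", "color"])

    # 4. independent transfer events on the tree
    events = None
    used_tree = None
    if presence:
        tree = _resolve_tree(tree_newick, all_calls, contig_by_id, thr)
        if tree is not None:
            leaf_ids = [c.contig_id for _, c in all_calls]
            full_presence = {
                t: {pid: bool(pres.get(pid, False)) for pid in leaf_ids}
                for t, pres in presence.items()}
            events = count_transfer_events(tree, full_presence)
            used_tree = tree.as_string(schema="newick").strip()

    # 5. codon-family usage and captured-family ranks
    fam_map = load_family_map()
    tables = []
    for h in hosts:
        if h.annotations is None or h.mtdna_id is None:
            continue
        mt = next((c for c in h.contigs if c.id == h.mtdna_id), None)
        if mt is None:
            continue
        a = h.annotations
        cds = [SequenceRecord(id=str(r.label),
                              residues=extract_feature(mt.residues, int(r.start),
                                                       int(r.end), str(r.strand)))
               for _, r in a[a.feature == "CDS"].iterrows()]
        if cds:
            tables.append(count_codons(cds, genome_id=h.host_id))
    if tables:
        avg = average_family_fractions(tables, fam_map)
        captured = sorted(presence)
        codon_df = rank_families(avg, [f for f in captured
                                       if f in set(avg.index)])
    else:
        codon_df = pd.DataFrame(columns=["family", "fraction", "rank", "captured"])

    return ReportBundle(calls=calls_df, fragments=frags_df, homology=hom,
                        captures=captures_df, events=events,
                        tree_newick=used_tree, codon_families=codon_df,
                        thresholds=thr,
                        plasmid_calls=[c for _, c in all_calls])


def _resolve_tree(tree_newick, all_calls, contig_by_id, thr):
    from .phylo import collapse_low_support, read_newick_string

    leaf_ids = [c.contig_id for _, c in all_calls]
    if tree_newick:
        tree = read_newick_string(tree_newick)
        tree = collapse_low_support(tree, threshold=thr.collapse_support)
        labels = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon}
        missing = set(leaf_ids) - labels
        if missing:
            raise ValueError(f"supplied tree lacks plasmid leaves: {sorted(missing)}")
        return tree
    if len(leaf_ids) < 3:
        log.warning("fewer than 3 plasmids; transfer events counted per plasmid")
        return None
    # NJ stand-in over concatenated polymerase translations
    rows1, rows2 = [], []
    for _, c in all_calls:
        orfs = sorted(c.orf_pair, key=lambda o: -o.nt_length)
        rows1.append(orfs[0].protein)
        rows2.append(orfs[1].protein)
    if len({len(r) for r in rows1}) > 1 or len({len(r) for r in rows2}) > 1:
        raise ValueError(
            "polymerase ORFs differ in length across plasmids; supply an "
            "externally aligned tree (tree_newick) for event counting")
    aln = concat_alignments(Alignment(list(leaf_ids), rows1),
                            Alignment(list(leaf_ids), rows2))
    tree = neighbor_joining(protein_distance(aln), leaf_ids)
    return midpoint_root(tree)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Load a dataset directory, run the analysis, return the bundle."""
    if config.dataset_dir is None:
        raise ValueError("PipelineConfig.dataset_dir is required")
    hosts, trna_refs, panel = load_dataset_dir(config.dataset_dir)
    tree_newick = None
    if config.tree_path:
        tree_newick = Path(config.tree_path).read_text()
    return run_analysis(hosts, trna_refs, panel, thresholds=config.thresholds,
                        tree_newick=tree_newick)


def write_report(bundle: ReportBundle, outdir: str | Path) -> dict[str, Path]:
    """TSV tables plus a JSON sidecar; stable column order; thresholds logged."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("plasmid_calls", bundle.calls),
                     ("fragments", bundle.fragments),
                     ("captures", bundle.captures),
                     ("codon_families", bundle.codon_families)]:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = outdir / "homology_matrix.tsv"
    bundle.homology.to_csv(p, sep="\t", index_label="plasmid_id")
    paths["homology_matrix"] = p
    sidecar = {
        "thresholds": dataclasses.asdict(bundle.thresholds),
        "tree_newick": bundle.tree_newick,
        "transfer_events": None if bundle.events is None else {
            t: {"gains": e.gain_count, "losses": e.loss_count,
                "origins": e.origins}
            for t, e in bundle.events.per_trna.items()},
    }
    p = outdir / "report.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True, default=int)
    paths["report"] = p
    return paths
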