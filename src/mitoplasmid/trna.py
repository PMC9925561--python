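"""Detection of tRNA genes captured by plasmids and of mitochondrial loss.

A capture is a near-complete copy of a reference mitochondrial tRNA gene
on a plasmid (identity >= 0.9 over >= 90 % of the gene). The host is
scored for retention or loss of its own mitochondrial copy by searching
the whole assembly (plasmid contigs excluded) with a looser threshold
(>= 70 % identity over >= 50 % of the gene) so that a "lost" call is
conservative. A capture whose host copy is lost makes the host dependent
on the plasmid for that anticodon ("adopted_lost", the red class of the
homology report); otherwise the capture is "retained" (blue).

The flank profile measures how far homology between the captured locus
and each comparison mtDNA extends beyond the tRNA gene boundaries —
mtDNA-derived flanks identify the donor lineage of the capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import HomologySegment, ScoringScheme, filter_segments, local_align
from .seqs import SequenceRecord

log = logging.getLogger(__name__)


@dataclass
class TrnaGene:
    """A reference mitochondrial tRNA gene with isotype and anticodon."""

    isotype: str
    anticodon: str
    residues: str
    source_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    anticodon_offset: int | None = None

    @property
    def name(self) -> str:
        return f"{self.isotype}-{self.anticodon}"

    def __post_init__(self) -> None:
        if self.anticodon_offset is not None:
            at = self.residues[self.anticodon_offset: self.anticodon_offset + 3]
            if at != self.anticodon:
                raise ValueError(
                    f"{self.name}: anticodon {self.anticodon!r} not found at "
                    f"offset {self.anticodon_offset} (saw {at!r})")


@dataclass
class TrnaCapture:
    plasmid_id: str
    trna: TrnaGene
    q_start: int  # location on the plasmid, forward strand
    q_end: int
    strand: str
    identity: float
    mutation_count: int
    dependency: str = "unknown"  # adopted_lost | retained | unknown


@dataclass
class FlankProfile:
    plasmid_id: str
    trna_name: str
    per_species: dict[str, dict[str, float]] = field(default_factory=dict)
    truncated: bool = False


def find_trna_captures(plasmid: SequenceRecord, trna_refs: Sequence[TrnaGene],
                       min_identity: float = 0.9, min_cov: float = 0.9,
                       host_assembly: Sequence[SequenceRecord] | None = None,
                       host_plasmid_ids: Iterable[str] = (),
                       scheme: ScoringScheme | None = None) -> list[TrnaCapture]:
    """Locate reference tRNA genes on a plasmid (both strands).

    ``mutation_count`` is mismatches plus indel columns on the aligned
    span. When ``host_assembly`` is given, each capture's dependency is
    filled via :func:`detect_mito_loss` with the host's plasmid contigs
    excluded.
    """
    if not trna_refs:
        raise ValueError("trna_refs must be non-empty")
    scheme = (scheme or ScoringScheme()).calibrated()
    captures: list[TrnaCapture] = []
    for ref in trna_refs:
        query = SequenceRecord(id=ref.name, residues=ref.residues)
        segs = local_align(query, plasmid, scheme, method="auto", min_raw_score=20)
        best = None
        for s in segs:
            cov = (s.q_end - s.q_start) / len(ref.residues)
            if cov >= min_cov and s.identity >= min_identity:
                if best is None or s.score > best.score:
                    best = s
        if best is None:
            continue
        captures.append(TrnaCapture(
            plasmid_id=plasmid.id, trna=ref,
            q_start=best.s_start, q_end=best.s_end, strand=best.strand,
            identity=best.identity,
            mutation_count=best.mismatches + _n_gap_cols(best)))
    if host_assembly is not None:
        for cap in captures:
            status = detect_mito_loss(host_assembly, cap.trna,
                                      exclude_ids=set(host_plasmid_ids) | {plasmid.id},
                                      scheme=scheme)
            cap.dependency = "adopted_lost" if status == "lost" else "retained"
    return captures


def _n_matches(seg: HomologySegment) -> int:
    return round(seg.identity * seg.length)


def _n_gap_cols(seg: HomologySegment) -> int:
    return seg.length - seg.mismatches - _n_matches(seg)


def detect_mito_loss(assembly: Sequence[SequenceRecord], trna: TrnaGene,
                     exclude_ids: Iterable[str] = (),
                     min_identity: float = 0.7, min_cov: float = 0.5,
                     scheme: ScoringScheme | None = None,
                     min_len: int = 50, max_e: float = 1e-3) -> str:
    """Search an assembly for a mitochondrial copy of ``trna``.

    Returns ``"present"`` if any non-excluded contig carries a segment
    passing the analysis-wide significance filter (> ``min_len`` bp and
    E < ``max_e``) that covers >= ``min_cov`` of the gene at >=
    ``min_identity``, else ``"lost"``. For a typical ~72 nt tRNA the
    > 50 bp rule is the binding constraint and suppresses short gapped
    chance hits in unrelated contigs.
    """
    if not assembly:
        raise ValueError("assembly must be non-empty")
    excluded = set(exclude_ids)
    scheme = (scheme or ScoringScheme()).calibrated()
    query = SequenceRecord(id=trna.name, residues=trna.residues)
    searched_any = False
    for contig in assembly:
        if contig.id in excluded:
            continue
        searched_any = True
        segs = filter_segments(
            local_align(query, contig, scheme, method="auto", min_raw_score=20),
            min_len=min_len, max_e=max_e)
        for s in segs:
            cov = (s.q_end - s.q_start) / len(trna.residues)
            if cov >= min_cov and s.identity >= min_identity:
                return "present"
    if not searched_any:
        log.warning("detect_mito_loss(%s): every contig excluded; vacuously lost",
                    trna.name)
    return "lost"


def classify_dependency(capture: TrnaCapture,
                        host_assembly: Sequence[SequenceRecord] | None,
                        plasmid_ids: Iterable[str] = (),
                        scheme: ScoringScheme | None = None) -> str:
    """adopted_lost iff the host assembly lacks a mitochondrial copy.

    With no host assembly the status is ``"unknown"`` and the capture is
    excluded from red/blue tallies.
    """
    if host_assembly is None:
        capture.dependency = "unknown"
        return "unknown"
    status = detect_mito_loss(host_assembly, capture.trna,
                              exclude_ids=set(plasmid_ids) | {capture.plasmid_id},
                              scheme=scheme)
    capture.dependency = "adopted_lost" if status == "lost" else "retained"
    return capture.dependency


def flank_homology_profile(plasmid: SequenceRecord, capture: TrnaCapture,
                           mtdna_set: Sequence[SequenceRecord],
                           flank_nt: int = 300,
                           scheme: ScoringScheme | None = None,
                           min_len: int = 50, max_e: float = 1e-3) -> FlankProfile:
    """How far does homology extend beyond the captured tRNA's boundaries?

    The captured gene ± ``flank_nt`` is excised from the plasmid and
    aligned to each comparison mtDNA; for segments overlapping the tRNA
    interval, the report gives the upstream/downstream extents beyond the
    gene boundaries plus identities over the tRNA and the flanks.
    """
    scheme = (scheme or ScoringScheme()).calibrated()
    lo = max(0, capture.q_start - flank_nt)
    hi = min(len(plasmid.residues), capture.q_end + flank_nt)
    truncated = (capture.q_start - flank_nt < 0
                 or capture.q_end + flank_nt > len(plasmid.residues))
    region = SequenceRecord(id=f"{plasmid.id}:capture_region",
                            residues=plasmid.residues[lo:hi])
    t0, t1 = capture.q_start - lo, capture.q_end - lo  # tRNA interval in region coords
    profile = FlankProfile(plasmid_id=plasmid.id, trna_name=capture.trna.name,
                           truncated=truncated)
    for mt in mtdna_set:
        segs = filter_segments(local_align(region, mt, scheme, method="auto"),
                               min_len=min_len, max_e=max_e)
        over = [s for s in segs if s.q_start < t1 and t0 < s.q_end]
        if not over:
            profile.per_species[mt.id] = {
                "upstream_extent": 0.0, "downstream_extent": 0.0,
                "trna_identity": 0.0, "flank_identity": 0.0}
            continue
        up = max(0, t0 - min(s.q_start for s in over))
        down = max(0, max(s.q_end for s in over) - t1)
        trna_segs = [s for s in over if min(s.q_end, t1) - max(s.q_start, t0)
                     >= 0.5 * (t1 - t0)]
        trna_ident = max((s.identity for s in trna_segs), default=0.0)
        flank_ident = _weighted_flank_identity(over, t0, t1)
        profile.per_species[mt.id] = {
            "upstream_extent": float(up), "downstream_extent": float(down),
            "trna_identity": float(trna_ident), "flank_identity": float(flank_ident)}
    return profile


def _weighted_flank_identity(segs: Sequence[HomologySegment], t0: int, t1: int) -> float:
    num = den = 0.0
    for s in segs:
        flank_cols = (s.q_end - s.q_start) - max(
            0, min(s.q_end, t1) - max(s.q_start, t0))
        num += s.identity * flank_cols
        den += flank_cols
    return num / den if den else 0.0
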