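"""Structural detection of linear mitochondrial plasmids in assemblies.

Invertron plasmids are 5–15 kb elements carrying two large (≥ 1 kb)
open-reading frames — a DNA and an RNA polymerase — in inverted
orientation, capped by terminal inverted repeats (TIRs). A minority of
linear plasmids carry both polymerases on the same strand but are still
TIR-capped. Autonomous plasmid contigs end at (or near) their TIRs;
recent mitochondrial insertions carry extended flanks beyond the TIRs
that share homology with mtDNA.

The screen proceeds contig by contig: size window → ORF pair → TIR search
→ optional polymerase verification against a reference protein panel →
autonomy judgement from the flanks. A second, homology-based pass flags
contigs of any size that match a known plasmid's polymerase region
("split" fragments that escaped contiguous assembly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .align import HomologySegment, ScoringScheme, filter_segments, local_align
from .seqs import (GeneticCode, MOLD_MITO, OpenReadingFrame, SequenceRecord,
                   revcomp)

log = logging.getLogger(__name__)


@dataclass
class TerminalInvertedRepeat:
    """A pairing between the two contig ends in inverted orientation."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    length: int
    identity: float

    def __post_init__(self) -> None:
        if not (self.left_start < self.left_end <= self.right_start < self.right_end):
            raise ValueError("left TIR interval must precede right TIR interval")


@dataclass
class PolymeraseHit:
    orf_index: int
    panel_id: str
    score: float


@dataclass
class PlasmidCall:
    contig_id: str
    structure: str  # invertron | non_invertron_linear | none
    autonomy: str = "ambiguous"  # autonomous | inserted | ambiguous
    orf_pair: tuple[OpenReadingFrame, OpenReadingFrame] | None = None
    tir: TerminalInvertedRepeat | None = None
    arrangement: str | None = None  # divergent | convergent (invertron only)
    polymerase_evidence: list[PolymeraseHit] = field(default_factory=list)
    flank_evidence: list[HomologySegment] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class FragmentRecord:
    """A contig matching a known plasmid without qualifying as a full call."""

    contig_id: str
    plasmid_id: str
    segments: list[HomologySegment]
    cumulative_nt: int


# ---------------------------------------------------------------------------
# TIR search: seed-and-extend between the left end and the reverse
# complement of the right end.


def find_tirs(contig: SequenceRecord, window_nt: int = 2000, min_len: int = 20,
              min_identity: float = 0.8, seed_word: int = 12) -> TerminalInvertedRepeat | None:
    """Best inverted pairing between the outermost windows of each end.

    Returns the highest-scoring repeat of length >= ``min_len`` whose
    identity is >= ``min_identity``, or ``None``. Ties prefer the longer,
    then the more leftward repeat.
    """
    L = len(contig.residues)
    if window_nt > L // 2:
        window_nt = L // 2
    if window_nt < min_len:
        return None
    left = contig.residues[:window_nt]
    right = contig.residues[L - window_nt:]
    q = SequenceRecord(id="left", residues=left)
    s = SequenceRecord(id="right_rc", residues=revcomp(right))
    scheme = ScoringScheme(word_size=seed_word).calibrated()
    segs = local_align(q, s, scheme, method="seed", min_raw_score=min_len,
                       both_strands=False)
    best = None
    best_key = None
    for seg in segs:
        if seg.length < min_len or seg.identity < min_identity:
            continue
        key = (-seg.score, -seg.length, seg.q_start)
        if best_key is None or key < best_key:
            best, best_key = seg, key
    if best is None:
        return None
    # project the right_rc interval back to forward-strand coordinates
    right_start = L - (best.s_end)
    right_end = L - best.s_start
    return TerminalInvertedRepeat(
        left_start=best.q_start, left_end=best.q_end,
        right_start=right_start, right_end=right_end,
        length=best.length, identity=best.identity)


# ---------------------------------------------------------------------------
# Structural classification


def classify_structure(contig: SequenceRecord, code: GeneticCode = MOLD_MITO,
                       size_range: tuple[int, int] = (5000, 15000),
                       min_orf_nt: int = 1000,
                       tir_kwargs: dict | None = None) -> PlasmidCall:
    """Classify one contig as invertron / non-invertron linear / none.

    The size window and the two-large-ORF criterion come first; the two
    longest qualifying non-overlapping ORFs decide the class: opposite
    strands → invertron; same strand with a TIR → non-invertron linear.
    """
    L = len(contig.residues)
    if not (size_range[0] <= L <= size_range[1]):
        return PlasmidCall(contig_id=contig.id, structure="none",
                           notes=[f"length {L} outside {size_range}"])
    from .seqs import find_orfs

    orfs = find_orfs(contig, code, min_nt=min_orf_nt)
    if len(orfs) < 2:
        return PlasmidCall(contig_id=contig.id, structure="none",
                           notes=[f"{len(orfs)} ORFs >= {min_orf_nt} nt"])
    o1 = orfs[0]
    o2 = next((o for o in orfs[1:] if not o.overlaps(o1)), None)
    if o2 is None:
        return PlasmidCall(contig_id=contig.id, structure="none",
                           notes=["no non-overlapping second ORF"])
    pair = tuple(sorted((o1, o2), key=lambda o: o.start))
    tir = find_tirs(contig, **(tir_kwargs or {}))
    if pair[0].strand != pair[1].strand:
        arrangement = "divergent" if pair[0].strand == "-" else "convergent"
        return PlasmidCall(contig_id=contig.id, structure="invertron",
                           orf_pair=pair, tir=tir, arrangement=arrangement)
    if tir is not None:
        return PlasmidCall(contig_id=contig.id, structure="non_invertron_linear",
                           orf_pair=pair, tir=tir)
    return PlasmidCall(contig_id=contig.id, structure="none", orf_pair=pair,
                       notes=["same-strand ORF pair without TIRs"])


# ---------------------------------------------------------------------------
# Polymerase verification against a reference protein panel (BLOSUM62,
# affine 11/1 — the classical BLASTp costs).


def _protein_aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def verify_polymerases(call: PlasmidCall, panel: Sequence[SequenceRecord],
                       min_score: float = 100.0, strict: bool = False) -> PlasmidCall:
    """Annotate each ORF with its best panel hit; optionally demote the call.

    In strict mode the structure is demoted to ``none`` when neither ORF
    reaches ``min_score`` against the panel. In permissive mode (default)
    structural evidence alone suffices and the hits are informational.
    """
    if call.structure == "none":
        raise ValueError("verify_polymerases requires a structural call")
    if strict and not panel:
        raise ValueError("strict polymerase verification requires a non-empty panel")
    aligner = _protein_aligner()
    hits: list[PolymeraseHit] = []
    for idx, orf in enumerate(call.orf_pair or ()):
        best_id, best_score = "", float("-inf")
        for ref in panel:
            score = aligner.score(orf.protein.replace("*", "X"), ref.residues)
            if score > best_score:
                best_id, best_score = ref.id, float(score)
        if panel:
            hits.append(PolymeraseHit(orf_index=idx, panel_id=best_id, score=best_score))
    call.polymerase_evidence = hits
    if strict and hits and all(h.score < min_score for h in hits):
        call.notes.append("demoted: no ORF reached the polymerase panel score floor")
        call.structure = "none"
    return call


# ---------------------------------------------------------------------------
# Autonomy: what lies beyond the TIRs?


def classify_autonomy(call: PlasmidCall, contig: SequenceRecord,
                      mtdna_set: Sequence[SequenceRecord],
                      scheme: ScoringScheme | None = None,
                      flank_min: int = 100, min_len: int = 50,
                      max_e: float = 1e-3) -> PlasmidCall:
    """Judge autonomous vs inserted from the sequence outside the TIRs.

    Flanks shorter than ``flank_min`` on both sides → autonomous. A flank
    with a significant homology segment against any mtDNA → inserted.
    Long flanks matching nothing → ambiguous.
    """
    if call.structure == "none":
        raise ValueError("classify_autonomy requires a structural call")
    scheme = (scheme or ScoringScheme()).calibrated()
    L = len(contig.residues)
    if call.tir is not None:
        left_end, right_start = call.tir.left_start, call.tir.right_end
    elif call.orf_pair is not None:
        left_end = min(o.start for o in call.orf_pair)
        right_start = max(o.end for o in call.orf_pair)
    else:  # pragma: no cover - structural calls always carry an ORF pair
        left_end, right_start = 0, L
    flanks = []
    if left_end >= flank_min:
        flanks.append(("left", contig.residues[:left_end]))
    if L - right_start >= flank_min:
        flanks.append(("right", contig.residues[right_start:]))
    if not flanks:
        call.autonomy = "autonomous"
        return call
    if not mtdna_set:
        log.warning("contig %s: long flanks but no mtDNA set supplied; "
                    "autonomy is ambiguous", call.contig_id)
        call.autonomy = "ambiguous"
        return call
    evidence: list[HomologySegment] = []
    for side, seq in flanks:
        frec = SequenceRecord(id=f"{call.contig_id}:{side}_flank", residues=seq)
        for mt in mtdna_set:
            segs = filter_segments(local_align(frec, mt, scheme, method="auto"),
                                   min_len=min_len, max_e=max_e)
            evidence.extend(segs)
    call.flank_evidence = evidence
    call.autonomy = "inserted" if evidence else "ambiguous"
    return call


# ---------------------------------------------------------------------------
# Assembly-level screen


def screen_assembly(contigs: Sequence[SequenceRecord],
                    code: GeneticCode = MOLD_MITO,
                    panel: Sequence[SequenceRecord] = (),
                    mtdna_set: Sequence[SequenceRecord] = (),
                    known_plasmids: Sequence[SequenceRecord] = (),
                    size_range: tuple[int, int] = (5000, 15000),
                    min_orf_nt: int = 1000, strict: bool = False,
                    min_polymerase_score: float = 100.0,
                    scheme: ScoringScheme | None = None,
                    rescue_min_nt: int = 200,
                    tir_kwargs: dict | None = None,
                    ) -> tuple[list[PlasmidCall], list[FragmentRecord]]:
    """Screen every contig structurally, then rescue split plasmids by homology.

    Full calls come only from the structural pass. The rescue pass reports
    contigs of any size whose nucleotide homology to a known plasmid (or an
    already-accepted call) overlaps that plasmid's polymerase ORFs over at
    least ``rescue_min_nt`` — candidates for plasmids split across contigs.
    Output is sorted by contig id.
    """
    scheme = (scheme or ScoringScheme()).calibrated()
    calls: list[PlasmidCall] = []
    called_ids: set[str] = set()
    by_id = {c.id: c for c in contigs}
    for contig in contigs:
        call = classify_structure(contig, code, size_range, min_orf_nt,
                                  tir_kwargs=tir_kwargs)
        if call.structure == "none":
            continue
        if panel or strict:
            call = verify_polymerases(call, panel, min_polymerase_score, strict)
            if call.structure == "none":
                continue
        call = classify_autonomy(call, contig, mtdna_set, scheme)
        calls.append(call)
        called_ids.add(call.contig_id)

    # references for the rescue pass: supplied known plasmids plus the
    # TIR-to-TIR span of each accepted call (ORF coordinates refreshed)
    refs: list[tuple[SequenceRecord, list[tuple[int, int]]]] = []
    for kp in known_plasmids:
        kp_call = classify_structure(kp, code, (0, 10**9), min_orf_nt,
                                     tir_kwargs=tir_kwargs)
        spans = ([(o.start, o.end) for o in kp_call.orf_pair]
                 if kp_call.orf_pair else [(0, len(kp.residues))])
        refs.append((kp, spans))
    for call in calls:
        contig = by_id[call.contig_id]
        spans = [(o.start, o.end) for o in call.orf_pair]
        refs.append((contig, spans))

    fragments: list[FragmentRecord] = []
    for contig in contigs:
        if contig.id in called_ids:
            continue
        for ref, orf_spans in refs:
            if ref.id == contig.id:
                continue
            segs = filter_segments(
                local_align(contig, ref, scheme, method="seed"),
                min_len=50, max_e=1e-3)
            overlapping = [
                s for s in segs
                if any(min(s.s_end, b) - max(s.s_start, a) > 0 for a, b in orf_spans)
            ]
            total = sum(
                min(s.s_end, b) - max(s.s_start, a)
                for s in overlapping for a, b in orf_spans
                if min(s.s_end, b) - max(s.s_start, a) > 0)
            if total >= rescue_min_nt:
                fragments.append(FragmentRecord(
                    contig_id=contig.id, plasmid_id=ref.id,
                    segments=overlapping, cumulative_nt=total))
                break

    calls.sort(key=lambda c: c.contig_id)
    fragments.sort(key=lambda f: f.contig_id)
    return calls, fragments
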