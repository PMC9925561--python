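"""Plasmid–mtDNA homology summaries.

Implements the significance filter used throughout the analysis (segments
kept only if strictly longer than 50 bp with E-value strictly below 1e-3)
and the cumulative-homology matrix: for each plasmid × mitochondrial
genome, the total number of plasmid positions covered by significant
homologous segments, after merging overlaps.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .align import HomologySegment, ScoringScheme, filter_segments, local_align
from .seqs import SequenceRecord


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and coalesced."""
    ivs = sorted((a, b) for a, b in intervals if b > a)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def reciprocal_segments(a: SequenceRecord, b: SequenceRecord,
                        scheme: ScoringScheme | None = None,
                        method: str = "auto") -> list[HomologySegment]:
    """Union of both query directions, projected onto ``a`` as the query.

    Segments found with ``b`` as query are coordinate-swapped; duplicates
    (segments overlapping an already-kept one on both axes) are merged away.
    """
    fwd = local_align(a, b, scheme, method=method)
    rev = local_align(b, a, scheme, method=method)
    swapped = [
        HomologySegment(
            query_id=a.id, subject_id=b.id,
            q_start=s.s_start, q_end=s.s_end,
            s_start=s.q_start, s_end=s.q_end,
            strand=s.strand, score=s.score, length=s.length,
            identity=s.identity, evalue=s.evalue,
            mismatches=s.mismatches, gap_opens=s.gap_opens)
        for s in rev
    ]
    out = list(fwd)
    for s in swapped:
        dup = any(s.q_start < t.q_end and t.q_start < s.q_end
                  and s.s_start < t.s_end and t.s_start < s.s_end
                  for t in out)
        if not dup:
            out.append(s)
    out.sort(key=lambda s: (-s.score, s.q_start))
    return out


def cumulative_homology(plasmid: SequenceRecord, mtdna: SequenceRecord,
                        scheme: ScoringScheme | None = None,
                        min_len: int = 50, max_e: float = 1e-3,
                        method: str = "auto", reciprocal: bool = True) -> int:
    """Total plasmid nt covered by significant homology to one mtDNA."""
    segs = (reciprocal_segments(plasmid, mtdna, scheme, method=method)
            if reciprocal else local_align(plasmid, mtdna, scheme, method=method))
    segs = filter_segments(segs, min_len=min_len, max_e=max_e)
    merged = merge_intervals((s.q_start, s.q_end) for s in segs)
    return sum(b - a for a, b in merged)


def homology_matrix(plasmids: Sequence[SequenceRecord],
                    mtdnas: Sequence[SequenceRecord],
                    scheme: ScoringScheme | None = None,
                    min_len: int = 50, max_e: float = 1e-3,
                    method: str = "auto") -> pd.DataFrame:
    """Plasmid × mtDNA table of cumulative homologous length (nt).

    Row and column order follow the input order.
    """
    scheme = (scheme or ScoringScheme()).calibrated()
    data = {
        m.id: [cumulative_homology(p, m, scheme, min_len, max_e, method)
               for p in plasmids]
        for m in mtdnas
    }
    return pd.DataFrame(data, index=[p.id for p in plasmids],
                        columns=[m.id for m in mtdnas])
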