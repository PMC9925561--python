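"""Scoring pipeline output against a generator ground-truth manifest."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass
class DetectionScore:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 1.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 1.0


def expected_calls(manifest: Mapping) -> dict[str, tuple[str, str]]:
    """contig_id → (structure, autonomy) for every plasmid emitted whole."""
    out = {}
    for p in manifest["plasmids"]:
        if p.get("split"):
            continue  # expected as fragments, never a full call
        out[p["contig_id"]] = (p["structure"], p["autonomy"])
    return out


def score_detection(calls: pd.DataFrame, manifest: Mapping) -> DetectionScore:
    """A call is correct only if structure AND autonomy match the plant."""
    expected = expected_calls(manifest)
    tp = fp = 0
    seen = set()
    for _, row in calls.iterrows():
        want = expected.get(row.contig_id)
        if want == (row.structure, row.autonomy):
            tp += 1
            seen.add(row.contig_id)
        else:
            fp += 1
    fn = len(set(expected) - seen)
    return DetectionScore(true_positives=tp, false_positives=fp, false_negatives=fn)


def expected_captures(manifest: Mapping) -> dict[str, tuple[str, str]]:
    """plasmid contig_id → (tRNA name, dependency) for planted captures."""
    out = {}
    for p in manifest["plasmids"]:
        cap = p.get("capture")
        if cap is None or p.get("split"):
            continue
        out[p["contig_id"]] = (cap["trna"],
                               "adopted_lost" if cap["loss"] else "retained")
    return out


def score_captures(captures: pd.DataFrame, manifest: Mapping) -> DetectionScore:
    """Capture calls scored on (plasmid, tRNA, dependency) triples."""
    expected = expected_captures(manifest)
    tp = fp = 0
    seen = set()
    for _, row in captures.iterrows():
        want = expected.get(row.plasmid_id)
        if want == (row.trna, row.dependency):
            tp += 1
            seen.add(row.plasmid_id)
        else:
            fp += 1
    fn = len(set(expected) - seen)
    return DetectionScore(true_positives=tp, false_positives=fp, false_negatives=fn)


def expected_losses(manifest: Mapping) -> list[tuple[str, str]]:
    return sorted((h["host_id"], t) for h in manifest["hosts"] for t in h["losses"])
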