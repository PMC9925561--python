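#!/usr/bin/env python
"""Screen every host assembly for linear-plasmid contigs.

Structural pass (5-15 kb size window, two >= 1 kb ORFs, TIR search,
polymerase verification against the panel, autonomy from the flanks)
plus the homology rescue pass for split plasmids. Writes
results/plasmid_calls.tsv and prints precision/recall against the
manifest when one is present.

Usage: python analysis/02_detect_plasmids.py [--dataset results/dataset]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mitoplasmid.align import ScoringScheme
from mitoplasmid.pipeline import load_dataset_dir
from mitoplasmid.plasmids import screen_assembly


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    hosts, _, panel = load_dataset_dir(args.dataset)
    mtdnas = [next(c for c in h.contigs if c.id == h.mtdna_id)
              for h in hosts if h.mtdna_id]
    scheme = ScoringScheme().calibrated()
    rows = []
    for h in hosts:
        calls, frags = screen_assembly(h.contigs, panel=panel,
                                       mtdna_set=mtdnas, strict=bool(panel),
                                       scheme=scheme)
        for c in calls:
            rows.append({"host_id": h.host_id, "contig_id": c.contig_id,
                         "structure": c.structure, "autonomy": c.autonomy,
                         "arrangement": c.arrangement,
                         "tir_length": c.tir.length if c.tir else 0})
        for f in frags:
            rows.append({"host_id": h.host_id, "contig_id": f.contig_id,
                         "structure": "fragment", "autonomy": "",
                         "arrangement": f"matches {f.plasmid_id}",
                         "tir_length": 0})
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "plasmid_calls.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    manifest_path = args.dataset / "manifest.json"
    if manifest_path.exists():
        from mitoplasmid.evaluate import score_detection

        manifest = json.loads(manifest_path.read_text())
        score = score_detection(df[df.structure != "fragment"], manifest)
        print(f"\ndetection vs manifest: precision={score.precision:.3f} "
              f"recall={score.recall:.3f}")


if __name__ == "__main__":
    main()
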