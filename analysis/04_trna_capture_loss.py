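#!/usr/bin/env python
"""tRNA captures on plasmids, mitochondrial loss, and flank profiles.

Finds reference tRNA genes on each detected plasmid (>= 90 % identity
over >= 90 % of the gene), tests whether the host assembly retains its
own mitochondrial copy (loss search at the looser 70 % / 50 % rule so
"lost" calls stay conservative), and writes the red/blue dependency
table plus a flank-homology profile of each capture against every
mitochondrial genome — the donor lineage shows homology extending
~300 bp beyond the gene on both sides.

Usage: python analysis/04_trna_capture_loss.py [--dataset results/dataset]
"""

import argparse
from pathlib import Path

import pandas as pd

from mitoplasmid.align import ScoringScheme
from mitoplasmid.pipeline import load_dataset_dir
from mitoplasmid.plasmids import screen_assembly
from mitoplasmid.trna import find_trna_captures, flank_homology_profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    hosts, trna_refs, panel = load_dataset_dir(args.dataset)
    mtdnas = [next(c for c in h.contigs if c.id == h.mtdna_id)
              for h in hosts if h.mtdna_id]
    scheme = ScoringScheme().calibrated()
    cap_rows, flank_rows = [], []
    for h in hosts:
        calls, _ = screen_assembly(h.contigs, panel=panel, mtdna_set=mtdnas,
                                   strict=bool(panel), scheme=scheme)
        by_id = {c.id: c for c in h.contigs}
        plasmid_ids = [c.contig_id for c in calls]
        for call in calls:
            plasmid = by_id[call.contig_id]
            caps = find_trna_captures(plasmid, trna_refs,
                                      host_assembly=h.contigs,
                                      host_plasmid_ids=plasmid_ids,
                                      scheme=scheme)
            for cap in caps:
                cap_rows.append({
                    "plasmid_id": call.contig_id, "host_id": h.host_id,
                    "trna": cap.trna.name, "identity": round(cap.identity, 4),
                    "mutations": cap.mutation_count,
                    "dependency": cap.dependency,
                    "color": "red" if cap.dependency == "adopted_lost" else "blue"})
                prof = flank_homology_profile(plasmid, cap, mtdnas,
                                              scheme=scheme)
                for sp, d in prof.per_species.items():
                    flank_rows.append({"plasmid_id": call.contig_id,
                                       "trna": cap.trna.name, "mtdna": sp, **d})
    caps_df = pd.DataFrame(cap_rows)
    flank_df = pd.DataFrame(flank_rows)
    args.out.mkdir(parents=True, exist_ok=True)
    caps_df.to_csv(args.out / "captures.tsv", sep="\t", index=False)
    flank_df.to_csv(args.out / "flank_profiles.tsv", sep="\t", index=False)
    print(caps_df.to_string(index=False))
    n_red = (caps_df.dependency == "adopted_lost").sum() if len(caps_df) else 0
    print(f"\n{len(caps_df)} captures; {n_red} with mitochondrial loss "
          f"(host dependent on the plasmid copy)")


if __name__ == "__main__":
    main()
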