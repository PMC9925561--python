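#!/usr/bin/env python
"""Cumulative plasmid-mtDNA homology matrix.

For every detected plasmid x every mitochondrial genome: total plasmid nt
covered by significant homologous segments (> 50 bp, E < 0.001), the
tabular analogue of the presence/length graph of the published homology
figure. A capture-bearing plasmid shows ~0.7 kb against its flank donor
(tRNA plus flanks) and only the bare tRNA (~70 nt) elsewhere; a host that
lost the locus shows nothing.

Usage: python analysis/03_homology_matrix.py [--dataset results/dataset]
"""

import argparse
from pathlib import Path

from mitoplasmid.align import ScoringScheme
from mitoplasmid.homology import homology_matrix
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
    plasmids = []
    for h in hosts:
        calls, _ = screen_assembly(h.contigs, panel=panel, mtdna_set=mtdnas,
                                   strict=bool(panel), scheme=scheme)
        by_id = {c.id: c for c in h.contigs}
        plasmids.extend(by_id[c.contig_id] for c in calls)
    m = homology_matrix(plasmids, mtdnas, scheme, method="seed")
    args.out.mkdir(parents=True, exist_ok=True)
    m.to_csv(args.out / "homology_matrix.tsv", sep="\t",
             index_label="plasmid_id")
    nonzero = (m > 0).sum().sum()
    print(m.to_string())
    print(f"\n{nonzero} plasmid-mtDNA pairs share significant homology")


if __name__ == "__main__":
    main()
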