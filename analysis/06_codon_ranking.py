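#!/usr/bin/env python
"""Codon-family usage over the 14 principal genes and captured-family ranks.

Tallies codons over atp6-nad6 for every mitochondrial genome, groups
them into the anticodon families decoded by the 24 mitochondrial tRNAs,
averages the per-genome fractions (unweighted), and ranks families
ascending by usage. On the default dataset the two captured-in-host
families, Arg-TCG and Cys, are the two rarest — rank 1 and 2 — echoing
the observation that plasmid-adopted tRNAs decode the least-used codons.

Usage: python analysis/06_codon_ranking.py [--dataset results/dataset]
"""

import argparse
from pathlib import Path

from mitoplasmid.codons import (average_family_fractions, count_codons,
                                load_family_map, rank_families)
from mitoplasmid.pipeline import load_dataset_dir
from mitoplasmid.seqs import SequenceRecord, extract_feature


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--captured", nargs="*",
                    default=["Arg-TCG", "Cys-GCA"],
                    help="families whose ranks to highlight")
    args = ap.parse_args()
    hosts, _, _ = load_dataset_dir(args.dataset)
    fam_map = load_family_map()
    tables = []
    for h in hosts:
        if h.annotations is None:
            continue
        mt = next(c for c in h.contigs if c.id == h.mtdna_id)
        a = h.annotations
        cds = [SequenceRecord(str(r.label),
                              extract_feature(mt.residues, int(r.start),
                                              int(r.end), str(r.strand)))
               for _, r in a[a.feature == "CDS"].iterrows()]
        tables.append(count_codons(cds, genome_id=h.host_id))
    avg = average_family_fractions(tables, fam_map)
    ranks = rank_families(avg, args.captured)
    args.out.mkdir(parents=True, exist_ok=True)
    ranks.to_csv(args.out / "codon_families.tsv", sep="\t", index=False)
    print(ranks.to_string(index=False))
    cap = ranks[ranks.captured]
    print("\ncaptured-family ranks:",
          dict(zip(cap.family, cap["rank"])))


if __name__ == "__main__":
    main()
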