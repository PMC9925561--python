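#!/usr/bin/env python
"""Generate the synthetic study dataset.

Twenty host strains, each with a mitochondrial genome (14 principal
genes, 24 tRNAs), 50 decoy contigs, and planted linear plasmids: nine
autonomous invertrons (two of them in one host), two non-invertron
linear plasmids, and three near-intact mitochondrial insertions. Six
tRNA captures are planted (three tRNA-Arg(TCG), two tRNA-Cys, one
tRNA-Trp), two of which coincide with loss of the mitochondrial copy.
The ground truth is written to results/dataset/manifest.json.

Usage: python analysis/01_simulate_dataset.py [--seed 1]
"""

import argparse
from pathlib import Path

from mitoplasmid.simulate import GeneratorConfig, generate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/dataset"))
    args = ap.parse_args()
    ds = generate_dataset(GeneratorConfig(seed=args.seed))
    write_dataset(ds, args.out)
    n_caps = sum(1 for p in ds.manifest["plasmids"] if p["capture"])
    n_loss = sum(len(h["losses"]) for h in ds.manifest["hosts"])
    print(f"wrote {len(ds.hosts)} hosts to {args.out}")
    print(f"planted: {len(ds.manifest['plasmids'])} plasmids, "
          f"{n_caps} tRNA captures, {n_loss} mitochondrial losses")


if __name__ == "__main__":
    main()
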