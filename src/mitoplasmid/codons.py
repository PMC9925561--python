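"""Codon usage over the principal mitochondrial genes, by anticodon family.

Codons are tallied cumulatively over the coding sequences of the 14
principal mitochondrial genes (atp6, atp8, atp9, cob, cox1-3, nad1-6,
nad4L), grouped into the synonymous families decoded by each
mitochondrial tRNA (isotype + anticodon), and the families are ranked by
usage. The shipped family map (``data/trna_families.tsv``) partitions the
62 mold-mitochondrial sense codons across a canonical 24-tRNA set and is
editable data, not code.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqs import GeneticCode, MOLD_MITO, SequenceRecord, check_nucleotide

log = logging.getLogger(__name__)

PRINCIPAL_GENES = ("atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
                   "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6")


@dataclass
class CodonUsageTable:
    genome_id: str
    counts: Counter = field(default_factory=Counter)
    internal_stops: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AnticodonFamily:
    isotype: str
    anticodon: str
    codons: tuple[str, ...]

    @property
    def name(self) -> str:
        return f"{self.isotype}-{self.anticodon}"


class AnticodonFamilyMap:
    """Mapping from mitochondrial tRNAs to the codon sets they decode."""

    def __init__(self, families: Sequence[AnticodonFamily],
                 code: GeneticCode = MOLD_MITO) -> None:
        self.families = list(families)
        self.code = code
        self.codon_to_family: dict[str, AnticodonFamily] = {}
        for fam in self.families:
            for codon in fam.codons:
                if codon in self.codon_to_family:
                    raise ValueError(f"codon {codon} assigned to two families")
                self.codon_to_family[codon] = fam
        sense = {c for c, aa in code.codon_to_aa.items() if aa != "*"}
        missing = sense - set(self.codon_to_family)
        if missing:
            raise ValueError(f"family map misses sense codons: {sorted(missing)}")

    def __iter__(self):
        return iter(self.families)

    def __len__(self) -> int:
        return len(self.families)

    def family(self, name: str) -> AnticodonFamily:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(f"no anticodon family named {name!r}")


def load_family_map(path: str | Path | None = None,
                    code: GeneticCode = MOLD_MITO) -> AnticodonFamilyMap:
    """Load the family map TSV (isotype, anticodon, comma-separated codons)."""
    if path is None:
        text = resources.files("mitoplasmid.data").joinpath("trna_families.tsv").read_text()
    else:
        text = Path(path).read_text()
    families = []
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        isotype, anticodon, codons = line.split("\t")
        families.append(AnticodonFamily(
            isotype=isotype, anticodon=anticodon,
            codons=tuple(c.strip().upper() for c in codons.split(","))))
    return AnticodonFamilyMap(families, code)


def count_codons(cds_list: Sequence[SequenceRecord],
                 code: GeneticCode = MOLD_MITO,
                 genome_id: str = "") -> CodonUsageTable:
    """Frame-0 triplet tally over a gene set; terminal stops excluded.

    Internal stop codons are counted but flagged as a data-quality
    warning.
    """
    table = CodonUsageTable(genome_id=genome_id)
    stops = code.stop_codons
    for cds in cds_list:
        seq = cds.residues.upper()
        if len(seq) < 3:
            raise ValueError(f"CDS {cds.id}: shorter than one codon")
        check_nucleotide(seq, f"CDS {cds.id}")
        codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        for c in codons:
            if c in stops:
                table.internal_stops += 1
            table.counts[c] += 1
    if table.internal_stops:
        log.warning("genome %s: %d internal stop codons in the gene set",
                    genome_id or "?", table.internal_stops)
    return table


def aggregate_families(table: CodonUsageTable,
                       family_map: AnticodonFamilyMap) -> pd.Series:
    """Per-family fraction of total codon count (sums to 1)."""
    counts: dict[str, int] = {fam.name: 0 for fam in family_map}
    for codon, n in table.counts.items():
        if "N" in codon:
            continue
        fam = family_map.codon_to_family.get(codon)
        if fam is None:
            if family_map.code.codon_to_aa.get(codon) == "*":
                continue  # internal stop, already flagged by count_codons
            raise ValueError(f"codon {codon} has no anticodon family")
        counts[fam.name] += n
    total = sum(counts.values())
    frac = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return pd.Series(frac, name=table.genome_id or "fraction")


def average_family_fractions(tables: Sequence[CodonUsageTable],
                             family_map: AnticodonFamilyMap,
                             pooled: bool = False) -> pd.Series:
    """Cross-genome average codon-family usage.

    Default is the unweighted mean of per-genome fractions (so long
    genomes do not dominate); ``pooled=True`` pools raw counts instead.
    """
    if pooled:
        merged = CodonUsageTable(genome_id="pooled")
        for t in tables:
            merged.counts.update(t.counts)
        return aggregate_families(merged, family_map)
    per = pd.DataFrame([aggregate_families(t, family_map) for t in tables])
    return per.mean(axis=0)


def rank_families(frequencies: Mapping[str, float] | pd.Series,
                  captured_families: Iterable[str] = ()) -> pd.DataFrame:
    """Rank families ascending by usage (1 = rarest; ties share the smaller rank).

    Returns a table with columns family, fraction, rank, captured.
    """
    freq = pd.Series(dict(frequencies), dtype=float).sort_values(kind="stable")
    captured = set(captured_families)
    unknown = captured - set(freq.index)
    if unknown:
        raise KeyError(f"captured families not in the map: {sorted(unknown)}")
    values = freq.to_numpy()
    ranks = [int((values < v).sum()) + 1 for v in values]  # competition ranking
    return pd.DataFrame({
        "family": freq.index,
        "fraction": values,
        "rank": ranks,
        "captured": [f in captured for f in freq.index],
    }).reset_index(drop=True)
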