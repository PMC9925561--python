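"""Nucleotide and protein sequence primitives.

Sequence records, genetic-code presets (standard and mold mitochondrial,
in which TGA encodes tryptophan), frame-0 translation, six-frame
stop-to-stop ORF calling, and FASTA / annotation-table I/O.

Coordinates are 0-based half-open on the forward strand throughout the
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NUC_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# residue -> small integer for numeric kernels; N=4, anything masked=5
_NUC_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NUC_CODE[ord(_b)] = _i
    _NUC_CODE[ord(_b.lower())] = _i


class InvalidAlphabetError(ValueError):
    """Raised when a nucleotide sequence contains characters outside ACGTN."""


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the offending line."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence."""

    id: str
    residues: str
    description: str = ""
    moltype: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table plus start codons."""

    name: str
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code {self.name!r}: expected 64 codons, "
                             f"got {len(self.codon_to_aa)}")

    @property
    def stop_codons(self) -> set[str]:
        return {c for c, a in self.codon_to_aa.items() if a == "*"}

    # 64-entry amino-acid array indexed by 16a+4b+c for numeric translation
    def aa_array(self) -> np.ndarray:
        arr = np.empty(64, dtype="U1")
        for codon, aa in self.codon_to_aa.items():
            i = _NUC_CODE[ord(codon[0])] * 16 + _NUC_CODE[ord(codon[1])] * 4 + _NUC_CODE[ord(codon[2])]
            arr[i] = aa
        return arr


def _load_codes() -> dict[str, GeneticCode]:
    text = resources.files("mitoplasmid.data").joinpath("genetic_codes.json").read_text()
    raw = json.loads(text)
    return {
        name: GeneticCode(name=name,
                          codon_to_aa=entry["codon_to_aa"],
                          start_codons=frozenset(entry["start_codons"]))
        for name, entry in raw.items()
    }


_CODES = _load_codes()


def genetic_code(name: str) -> GeneticCode:
    """Return a shipped genetic-code preset (``"mold_mito"`` or ``"standard"``)."""
    try:
        return _CODES[name]
    except KeyError:
        raise KeyError(f"unknown genetic code {name!r}; available: {sorted(_CODES)}") from None


MOLD_MITO = genetic_code("mold_mito")
STANDARD = genetic_code("standard")


def check_nucleotide(seq: str, where: str = "sequence") -> None:
    bad = set(seq.upper()) - NUC_ALPHABET
    if bad:
        raise InvalidAlphabetError(f"{where}: non-ACGTN characters {sorted(bad)!r}")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map residues to int8 codes A=0 C=1 G=2 T=3 N=4 (vectorised)."""
    return _NUC_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def translate(seq: str, code: GeneticCode = MOLD_MITO) -> str:
    """Translate frame 0; incomplete trailing triplet dropped, stops are '*'.

    Codons containing N translate to 'X' and never register as stops.
    """
    if len(seq) < 3:
        raise ValueError("translate: sequence shorter than one codon")
    check_nucleotide(seq, "translate")
    codes = encode(seq)
    n = len(codes) // 3
    trip = codes[: n * 3].reshape(n, 3)
    has_n = (trip == 4).any(axis=1)
    idx = trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]
    idx[has_n] = 0
    aa = code.aa_array()[idx]
    aa[has_n] = "X"
    return "".join(aa)


@dataclass
class OpenReadingFrame:
    """A maximal stop-free stretch on one strand, forward-strand coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    aa_length: int
    protein: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ORF end must exceed start")
        if (self.end - self.start) % 3:
            raise ValueError("ORF span must be a codon multiple")

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "OpenReadingFrame") -> bool:
        return self.start < other.end and other.start < self.end


def find_orfs(contig: SequenceRecord, code: GeneticCode = MOLD_MITO,
              min_nt: int = 1000, require_start: bool = False) -> list[OpenReadingFrame]:
    """Call stop-to-stop ORFs on both strands, all six frames.

    Returns every maximal stop-free stretch of length >= ``min_nt``
    (nucleotides), sorted by amino-acid length descending then by forward
    coordinate. An initiator codon is not required unless
    ``require_start`` is set, in which case the stretch is trimmed to its
    first start codon.
    """
    if min_nt < 3:
        raise ValueError("min_nt must be >= 3")
    check_nucleotide(contig.residues, f"contig {contig.id}")
    seq = contig.residues.upper()
    L = len(seq)
    orfs: list[OpenReadingFrame] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            if L - frame < 3:
                continue
            prot = translate(s[frame:], code)
            pos = 0
            for chunk in prot.split("*"):
                if chunk:
                    a0, a1 = pos, pos + len(chunk)
                    if require_start:
                        trimmed = _trim_to_start(s, frame, a0, a1, code)
                        if trimmed is None:
                            pos = a1 + 1
                            continue
                        a0 = trimmed
                        chunk = chunk[trimmed - pos:]
                    nt0 = frame + 3 * a0
                    nt1 = frame + 3 * a1
                    if nt1 - nt0 >= min_nt:
                        if strand == "+":
                            start, end = nt0, nt1
                        else:
                            start, end = L - nt1, L - nt0
                        orfs.append(OpenReadingFrame(
                            contig_id=contig.id, start=start, end=end,
                            strand=strand, aa_length=len(chunk), protein=chunk))
                pos += len(chunk) + 1
    orfs.sort(key=lambda o: (-o.aa_length, o.start, o.strand))
    return orfs


def _trim_to_start(s: str, frame: int, a0: int, a1: int, code: GeneticCode) -> int | None:
    for a in range(a0, a1):
        codon = s[frame + 3 * a: frame + 3 * a + 3]
        if codon in code.start_codons:
            return a
    return None


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, moltype: str = "nucleotide",
               uppercase: bool = True) -> list[SequenceRecord]:
    """Parse a multi-record FASTA file (wrapped or unwrapped dialects).

    Residues are uppercased on read by default. Malformed headers and empty
    files raise :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []
    lineno_of_header = 0
    seen: set[str] = set()

    def flush(lineno: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}:{lineno_of_header}: record {header!r} has no residues")
        if uppercase:
            seq = seq.upper()
        rid, _, desc = header.partition(" ")
        if rid in seen:
            raise FastaParseError(f"{path}:{lineno_of_header}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, residues=seq, description=desc, moltype=moltype))
        header, chunks = None, []

    with open(path) as fh:
        any_line = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            any_line = True
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                lineno_of_header = lineno
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FastaParseError(f"{path}:{lineno}: residues before any '>' header")
                chunks.append(line)
        if not any_line:
            raise FastaParseError(f"{path}:1: empty FASTA file")
        flush(lineno + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i: i + width] + "\n")


# ---------------------------------------------------------------------------
# Minimal annotation table (id, feature, start, end, strand, label)

ANNOTATION_COLUMNS = ["seq_id", "feature", "start", "end", "strand", "label"]


def read_annotations(path: str | Path) -> "pd.DataFrame":
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {sorted(missing)}")
    return df


def write_annotations(df: "pd.DataFrame", path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def extract_feature(seq: str, start: int, end: int, strand: str) -> str:
    """Pull a feature's residues given forward-strand half-open coordinates."""
    sub = seq[start:end]
    return revcomp(sub) if strand == "-" else sub
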