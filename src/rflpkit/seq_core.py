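"""Sequence foundation: IUPAC alphabet semantics, reverse complement, FASTA I/O.

DNA is held as uppercase IUPAC text (``ACGTRYSWKMBDHVN``; ``U`` is normalised
to ``T`` on input).  Degenerate matching comes in two modes used throughout
the package:

``strict``
    the template symbol's base set is a *subset* of the pattern symbol's —
    a match is guaranteed whatever concrete base the template represents.
``permissive``
    the two base sets merely intersect — a match is possible.

Strict matching is what makes in-silico digestion reproducible: an ambiguous
template base only produces a cut if every base it could stand for completes
the recognition site.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from typing import Iterable, TextIO

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import AlphabetError, EmptyInput

#: Base sets of the 15 IUPAC DNA symbols, as frozensets of {A, C, G, T}.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}

COMPLEMENT = {
    code: _SET_TO_CODE[frozenset({"T": "A", "A": "T", "C": "G", "G": "C"}[b]
                                 for b in bases)]
    for code, bases in IUPAC_SETS.items()
}

# Per pattern symbol, the template symbols it accepts in each mode.
STRICT_ACCEPTS: dict[str, frozenset[str]] = {
    p: frozenset(t for t in IUPAC_ALPHABET if IUPAC_SETS[t] <= IUPAC_SETS[p])
    for p in IUPAC_ALPHABET
}
PERMISSIVE_ACCEPTS: dict[str, frozenset[str]] = {
    p: frozenset(t for t in IUPAC_ALPHABET if IUPAC_SETS[t] & IUPAC_SETS[p])
    for p in IUPAC_ALPHABET
}

_TAG_RE = re.compile(r"\[(\w+)=([^\]]*)\]")


@dataclass
class NucleotideSequence:
    """An identified IUPAC DNA sequence, optionally species/region labelled."""

    id: str
    residues: str
    topology: str = "linear"  # "linear" or "circular"
    species: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.residues = normalize(self.residues, record=self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def with_residues(self, residues: str) -> "NucleotideSequence":
        return replace(self, residues=residues)


def normalize(residues: str, record: str = "<anonymous>") -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet.

    Raises :class:`AlphabetError` naming the record and the 0-based position
    of the first offending symbol.  Gap and whitespace characters are
    rejected: the toolkit operates on unaligned amplicon sequences.
    """
    if not residues:
        raise AlphabetError(f"record {record!r} has an empty sequence",
                            record=record)
    out = residues.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in IUPAC_ALPHABET:
            raise AlphabetError(
                f"record {record!r} has non-IUPAC symbol {ch!r} at "
                f"position {i}", record=record, position=i)
    return out


def reverse_complement(residues: str) -> str:
    """Reverse complement of IUPAC text; ambiguity codes complement by
    base-set complement (R<->Y, S<->S, W<->W, K<->M, B<->V, D<->H, N<->N)."""
    residues = normalize(residues)
    # Bio.Seq implements exactly the base-set complement for IUPAC codes.
    return str(Seq(residues).reverse_complement())


def iupac_match(pattern_symbol: str, template_symbol: str,
                mode: str = "strict") -> bool:
    """Does ``template_symbol`` match ``pattern_symbol``?

    strict: template base set is a subset of the pattern's (match guaranteed
    for any underlying base).  permissive: the base sets intersect.
    """
    p = pattern_symbol.upper()
    t = template_symbol.upper()
    if p not in IUPAC_ALPHABET or t not in IUPAC_ALPHABET:
        raise AlphabetError(f"non-IUPAC symbol in pair ({p!r}, {t!r})")
    if mode == "strict":
        return t in STRICT_ACCEPTS[p]
    if mode == "permissive":
        return t in PERMISSIVE_ACCEPTS[p]
    raise ValueError(f"unknown match mode {mode!r}")


def _parse_header(header: str) -> tuple[str, dict[str, str]]:
    tags = dict(_TAG_RE.findall(header))
    ident = _TAG_RE.sub("", header).split()
    if not ident:
        raise EmptyInput(f"FASTA header {header!r} has no id")
    return ident[0], tags


def parse_fasta(stream: TextIO | str) -> list[NucleotideSequence]:
    """Parse FASTA into records.

    Header dialect: ``>id [species=...] [region=...] [topology=...]`` with all
    bracketed tags optional.  Residues are normalised (uppercase, U->T) and
    validated.  Ids must be unique.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for header, seq in SimpleFastaParser(stream):
        ident, tags = _parse_header(header)
        if ident in seen:
            raise ValueError(f"duplicate FASTA id {ident!r}")
        seen.add(ident)
        records.append(NucleotideSequence(
            id=ident,
            residues=seq.replace(" ", ""),
            topology=tags.get("topology", "linear"),
            species=tags.get("species"),
            region=tags.get("region"),
        ))
    if not records:
        raise EmptyInput("no FASTA records in input")
    return records


def format_fasta(records: Iterable[NucleotideSequence], width: int = 70) -> str:
    """Serialise records back to FASTA with the bracketed tag dialect.

    Round-trips with :func:`parse_fasta` (id, tags, residues preserved)."""
    chunks: list[str] = []
    for rec in records:
        header = rec.id
        if rec.species is not None:
            header += f" [species={rec.species}]"
        if rec.region is not None:
            header += f" [region={rec.region}]"
        if rec.topology != "linear":
            header += f" [topology={rec.topology}]"
        chunks.append(">" + header)
        for i in range(0, len(rec.residues), width):
            chunks.append(rec.residues[i:i + width])
    return "\n".join(chunks) + "\n"


def write_fasta(records: Iterable[NucleotideSequence], stream: TextIO,
                width: int = 70) -> None:
    stream.write(format_fasta(records, width=width))


def read_species_map(stream: TextIO | str) -> dict[str, str]:
    """Read a two-column ``id<TAB>species`` sidecar mapping file."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping: dict[str, str] = {}
    for n, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {n}: expected 'id<TAB>species'")
        mapping[parts[0]] = parts[1]
    return mapping


def apply_species_map(records: Iterable[NucleotideSequence],
                      mapping: dict[str, str]) -> list[NucleotideSequence]:
    """Attach species labels from a sidecar map (header tags win)."""
    out = []
    for rec in records:
        if rec.species is None and rec.id in mapping:
            rec = replace(rec, species=mapping[rec.id])
        out.append(rec)
    return out
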