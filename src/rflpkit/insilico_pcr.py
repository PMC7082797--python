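"""In-silico PCR: degenerate primer binding-site search and amplicon extraction.

Primers are written 5'->3'.  A forward primer binds the plus strand directly;
a reverse primer binds the minus strand, so its binding site appears on the
plus strand as the primer's reverse complement.  Matching is strict-IUPAC
(template base set contained in the primer's) with an optional whole-primer
mismatch budget; by default the 3'-terminal three positions must match
exactly, reflecting the polymerase's intolerance of 3' mispairing.

Coordinates are 0-based half-open on the plus strand of the template.  On
circular templates an origin-spanning product reports ``end > len(template)``
and is interpreted modulo the template length.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

from .errors import NoMatchPossible
from .seq_core import (NucleotideSequence, STRICT_ACCEPTS, normalize,
                       reverse_complement)

DEFAULT_MAX_MISMATCH = 2
DEFAULT_ANCHOR_3PRIME = 3
DEFAULT_MAX_PRODUCT = 2000


@dataclass(frozen=True)
class Primer:
    """A degenerate oligo, 5'->3'."""

    name: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", normalize(self.residues, self.name))
        if len(self.residues) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: Primer
    reverse: Primer
    expected_length: int | None = None

    def __post_init__(self):
        if (self.expected_length is not None
                and self.expected_length <= len(self.forward) + len(self.reverse)):
            raise ValueError("expected_length must exceed combined primer length")


@dataclass(frozen=True)
class PrimerMatch:
    """One binding site: [start, end) on the plus strand, mismatch count."""

    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A PCR product.  ``residues`` includes both primer-binding regions;
    ``end`` may exceed the template length for origin-spanning circular
    products (interpret modulo length)."""

    source_id: str
    start: int
    end: int
    residues: str
    species: str | None = None
    region: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def to_record(self) -> NucleotideSequence:
        return NucleotideSequence(
            id=f"{self.source_id}:{self.start}-{self.end}",
            residues=self.residues, species=self.species, region=self.region)


def _scan(template: str, pattern: str, max_mismatch: int,
          anchored_tail: int) -> list[PrimerMatch]:
    """All windows where <= max_mismatch template symbols fail a strict
    IUPAC match against ``pattern``; the last ``anchored_tail`` pattern
    positions must match exactly."""
    m = len(pattern)
    n = len(template)
    accepts = [STRICT_ACCEPTS[p] for p in pattern]
    tail_from = m - anchored_tail
    hits: list[PrimerMatch] = []
    for start in range(n - m + 1):
        mism = 0
        for j in range(m):
            if template[start + j] not in accepts[j]:
                if j >= tail_from:
                    mism = max_mismatch + 1
                    break
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            hits.append(PrimerMatch(start, start + m, mism))
    return hits


def find_primer_matches(template: NucleotideSequence, primer: Primer,
                        strand: str = "plus", max_mismatch: int = 0,
                        anchor_3prime: int = 0) -> list[PrimerMatch]:
    """Locate primer binding sites on one strand of a template.

    For ``strand="minus"`` the primer's reverse complement is matched against
    the plus strand (coordinates still reported on the plus strand).  With
    ``anchor_3prime=k`` the k primer positions at the 3' end must match with
    zero mismatches.  Circular templates also report origin-spanning sites,
    whose start lies in ``[0, len)`` with ``end`` possibly beyond ``len``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if len(primer) > len(template):
        raise NoMatchPossible(
            f"primer {primer.name!r} ({len(primer)} nt) longer than template "
            f"{template.id!r} ({len(template)} nt)")
    if strand == "plus":
        pattern = primer.residues
        anchored_tail = anchor_3prime
    elif strand == "minus":
        pattern = reverse_complement(primer.residues)
        anchored_tail = 0  # the primer 3' end is now the pattern's left edge
    else:
        raise ValueError(f"unknown strand {strand!r}")

    seq = template.residues
    if template.is_circular:
        # extend past the origin by one pattern length to catch spanning hits
        seq = seq + seq[:len(pattern) - 1]
    hits = _scan(seq, pattern, max_mismatch, anchored_tail)
    if strand == "minus" and anchor_3prime:
        # re-check the anchored positions: leftmost k pattern symbols
        hits = [h for h in hits
                if all(seq[h.start + j] in STRICT_ACCEPTS[pattern[j]]
                       for j in range(anchor_3prime))]
    return sorted(hits, key=lambda h: h.start)


def amplify(template: NucleotideSequence, pair: PrimerPair,
            max_mismatch: int = DEFAULT_MAX_MISMATCH,
            max_product: int = DEFAULT_MAX_PRODUCT,
            anchor_3prime: int = DEFAULT_ANCHOR_3PRIME,
            trim_primers: bool = False) -> list[Amplicon]:
    """All products the primer pair would amplify from one template.

    A product pairs a forward plus-strand hit with a reverse minus-strand hit
    lying downstream (for circular templates, possibly across the origin) and
    spans from the first base of the forward match through the last base of
    the reverse match.  No valid pairing yields an empty list, not an error:
    templates genuinely may fail to amplify with a given pair.
    """
    if max_product <= 0:
        raise ValueError("max_product must be positive")
    try:
        fwd = find_primer_matches(template, pair.forward, "plus",
                                  max_mismatch, anchor_3prime)
        rev = find_primer_matches(template, pair.reverse, "minus",
                                  max_mismatch, anchor_3prime)
    except NoMatchPossible:
        return []
    L = len(template)
    doubled = template.residues * 2
    products: list[Amplicon] = []
    for f in fwd:
        if f.start >= L:  # only seed from canonical coordinates
            continue
        for r in rev:
            r_start, r_end = r.start, r.end
            if template.is_circular and r_start < f.end:
                r_start, r_end = r_start + L, r_end + L
            if r_start < f.end:
                continue  # primers overlap or reverse upstream of forward
            length = r_end - f.start
            if length > max_product or length > len(doubled):
                continue
            if template.is_circular and length > L:
                continue
            residues = (doubled[f.start:r_end] if template.is_circular
                        else template.residues[f.start:r_end])
            start, end = f.start, r_end
            if trim_primers:
                residues = residues[len(pair.forward):-len(pair.reverse)]
                start += len(pair.forward)
                end -= len(pair.reverse)
                if not residues:
                    continue
            products.append(Amplicon(
                source_id=template.id, start=start, end=end,
                residues=residues, species=template.species,
                region=template.region))
    products.sort(key=lambda a: (a.start, len(a)))
    return products


def load_primer_pairs() -> dict[str, PrimerPair]:
    """Load the bundled primer-pair table (16S, COI-short, COI-LCO, COI-long)."""
    text = (importlib.resources.files("rflpkit.data") / "primers.tsv").read_text()
    pairs: dict[str, PrimerPair] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, fname, fseq, rname, rseq, exp = line.split("\t")
        pairs[name] = PrimerPair(
            name=name,
            forward=Primer(fname, fseq),
            reverse=Primer(rname, rseq),
            expected_length=int(exp) if exp else None)
    return pairs
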