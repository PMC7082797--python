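"""Restriction digestion of linear DNA: site mapping and fragment lengths.

An enzyme is modelled by its IUPAC recognition site and a single top-strand
cut offset (blunt/palindromic model): the double-strand geometry of sticky
ends is irrelevant when the only observable is fragment length on an agarose
gel.  Both strands are searched — a non-palindromic site occurring as its
reverse complement on the plus strand cuts at the mirrored offset.

Strict matching (ambiguous template bases must *guarantee* the site) is the
default so digest patterns are reproducible; permissive matching (the site is
merely possible) is available for exploratory screening and always yields a
superset of the strict cuts.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass

from .insilico_pcr import Amplicon
from .seq_core import (PERMISSIVE_ACCEPTS, STRICT_ACCEPTS, normalize,
                       reverse_complement)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """name, IUPAC recognition site, and top-strand cut offset.

    ``cut_offset`` counts positions from the site's 5' end on the top strand,
    e.g. DraI TTT^AAA has site ``TTTAAA`` and offset 3.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        object.__setattr__(self, "site", normalize(self.site, self.name))
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site "
                f"of length {len(self.site)}")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


@dataclass(frozen=True)
class DigestResult:
    amplicon_id: str
    enzyme: str
    fragments: tuple[int, ...]        # sorted descending
    cut_positions: tuple[int, ...]    # sorted ascending, 0-based
    length: int

    def __post_init__(self):
        assert sum(self.fragments) == self.length
        assert len(self.fragments) == len(self.cut_positions) + 1


def _site_regex(site: str, mode: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all found
    accepts = STRICT_ACCEPTS if mode == "strict" else PERMISSIVE_ACCEPTS
    body = "".join("[" + "".join(sorted(accepts[s])) + "]" for s in site)
    return re.compile(f"(?=({body}))")


def _occurrences(seq: str, site: str, mode: str) -> list[int]:
    return [m.start() for m in _site_regex(site, mode).finditer(seq)]


def find_sites(seq: str, enzyme: RestrictionEnzyme,
               mode: str = "strict") -> list[int]:
    """All cut positions the enzyme produces on a linear sequence.

    A top-strand site occurrence at i cuts at ``i + cut_offset``; an
    occurrence of the site's reverse complement at i (non-palindromic
    enzymes) cuts at ``i + len(site) - cut_offset``.  Duplicates collapse;
    positions are 0-based counts of nucleotides left of the cut.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown match mode {mode!r}")
    seq = normalize(seq)
    cuts = {i + enzyme.cut_offset
            for i in _occurrences(seq, enzyme.site, mode)}
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.site)
        cuts |= {i + len(enzyme.site) - enzyme.cut_offset
                 for i in _occurrences(seq, rc, mode)}
    # end cuts produce no new fragment boundary on a linear molecule
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest_linear(amplicon: Amplicon | str, enzyme: RestrictionEnzyme,
                  mode: str = "strict") -> DigestResult:
    """Fragment-length multiset from digesting one linear amplicon.

    Fragments are the consecutive differences of ``[0] + cuts + [length]``,
    reported sorted descending (gel order, largest first)."""
    if isinstance(amplicon, str):
        seq, ident = normalize(amplicon), "<anonymous>"
    else:
        seq, ident = amplicon.residues, amplicon.source_id
    cuts = find_sites(seq, enzyme, mode)
    bounds = [0, *cuts, len(seq)]
    fragments = sorted((b - a for a, b in zip(bounds, bounds[1:])),
                       reverse=True)
    return DigestResult(amplicon_id=ident, enzyme=enzyme.name,
                        fragments=tuple(fragments),
                        cut_positions=tuple(cuts), length=len(seq))


def load_enzymes() -> dict[str, RestrictionEnzyme]:
    """Load the bundled commercial enzyme table (name, site, cut_offset)."""
    text = (importlib.resources.files("rflpkit.data") / "enzymes.tsv").read_text()
    enzymes: dict[str, RestrictionEnzyme] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, site, offset = line.split("\t")
        enzymes[name] = RestrictionEnzyme(name, site, int(offset))
    return enzymes


DRA_I = RestrictionEnzyme("DraI", "TTTAAA", 3)
ALU_I = RestrictionEnzyme("AluI", "AGCT", 2)
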