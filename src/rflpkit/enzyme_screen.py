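"""Screen a restriction-enzyme library for species-discriminating power.

For each enzyme every amplicon is digested, digests are grouped into a
per-species pattern catalogue under the gel model, and a species pair counts
as *separated* when no pattern of one equals any pattern of the other.  The
score is the fraction of species pairs separated; intra-species pattern
multiplicity is a tie-break penalty (multiple patterns per species make an
assay harder to read) rather than a hard filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .digestion import RestrictionEnzyme, digest_linear
from .errors import EmptyLibrary, IncomparablePatterns
from .insilico_pcr import Amplicon
from .rflp_patterns import GelModel, PatternCatalog, group_patterns, patterns_equal


@dataclass(frozen=True)
class EnzymeScore:
    enzyme: str
    pairs_separated: int
    pairs_total: int
    intra_species_splits: int
    discriminates_target: bool
    score: float
    total_cuts: int

    def __post_init__(self):
        assert self.pairs_separated <= self.pairs_total


def _species_separated(catalog: PatternCatalog, a: str, b: str,
                       gel: GelModel) -> bool:
    for ea in catalog.by_species[a]:
        for eb in catalog.by_species[b]:
            try:
                if patterns_equal(ea.pattern, eb.pattern, gel):
                    return False
            except IncomparablePatterns:  # pragma: no cover - same catalogue
                raise
    return True


def score_enzyme(labeled: list[tuple[str, Amplicon]],
                 enzyme: RestrictionEnzyme, gel: GelModel,
                 target: str | None = None,
                 region: str = "") -> EnzymeScore:
    digests = [(sp, digest_linear(amp, enzyme)) for sp, amp in labeled]
    total_cuts = sum(len(d.cut_positions) for _, d in digests)
    catalog = group_patterns(digests, gel, region=region)
    species = sorted(catalog.by_species)
    pairs = list(combinations(species, 2))
    separated = {(a, b) for a, b in pairs
                 if _species_separated(catalog, a, b, gel)}
    intra = sum(1 for sp in species if len(catalog.by_species[sp]) > 1)
    if target is not None and target in species:
        discriminates = all((a, b) in separated
                            for a, b in pairs if target in (a, b))
    else:
        discriminates = False
    return EnzymeScore(
        enzyme=enzyme.name,
        pairs_separated=len(separated), pairs_total=len(pairs),
        intra_species_splits=intra, discriminates_target=discriminates,
        score=len(separated) / len(pairs) if pairs else 0.0,
        total_cuts=total_cuts)


def screen_enzymes(labeled: list[tuple[str, Amplicon]],
                   library: list[RestrictionEnzyme],
                   gel: GelModel = GelModel(),
                   target: str | None = None,
                   region: str = "") -> list[EnzymeScore]:
    """Rank a library of enzymes by pairwise species separation.

    Ranking: score descending, then fewer intra-species splits, then fewer
    total cuts (simpler gels win ties), then name.  Scores are independent:
    adding or removing other enzymes never changes an enzyme's score.
    """
    if not library:
        raise EmptyLibrary("no enzymes to screen")
    if len({sp for sp, _ in labeled}) < 2:
        raise ValueError("screening needs at least two species")
    scores = [score_enzyme(labeled, enz, gel, target, region)
              for enz in library]
    scores.sort(key=lambda s: (-s.score, s.intra_species_splits,
                               s.total_cuts, s.enzyme))
    return scores


def screen_to_tsv(scores: list[EnzymeScore]) -> str:
    lines = ["enzyme\tscore\tpairs_separated\tpairs_total"
             "\tintra_species_splits\tdiscriminates_target"]
    for s in scores:
        lines.append(f"{s.enzyme}\t{s.score:.4f}\t{s.pairs_separated}"
                     f"\t{s.pairs_total}\t{s.intra_species_splits}"
                     f"\t{str(s.discriminates_target).lower()}")
    return "\n".join(lines) + "\n"
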