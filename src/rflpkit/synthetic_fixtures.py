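"""Synthetic species-labelled amplicon sets with known ground truth.

The generator plants concrete primer-binding regions at the amplicon ends
and concrete enzyme recognition sites at chosen cut positions, excludes the
recognition site everywhere else by rejection sampling, and then applies
per-sequence mutations outside the protected windows (primers + sites).
Planted fragment lengths are therefore exact ground truth at zero mutation
rate, and every record amplifies to exactly one full-length product with the
paired primers.

This emulates curated GenBank amplicon sets — species-labelled, with modest
intra-species variation — but not real mitochondrial base composition,
phylogenetic correlation structure, or sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digestion import RestrictionEnzyme, find_sites
from .errors import InfeasibleConfig
from .insilico_pcr import PrimerPair
from .rflp_patterns import GelModel
from .seq_core import (IUPAC_SETS, NucleotideSequence, format_fasta,
                       reverse_complement)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Geometry and noise model for one synthetic dataset.

    ``planted_patterns`` maps species name to one or more fragment-length
    lists, each summing to ``amplicon_length``; sequences of a species are
    assigned to its patterns round-robin.
    """

    planted_patterns: dict[str, list[list[int]]]
    seqs_per_species: int = 10
    amplicon_length: int = 438
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    max_substitutions: int | None = None
    shared_background: bool = False
    seed: int = 0

    @property
    def n_species(self) -> int:
        return len(self.planted_patterns)

    def __post_init__(self):
        if not self.planted_patterns:
            raise InfeasibleConfig("need at least one species")
        if self.seqs_per_species < 1:
            raise InfeasibleConfig("need at least one sequence per species")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise InfeasibleConfig("rates must be in [0, 1)")
        for sp, patterns in self.planted_patterns.items():
            if not patterns:
                raise InfeasibleConfig(f"species {sp!r} has no patterns")
            for frags in patterns:
                if any(f < 1 for f in frags):
                    raise InfeasibleConfig(
                        f"species {sp!r} has a fragment < 1 bp")
                if sum(frags) != self.amplicon_length:
                    raise InfeasibleConfig(
                        f"species {sp!r}: fragments {frags} sum to "
                        f"{sum(frags)}, not {self.amplicon_length}")


@dataclass
class TruthRow:
    id: str
    species: str
    intended_fragments: tuple[int, ...]
    n_substitutions: int
    n_indels: int


def _realize(iupac: str, rng: np.random.Generator) -> str:
    """A concrete ACGT realisation of degenerate IUPAC text."""
    return "".join(
        ch if ch in "ACGT"
        else sorted(IUPAC_SETS[ch])[rng.integers(len(IUPAC_SETS[ch]))]
        for ch in iupac)


def _strict_occurrences(seq: str, site: str) -> list[int]:
    hits = []
    for i in range(len(seq) - len(site) + 1):
        if all(seq[i + j] in IUPAC_SETS[site[j]] for j in range(len(site))):
            hits.append(i)
    return hits


def _build_master(frags: list[int], enzyme: RestrictionEnzyme,
                  fwd: str, rev_rc: str, length: int,
                  rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """One concrete master amplicon digesting to exactly ``frags``.

    Returns the sequence and the protected windows (primers + sites)."""
    site_len = len(enzyme.site)
    cuts = list(np.cumsum(frags)[:-1])
    windows = []
    for cut in cuts:
        start = cut - enzyme.cut_offset
        if start < len(fwd) or start + site_len > length - len(rev_rc):
            raise InfeasibleConfig(
                f"cut at {cut} places the {enzyme.name} site inside a "
                f"primer region")
        windows.append((start, start + site_len))
    windows.sort()
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if a2 < b1:
            raise InfeasibleConfig(
                f"planted {enzyme.name} sites at {a1} and {a2} overlap")
    protected = [(0, len(fwd)), (length - len(rev_rc), length), *windows]
    rc_site = None if enzyme.is_palindromic else reverse_complement(enzyme.site)

    planted_starts = {a for a, _ in windows}
    mutable = np.ones(length, dtype=bool)
    for a, b in protected:
        mutable[a:b] = False

    for _attempt in range(200):
        seq = list(fwd + "".join(rng.choice(_BASES, length - len(fwd)
                                            - len(rev_rc))) + rev_rc)
        for a, b in windows:
            seq[a:b] = _realize(enzyme.site, rng)
        text = "".join(seq)
        bad: set[int] = set()
        for i in _strict_occurrences(text, enzyme.site):
            if i not in planted_starts:
                bad.add(i)
        if rc_site is not None:
            for i in _strict_occurrences(text, rc_site):
                bad.add(i)
        fixable = True
        for i in sorted(bad):
            span = [j for j in range(i, i + site_len) if mutable[j]]
            if not span:
                fixable = False
                break
        if not fixable:
            continue  # unlucky primer-realisation overlap; try again
        # iteratively knock out spurious occurrences
        for _round in range(50):
            if not bad:
                break
            for i in sorted(bad):
                span = [j for j in range(i, i + site_len) if mutable[j]]
                j = span[rng.integers(len(span))]
                seq[j] = str(rng.choice(_BASES))
            text = "".join(seq)
            bad = {i for i in _strict_occurrences(text, enzyme.site)
                   if i not in planted_starts}
            if rc_site is not None:
                bad |= set(_strict_occurrences(text, rc_site))
        if bad:
            continue
        # verify against the digestion module itself
        got = find_sites(text, enzyme, mode="strict")
        if got == cuts:
            return text, protected
    raise InfeasibleConfig(
        f"could not realise fragments {frags} with {enzyme.name} after "
        f"200 attempts")


def _site_windows(frags: list[int], enzyme: RestrictionEnzyme,
                  fwd_len: int, rev_len: int,
                  length: int) -> tuple[list[int], list[tuple[int, int]]]:
    cuts = list(np.cumsum(frags)[:-1])
    windows = []
    for cut in cuts:
        start = cut - enzyme.cut_offset
        if start < fwd_len or start + len(enzyme.site) > length - rev_len:
            raise InfeasibleConfig(
                f"cut at {cut} places the {enzyme.name} site inside a "
                f"primer region")
        windows.append((start, start + len(enzyme.site)))
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if a2 < b1:
            raise InfeasibleConfig(
                f"planted {enzyme.name} sites at {a1} and {a2} overlap")
    return cuts, windows


def _build_shared_masters(patterns: dict[tuple[str, int], list[int]],
                          enzyme: RestrictionEnzyme, fwd: str, rev_rc: str,
                          length: int, rng: np.random.Generator):
    """Masters for all species stamped onto one common background, so
    species differ only within the planted recognition-site windows."""
    geometry = {key: _site_windows(frags, enzyme, len(fwd), len(rev_rc),
                                   length)
                for key, frags in patterns.items()}
    for _attempt in range(200):
        # a background with no site at all = the single-fragment master
        background, _ = _build_master([length], enzyme, fwd, rev_rc,
                                      length, rng)
        masters = {}
        ok = True
        for key, (cuts, windows) in geometry.items():
            seq = list(background)
            for a, b in windows:
                seq[a:b] = _realize(enzyme.site, rng)
            text = "".join(seq)
            if find_sites(text, enzyme, mode="strict") != cuts:
                ok = False  # stamping created a spurious flanking site
                break
            protected = [(0, len(fwd)), (length - len(rev_rc), length),
                         *windows]
            masters[key] = (text, protected)
        if ok:
            return masters
    raise InfeasibleConfig(
        f"could not stamp all planted {enzyme.name} patterns onto a "
        f"shared background after 200 attempts")


def _mutate(master: str, protected: list[tuple[int, int]],
            config: SyntheticConfig,
            rng: np.random.Generator) -> tuple[str, int, int]:
    mutable = np.ones(len(master), dtype=bool)
    for a, b in protected:
        mutable[a:b] = False
    positions = np.flatnonzero(mutable)
    seq = list(master)
    n_subs = 0
    if config.substitution_rate > 0 and positions.size:
        hit = positions[rng.random(positions.size) < config.substitution_rate]
        if config.max_substitutions is not None:
            hit = hit[:config.max_substitutions]
        for p in hit:
            current = seq[p]
            choices = [b for b in "ACGT" if b != current]
            seq[p] = choices[rng.integers(3)]
            n_subs += 1
    n_indels = 0
    if config.indel_rate > 0 and positions.size:
        hit = positions[rng.random(positions.size) < config.indel_rate]
        # apply right-to-left so earlier coordinates stay valid
        for p in sorted(hit, reverse=True):
            if rng.random() < 0.5:
                del seq[p]
            else:
                seq.insert(p, str(rng.choice(_BASES)))
            n_indels += 1
    return "".join(seq), n_subs, n_indels


def make_dataset(config: SyntheticConfig, enzyme: RestrictionEnzyme,
                 pair: PrimerPair,
                 region: str = "16S") -> tuple[list[NucleotideSequence],
                                               list[TruthRow]]:
    """Generate the labelled records and the ground-truth table.

    Deterministic for a fixed config (seed included): the same config yields
    byte-identical FASTA output.
    """
    rng = np.random.default_rng(config.seed)
    fwd = _realize(pair.forward.residues, rng)
    rev_rc = _realize(reverse_complement(pair.reverse.residues), rng)
    min_len = len(fwd) + len(rev_rc) + len(enzyme.site)
    if config.amplicon_length < min_len:
        raise InfeasibleConfig(
            f"amplicon_length {config.amplicon_length} < primers + one "
            f"site ({min_len})")
    masters: dict[tuple[str, int], tuple[str, list[tuple[int, int]]]] = {}
    if config.shared_background:
        wanted = {(sp, pi): list(frags)
                  for sp, patterns in config.planted_patterns.items()
                  for pi, frags in enumerate(patterns)}
        masters = _build_shared_masters(wanted, enzyme, fwd, rev_rc,
                                        config.amplicon_length, rng)
    else:
        for sp, patterns in config.planted_patterns.items():
            for pi, frags in enumerate(patterns):
                masters[(sp, pi)] = _build_master(
                    list(frags), enzyme, fwd, rev_rc,
                    config.amplicon_length, rng)
    records: list[NucleotideSequence] = []
    truth: list[TruthRow] = []
    counter = 0
    for sp, patterns in config.planted_patterns.items():
        for k in range(config.seqs_per_species):
            pi = k % len(patterns)
            master, protected = masters[(sp, pi)]
            seq, n_subs, n_indels = _mutate(master, protected, config, rng)
            counter += 1
            ident = f"syn{counter:04d}"
            records.append(NucleotideSequence(
                id=ident, residues=seq, species=sp, region=region))
            truth.append(TruthRow(
                id=ident, species=sp,
                intended_fragments=tuple(sorted(patterns[pi], reverse=True)),
                n_substitutions=n_subs, n_indels=n_indels))
    return records, truth


def truth_to_tsv(truth: list[TruthRow]) -> str:
    lines = ["id\tspecies\tintended_fragments\tn_substitutions\tn_indels"]
    for row in truth:
        frags = ",".join(map(str, row.intended_fragments))
        lines.append(f"{row.id}\t{row.species}\t{frags}"
                     f"\t{row.n_substitutions}\t{row.n_indels}")
    return "\n".join(lines) + "\n"


def dataset_fasta(records: list[NucleotideSequence]) -> str:
    return format_fasta(records)


# --- random configuration helpers used by the test-bench -------------------

def _gel_bands(frags: list[int], gel: GelModel) -> tuple[int, ...]:
    import math
    visible = sorted(f for f in frags if f >= gel.min_visible)
    if not visible:
        return ()
    bands, cluster = [], [visible[0]]
    for f in visible[1:]:
        if f - cluster[-1] <= gel.co_migration_tol:
            cluster.append(f)
        else:
            bands.append(math.floor(sum(cluster) / len(cluster) + 0.5))
            cluster = [f]
    bands.append(math.floor(sum(cluster) / len(cluster) + 0.5))
    return tuple(sorted(bands, reverse=True))


def _robustly_distinct(a: tuple[int, ...], b: tuple[int, ...],
                       gel: GelModel) -> bool:
    if len(a) != len(b):
        return True
    return any(abs(x - y) > 2 * gel.co_migration_tol + 2
               for x, y in zip(a, b))


def _random_fragments(total: int, n_frags: int, gel: GelModel,
                      rng: np.random.Generator) -> list[int]:
    """Fragments on a coarse grid, all comfortably visible, summing to total."""
    floor = gel.min_visible + 2 * gel.co_migration_tol + 10
    for _ in range(200):
        if n_frags == 1:
            return [total]
        grid = 4 * gel.co_migration_tol  # spacing beats double the tolerance
        cuts = sorted(rng.choice(
            np.arange(floor, total - floor + 1, grid),
            size=n_frags - 1, replace=False)) if total - 2 * floor >= grid \
            else None
        if cuts is None:
            break
        frags = np.diff([0, *cuts, total]).tolist()
        if min(frags) >= floor:
            return [int(f) for f in frags]
    raise InfeasibleConfig(
        f"cannot place {n_frags} visible fragments in {total} bp")


def random_discriminable_config(
        seed: int, n_species: int = 3, seqs_per_species: int = 10,
        amplicon_length: int = 438, max_patterns_per_species: int = 2,
        max_fragments: int = 4, substitution_rate: float = 0.0,
        gel: GelModel = GelModel()) -> SyntheticConfig:
    """Draw a config whose planted patterns are pairwise robustly distinct
    under the gel model, across and within species (rejection sampling)."""
    rng = np.random.default_rng(seed)
    species = [f"species_{chr(ord('A') + i)}" for i in range(n_species)]
    chosen: list[tuple[int, ...]] = []
    patterns: dict[str, list[list[int]]] = {}
    for sp in species:
        n_pat = int(rng.integers(1, max_patterns_per_species + 1))
        patterns[sp] = []
        for _ in range(n_pat):
            for _try in range(500):
                n_frags = int(rng.integers(1, max_fragments + 1))
                frags = _random_fragments(amplicon_length, n_frags, gel, rng)
                bands = _gel_bands(frags, gel)
                if bands and all(_robustly_distinct(bands, prev, gel)
                                 for prev in chosen):
                    chosen.append(bands)
                    patterns[sp].append(frags)
                    break
            else:
                raise InfeasibleConfig("pattern space exhausted")
    return SyntheticConfig(
        planted_patterns=patterns, seqs_per_species=seqs_per_species,
        amplicon_length=amplicon_length,
        substitution_rate=substitution_rate,
        seed=int(np.random.default_rng(seed + 1).integers(2 ** 31)))
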