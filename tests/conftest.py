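"""Shared fixtures and independent oracles.

The oracle implementations here deliberately duplicate domain knowledge in
the plainest possible form (literal IUPAC tables, O(n*m) scans) so they
share no code with the package under test.
"""

import numpy as np
import pytest

import rflpkit as rk

# Independent IUPAC table, written out literally.
ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A",
                     "R": "Y", "Y": "R", "S": "S", "W": "W",
                     "K": "M", "M": "K", "B": "V", "V": "B",
                     "D": "H", "H": "D", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(ORACLE_COMPLEMENT[c] for c in reversed(seq))


def oracle_site_scan(seq: str, site: str, mode: str = "strict") -> list[int]:
    """Positions where the site occurs: naive nested-loop re-scan."""
    hits = []
    for i in range(len(seq) - len(site) + 1):
        ok = True
        for j, s in enumerate(site):
            t = seq[i + j]
            if mode == "strict":
                ok = ORACLE_SETS[t] <= ORACLE_SETS[s]
            else:
                ok = bool(ORACLE_SETS[t] & ORACLE_SETS[s])
            if not ok:
                break
        if ok:
            hits.append(i)
    return hits


def oracle_fragments(seq: str, site: str, cut_offset: int) -> list[int]:
    """Fragment multiset by naive scan on both strands."""
    cuts = set()
    for i in oracle_site_scan(seq, site):
        cuts.add(i + cut_offset)
    rc = oracle_revcomp(site)
    if rc != site:
        for i in oracle_site_scan(seq, rc):
            cuts.add(i + len(site) - cut_offset)
    cuts = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0, *cuts, len(seq)]
    return sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(len(alphabet), size=n)])


def as_amplicon(record: rk.NucleotideSequence) -> rk.Amplicon:
    return rk.Amplicon(source_id=record.id, start=0, end=len(record),
                       residues=record.residues, species=record.species,
                       region=record.region)


@pytest.fixture(scope="session")
def primer_pairs():
    return rk.load_primer_pairs()


@pytest.fixture(scope="session")
def enzyme_library():
    return rk.load_enzymes()


@pytest.fixture(scope="session")
def na16s():
    return rk.load_builtin_key("na16s")


@pytest.fixture
def gel():
    return rk.GelModel()
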