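"""Dichotomous identification keys over RFLP band patterns.

A key is an ordered list of numbered couplets; each couplet offers two leads
(mutually exclusive predicates over the visible band pattern) whose
consequent is either another couplet or a species name.  Keys can be built
automatically from a pattern catalogue (greedy max-min splitting), applied to
observed band lists, pretty-printed in the classic taxonomic-key layout with
dot leaders, and round-tripped through a plain-text canonical format.

Band features come in three families:

* band-count predicates (``count>2``, ``count==2``, ``count<=2``);
* size thresholds on the nth-largest band (``band1>400``, rank 1 = largest);
* approximate-size predicates (``band2~200``: second band within the gel's
  co-migration tolerance of 200 bp), plus negations.

The published North-American 16S/DraI key ships as the built-in ``na16s``
and is usable without any sequence data.
"""

from __future__ import annotations

import importlib.resources
import re
from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, Union

from .errors import (IndistinguishableSpecies, KeyConstructionFailure,
                     KeyParseError)
from .rflp_patterns import GelModel, PatternCatalog, RflpPattern, patterns_equal

_KINDS = ("band_count_gt", "band_count_le", "band_count_eq",
          "nth_band_gt", "nth_band_lt", "nth_band_le",
          "has_band_near", "no_band_near")


@dataclass(frozen=True)
class KeyFeature:
    """One lead predicate.

    ``rank`` is 1-based from the largest band (None for any-band ``~``
    features); ``threshold`` is a band count for count kinds, else bp (the
    target size for ``~`` kinds).  ``tol`` overrides the key's gel tolerance
    for ``~`` kinds when set.
    """

    kind: str
    threshold: int
    rank: int | None = None
    tol: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be >= 1")

    def evaluate(self, bands: tuple[int, ...], default_tol: int) -> bool:
        n = len(bands)
        k = self.kind
        if k == "band_count_gt":
            return n > self.threshold
        if k == "band_count_le":
            return n <= self.threshold
        if k == "band_count_eq":
            return n == self.threshold
        if k in ("nth_band_gt", "nth_band_lt", "nth_band_le"):
            if self.rank is None or n < self.rank:
                return False
            b = bands[self.rank - 1]
            return (b > self.threshold if k == "nth_band_gt"
                    else b < self.threshold if k == "nth_band_lt"
                    else b <= self.threshold)
        tol = self.tol if self.tol is not None else default_tol
        if self.rank is None:
            near = any(abs(b - self.threshold) <= tol for b in bands)
        elif n < self.rank:
            near = False
        else:
            near = abs(bands[self.rank - 1] - self.threshold) <= tol
        return near if k == "has_band_near" else not near

    def complement(self) -> "KeyFeature":
        pairs = {"band_count_gt": "band_count_le",
                 "band_count_le": "band_count_gt",
                 "nth_band_gt": "nth_band_le",
                 "nth_band_le": "nth_band_gt",
                 "has_band_near": "no_band_near",
                 "no_band_near": "has_band_near"}
        if self.kind not in pairs:
            raise ValueError(f"{self.kind} has no simple complement")
        return replace(self, kind=pairs[self.kind])

    def ambiguity(self, bands: tuple[int, ...], default_tol: int) -> str | None:
        """A warning when a band sits within tolerance of a hard threshold."""
        if self.kind in ("nth_band_gt", "nth_band_lt", "nth_band_le") \
                and self.rank is not None and len(bands) >= self.rank:
            b = bands[self.rank - 1]
            if b != self.threshold and abs(b - self.threshold) <= default_tol:
                return (f"band {b} bp is within {default_tol} bp of the "
                        f"{self.threshold} bp threshold")
        return None


Consequent = Union[int, str]  # couplet number or species label


@dataclass(frozen=True)
class KeyLead:
    feature: KeyFeature
    consequent: Consequent


@dataclass(frozen=True)
class KeyCouplet:
    number: int
    lead_a: KeyLead
    lead_b: KeyLead
    back_ref: int | None = None

    @property
    def leads(self) -> tuple[KeyLead, KeyLead]:
        return (self.lead_a, self.lead_b)


@dataclass(frozen=True)
class KeyResult:
    """Outcome of applying a key: the species (or None for undetermined),
    the couplet numbers visited, any near-threshold warnings, and the
    couplet where classification stalled (undetermined only)."""

    species: str | None
    trace: tuple[int, ...]
    warnings: tuple[str, ...] = ()
    stalled_at: int | None = None

    @property
    def determined(self) -> bool:
        return self.species is not None


@dataclass(frozen=True)
class DichotomousKey:
    name: str
    enzyme: str
    region: str
    gel: GelModel
    couplets: tuple[KeyCouplet, ...]

    def __post_init__(self):
        self._validate()

    def couplet(self, number: int) -> KeyCouplet:
        for c in self.couplets:
            if c.number == number:
                return c
        raise KeyError(f"no couplet {number}")

    def species(self) -> set[str]:
        return {lead.consequent for c in self.couplets for lead in c.leads
                if isinstance(lead.consequent, str)}

    def _validate(self) -> None:
        numbers = [c.number for c in self.couplets]
        if not numbers:
            raise ValueError("a key needs at least one couplet")
        if len(set(numbers)) != len(numbers):
            raise ValueError("duplicate couplet numbers")
        known = set(numbers)
        for c in self.couplets:
            for lead in c.leads:
                if isinstance(lead.consequent, int) \
                        and lead.consequent not in known:
                    raise ValueError(
                        f"couplet {c.number} refers to missing couplet "
                        f"{lead.consequent}")
        # every path from couplet 1 must terminate (no cycles) and every
        # couplet must be reachable
        seen: set[int] = set()
        stack: list[int] = []

        def visit(n: int) -> None:
            if n in stack:
                raise ValueError(f"cycle through couplet {n}")
            if n in seen:
                return
            seen.add(n)
            stack.append(n)
            for lead in self.couplet(n).leads:
                if isinstance(lead.consequent, int):
                    visit(lead.consequent)
            stack.pop()

        visit(self.couplets[0].number)
        unreachable = known - seen
        if unreachable:
            raise ValueError(f"unreachable couplets: {sorted(unreachable)}")


# --- applying a key --------------------------------------------------------

def _gel_filter(bands: Iterable[int], gel: GelModel) -> tuple[int, ...]:
    """Visibility + co-migration preprocessing of an observed band list."""
    import math
    visible = sorted(b for b in bands if b >= gel.min_visible)
    if not visible:
        return ()
    merged: list[int] = []
    cluster = [visible[0]]
    for b in visible[1:]:
        if b - cluster[-1] <= gel.co_migration_tol:
            cluster.append(b)
        else:
            merged.append(math.floor(sum(cluster) / len(cluster) + 0.5))
            cluster = [b]
    merged.append(math.floor(sum(cluster) / len(cluster) + 0.5))
    return tuple(sorted(merged, reverse=True))


def apply_key(key: DichotomousKey, bands: Iterable[int]) -> KeyResult:
    """Classify an observed band list.

    Bands are first passed through the key's gel model (sub-visible bands
    dropped, co-migrating bands merged), then couplets are evaluated from
    the first; the first satisfied lead of each couplet is followed.  If
    neither lead holds the result is undetermined at that couplet.
    """
    visible = _gel_filter(bands, key.gel)
    tol = key.gel.co_migration_tol
    trace: list[int] = []
    warnings: list[str] = []
    current = key.couplets[0].number
    while True:
        couplet = key.couplet(current)
        trace.append(current)
        chosen: KeyLead | None = None
        for lead in couplet.leads:
            warn = lead.feature.ambiguity(visible, tol)
            if warn:
                warnings.append(f"couplet {current}: {warn}")
            if chosen is None and lead.feature.evaluate(visible, tol):
                chosen = lead
        if chosen is None:
            return KeyResult(species=None, trace=tuple(trace),
                             warnings=tuple(warnings), stalled_at=current)
        if isinstance(chosen.consequent, str):
            return KeyResult(species=chosen.consequent, trace=tuple(trace),
                             warnings=tuple(warnings))
        current = chosen.consequent


# --- building a key from a catalogue ---------------------------------------

_KIND_PRIORITY = {"band_count_gt": 0, "band_count_le": 0, "band_count_eq": 0,
                  "nth_band_gt": 1, "nth_band_lt": 1, "nth_band_le": 1,
                  "has_band_near": 2, "no_band_near": 2}


def _candidate_features(items: list[tuple[str, tuple[int, ...]]],
                        tol: int) -> list[tuple[KeyFeature, float]]:
    """All usable split features at a node, with their threshold margins."""
    counts = sorted({len(b) for _, b in items})
    feats: list[tuple[KeyFeature, float]] = []
    for c in counts[:-1]:  # splitting at the max count separates nothing
        feats.append((KeyFeature("band_count_gt", threshold=c), float("inf")))
    min_count = min(counts)
    for r in range(1, min_count + 1):
        values = sorted({b[r - 1] for _, b in items})
        for lo, hi in zip(values, values[1:]):
            if hi - lo > 2 * tol:
                feats.append((KeyFeature("nth_band_gt", rank=r,
                                         threshold=(lo + hi) // 2),
                              (hi - lo) / 2))
        for v in values:
            feats.append((KeyFeature("has_band_near", rank=r, threshold=v),
                          float(tol)))
    return feats


def _split(items: list[tuple[str, tuple[int, ...]]], tol: int):
    """Pick the feature maximising the smaller branch; deterministic
    tie-break: band-count first, then smaller rank, then larger margin."""
    best = None
    for feat, margin in _candidate_features(items, tol):
        true_side = [it for it in items if feat.evaluate(it[1], tol)]
        false_side = [it for it in items if not feat.evaluate(it[1], tol)]
        if not true_side or not false_side:
            continue
        score = min(len(true_side), len(false_side))
        rank_key = feat.rank if feat.rank is not None else 0
        key = (-score, _KIND_PRIORITY[feat.kind], rank_key, -margin,
               -feat.threshold)
        if best is None or key < best[0]:
            best = (key, feat, true_side, false_side)
    if best is None:
        raise KeyConstructionFailure(
            f"no feature separates the {len(items)} patterns "
            f"{[b for _, b in items]}")
    return best[1], best[2], best[3]


class _Node:
    def __init__(self, feature=None, species=None):
        self.feature = feature
        self.species = species
        self.true_child: "_Node | None" = None
        self.false_child: "_Node | None" = None


def _grow(items: list[tuple[str, tuple[int, ...]]], tol: int) -> _Node:
    if len(items) == 1:
        return _Node(species=items[0][0])
    try:
        feat, true_side, false_side = _split(items, tol)
    except KeyConstructionFailure:
        species = {sp for sp, _ in items}
        if len(species) == 1:  # indistinct patterns of one species: safe leaf
            return _Node(species=species.pop())
        raise
    node = _Node(feature=feat)
    node.true_child = _grow(true_side, tol)
    node.false_child = _grow(false_side, tol)
    return node


def build_key(catalog: PatternCatalog, gel: GelModel | None = None,
              name: str = "auto") -> DichotomousKey:
    """Construct a key by greedy recursive max-min splitting of the
    catalogue's distinct patterns.

    Raises :class:`IndistinguishableSpecies` if two species share a pattern
    under the gel model, and :class:`KeyConstructionFailure` if the feature
    pool cannot separate some pair of patterns.
    """
    gel = gel or catalog.gel
    items: list[tuple[str, tuple[int, ...]]] = []
    patterns: list[RflpPattern] = []
    for sp, _, entry in catalog.all_entries():
        items.append((sp, entry.pattern.bands))
        patterns.append(entry.pattern)
    if len(items) < 2:
        raise KeyConstructionFailure("need at least two distinct patterns")
    for i, (sp_a, _) in enumerate(items):
        for j in range(i + 1, len(items)):
            sp_b = items[j][0]
            if sp_a != sp_b and patterns_equal(patterns[i], patterns[j], gel):
                raise IndistinguishableSpecies(sp_a, sp_b, items[i][1])

    root = _grow(items, gel.co_migration_tol)

    # breadth-first numbering with back-references
    numbers: dict[int, int] = {id(root): 1}
    order: list[tuple[_Node, int | None]] = []
    queue: deque[tuple[_Node, int | None]] = deque([(root, None)])
    next_number = 1
    while queue:
        node, back = queue.popleft()
        order.append((node, back))
        mine = numbers[id(node)]
        for child in (node.true_child, node.false_child):
            if child is not None and child.species is None:
                next_number += 1
                numbers[id(child)] = next_number
                queue.append((child, mine))

    def consequent(child: _Node) -> Consequent:
        return child.species if child.species is not None \
            else numbers[id(child)]

    couplets = []
    for node, back in order:
        couplets.append(KeyCouplet(
            number=numbers[id(node)], back_ref=back,
            lead_a=KeyLead(node.feature, consequent(node.true_child)),
            lead_b=KeyLead(node.feature.complement(),
                           consequent(node.false_child))))
    return DichotomousKey(name=name, enzyme=catalog.enzyme,
                          region=catalog.region, gel=gel,
                          couplets=tuple(couplets))


# --- serialisation ---------------------------------------------------------

_RANK_NAMES = {1: "Largest", 2: "Middle"}


def _feature_to_canonical(f: KeyFeature) -> str:
    tol = f"@{f.tol}" if f.tol is not None else ""
    if f.kind == "band_count_gt":
        return f"count>{f.threshold}"
    if f.kind == "band_count_le":
        return f"count<={f.threshold}"
    if f.kind == "band_count_eq":
        return f"count=={f.threshold}"
    if f.kind == "nth_band_gt":
        return f"band{f.rank}>{f.threshold}"
    if f.kind == "nth_band_lt":
        return f"band{f.rank}<{f.threshold}"
    if f.kind == "nth_band_le":
        return f"band{f.rank}<={f.threshold}"
    where = "any" if f.rank is None else f"band{f.rank}"
    bang = "!" if f.kind == "no_band_near" else ""
    return f"{bang}{where}~{f.threshold}{tol}"


_CANON_RES = [
    (re.compile(r"^count>(\d+)$"), lambda m: KeyFeature("band_count_gt", int(m[1]))),
    (re.compile(r"^count<=(\d+)$"), lambda m: KeyFeature("band_count_le", int(m[1]))),
    (re.compile(r"^count==(\d+)$"), lambda m: KeyFeature("band_count_eq", int(m[1]))),
    (re.compile(r"^band(\d+)>(\d+)$"),
     lambda m: KeyFeature("nth_band_gt", int(m[2]), rank=int(m[1]))),
    (re.compile(r"^band(\d+)<(\d+)$"),
     lambda m: KeyFeature("nth_band_lt", int(m[2]), rank=int(m[1]))),
    (re.compile(r"^band(\d+)<=(\d+)$"),
     lambda m: KeyFeature("nth_band_le", int(m[2]), rank=int(m[1]))),
    (re.compile(r"^(!?)(any|band(\d+))~(\d+)(?:@(\d+))?$"),
     lambda m: KeyFeature("no_band_near" if m[1] else "has_band_near",
                          int(m[4]), rank=int(m[3]) if m[3] else None,
                          tol=int(m[5]) if m[5] else None)),
]


def _feature_from_canonical(text: str, line_no: int) -> KeyFeature:
    text = text.strip()
    for rx, make in _CANON_RES:
        m = rx.match(text)
        if m:
            return make(m)
    raise KeyParseError(f"unparseable feature {text!r}", line=line_no)


def _rank_phrase(rank: int | None) -> str:
    if rank is None:
        return "A"
    return _RANK_NAMES.get(rank, f"No. {rank}")


def _feature_to_pretty(f: KeyFeature) -> str:
    tol = f" (±{f.tol} bp)" if f.tol is not None else ""
    if f.kind == "band_count_gt":
        return f"More than {f.threshold} bands present"
    if f.kind == "band_count_le":
        return f"At most {f.threshold} bands present"
    if f.kind == "band_count_eq":
        return f"Only {f.threshold} bands present"
    if f.kind == "nth_band_gt":
        return f"{_rank_phrase(f.rank)} band > {f.threshold} bp"
    if f.kind == "nth_band_lt":
        return f"{_rank_phrase(f.rank)} band < {f.threshold} bp"
    if f.kind == "nth_band_le":
        return f"{_rank_phrase(f.rank)} band <= {f.threshold} bp"
    if f.kind == "has_band_near":
        if f.rank is None:
            return f"A band approximately {f.threshold} bp{tol}"
        return (f"{_rank_phrase(f.rank)} band approximately "
                f"{f.threshold} bp{tol}")
    if f.rank is None:
        return f"No band approximately {f.threshold} bp{tol}"
    return (f"{_rank_phrase(f.rank)} band not approximately "
            f"{f.threshold} bp{tol}")


_PRETTY_RES = [
    (re.compile(r"^More than (\d+) bands present$"),
     lambda m: KeyFeature("band_count_gt", int(m[1]))),
    (re.compile(r"^At most (\d+) bands present$"),
     lambda m: KeyFeature("band_count_le", int(m[1]))),
    (re.compile(r"^Only (\d+) bands present$"),
     lambda m: KeyFeature("band_count_eq", int(m[1]))),
    (re.compile(r"^(Largest|Top|Middle|No\. (\d+)) band (>|<|<=) (\d+) bp$"),
     lambda m: KeyFeature({"<": "nth_band_lt", ">": "nth_band_gt",
                           "<=": "nth_band_le"}[m[3]], int(m[4]),
                          rank=_pretty_rank(m[1], m[2]))),
    (re.compile(r"^A band approximately (\d+) bp(?: \(±(\d+) bp\))?$"),
     lambda m: KeyFeature("has_band_near", int(m[1]),
                          tol=int(m[2]) if m[2] else None)),
    (re.compile(r"^(Largest|Top|Middle|No\. (\d+)) band "
                r"(not )?approximately (\d+) bp(?: \(±(\d+) bp\))?$"),
     lambda m: KeyFeature("no_band_near" if m[3] else "has_band_near",
                          int(m[4]), rank=_pretty_rank(m[1], m[2]),
                          tol=int(m[5]) if m[5] else None)),
    (re.compile(r"^No band approximately (\d+) bp(?: \(±(\d+) bp\))?$"),
     lambda m: KeyFeature("no_band_near", int(m[1]),
                          tol=int(m[2]) if m[2] else None)),
]


def _pretty_rank(word: str, num: str | None) -> int:
    if num:
        return int(num)
    return {"Largest": 1, "Top": 1, "Middle": 2}[word]


def _feature_from_pretty(text: str, line_no: int) -> KeyFeature:
    text = text.strip()
    for rx, make in _PRETTY_RES:
        m = rx.match(text)
        if m:
            return make(m)
    raise KeyParseError(f"unparseable lead {text!r}", line=line_no)


def _meta_line(key: DichotomousKey) -> str:
    return (f"# key={key.name} enzyme={key.enzyme} region={key.region} "
            f"min_visible={key.gel.min_visible} tol={key.gel.co_migration_tol}")


def format_key_canonical(key: DichotomousKey) -> str:
    """Machine-readable canonical form: one couplet per line."""
    lines = [_meta_line(key)]
    for c in key.couplets:
        num = f"{c.number}({c.back_ref})" if c.back_ref else str(c.number)
        leads = " | ".join(
            f"{_feature_to_canonical(lead.feature)} -> {lead.consequent}"
            for lead in c.leads)
        lines.append(f"{num} {leads}")
    return "\n".join(lines) + "\n"


def format_key(key: DichotomousKey, width: int = 72) -> str:
    """Paper-style pretty print: numbered couplets with dot leaders."""
    lines = [_meta_line(key)]
    for c in key.couplets:
        num = f"{c.number}({c.back_ref})" if c.back_ref else str(c.number)
        for i, lead in enumerate(c.leads):
            label = num if i == 0 else ""
            text = _feature_to_pretty(lead.feature)
            dots = "." * max(3, width - len(label) - len(text) -
                             len(str(lead.consequent)) - 2)
            lines.append(f"{label}\t{text}{dots} {lead.consequent}")
    return "\n".join(lines) + "\n"


_META_RE = re.compile(
    r"^# key=(\S+) enzyme=(\S*) region=(\S*) min_visible=(\d+) tol=(\d+)$")
_NUM_RE = re.compile(r"^(\d+)(?:\((\d+)\))?$")


def _parse_consequent(text: str) -> Consequent:
    text = text.strip()
    return int(text) if text.isdigit() else text


def parse_key(text: str) -> DichotomousKey:
    """Parse either serialisation (canonical or pretty) back into a key.

    Round-trips: ``parse_key(format_key(k)) == k`` and likewise for the
    canonical form."""
    lines = text.splitlines()
    meta = None
    couplets: list[KeyCouplet] = []
    pending: tuple[int, int | None, KeyLead] | None = None
    for n, raw in enumerate(lines, 1):
        line = raw.rstrip()
        if not line:
            continue
        m = _META_RE.match(line)
        if m:
            meta = m
            continue
        if line.startswith("#"):  # other comment lines are ignored
            continue
        if " -> " in line and " | " in line:  # canonical couplet line
            try:
                num_part, rest = line.split(" ", 1)
                nm = _NUM_RE.match(num_part)
                lead_texts = rest.split(" | ")
                leads = []
                for lt in lead_texts:
                    feat_text, cons_text = lt.rsplit(" -> ", 1)
                    leads.append(KeyLead(
                        _feature_from_canonical(feat_text, n),
                        _parse_consequent(cons_text)))
                if nm is None or len(leads) != 2:
                    raise ValueError
            except (ValueError, KeyParseError) as exc:
                if isinstance(exc, KeyParseError):
                    raise
                raise KeyParseError(f"malformed couplet line {line!r}",
                                    line=n) from None
            couplets.append(KeyCouplet(
                number=int(nm[1]),
                back_ref=int(nm[2]) if nm[2] else None,
                lead_a=leads[0], lead_b=leads[1]))
            continue
        # pretty form: "num\ttext....... consequent" / "\ttext....... cons"
        if "\t" not in line:
            raise KeyParseError(f"malformed line {line!r}", line=n)
        label, body = line.split("\t", 1)
        m2 = re.match(r"^(.*?)\.{3,} (.+)$", body)
        if not m2:
            raise KeyParseError(f"no dot leader in {line!r}", line=n)
        lead = KeyLead(_feature_from_pretty(m2[1], n),
                       _parse_consequent(m2[2]))
        if label:
            nm = _NUM_RE.match(label.strip())
            if not nm:
                raise KeyParseError(f"bad couplet number {label!r}", line=n)
            if pending is not None:
                raise KeyParseError("couplet missing its second lead", line=n)
            pending = (int(nm[1]), int(nm[2]) if nm[2] else None, lead)
        else:
            if pending is None:
                raise KeyParseError("second lead without a first", line=n)
            num, back, lead_a = pending
            couplets.append(KeyCouplet(number=num, back_ref=back,
                                       lead_a=lead_a, lead_b=lead))
            pending = None
    if pending is not None:
        raise KeyParseError("couplet missing its second lead",
                            line=len(lines))
    if not couplets:
        raise KeyParseError("no couplets found", line=0)
    if meta is None:
        name, enzyme, region = "unnamed", "", ""
        gel = GelModel()
    else:
        name, enzyme, region = meta[1], meta[2], meta[3]
        gel = GelModel(min_visible=int(meta[4]),
                       co_migration_tol=int(meta[5]))
    return DichotomousKey(name=name, enzyme=enzyme, region=region, gel=gel,
                          couplets=tuple(couplets))


def load_builtin_key(name: str = "na16s") -> DichotomousKey:
    """Load a bundled key; ``na16s`` is the published North-American
    16S rRNA / DraI key."""
    path = importlib.resources.files("rflpkit.data") / f"{name}.key"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled key named {name!r}") from None
    return parse_key(text)
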