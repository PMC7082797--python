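"""Gel-visible band patterns: resolution model, comparison, grouping, rendering.

A 4% agarose gel resolves small fragments well but still cannot separate
bands within a few base pairs, and very short fragments run off or stain too
faintly to call.  :class:`GelModel` captures both effects with two knobs:
``min_visible`` (fragments below it are dropped) and ``co_migration_tol``
(fragments closer than it merge into one band).

Because tolerance-based equality is not transitive, sequences are grouped
into per-species patterns by leader clustering: each digest joins the first
catalogued pattern it equals, else founds a new one.  Input order is file
order, which makes catalogues reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .digestion import DigestResult
from .errors import EmptyPattern, IncomparablePatterns


@dataclass(frozen=True)
class GelModel:
    """Resolution model for a virtual agarose gel."""

    min_visible: int = 40          # bp; smaller fragments are not called
    co_migration_tol: int = 5      # bp; closer bands merge / compare equal
    percent_agarose: float = 4.0   # metadata only

    def __post_init__(self):
        if self.min_visible < 1:
            raise ValueError("min_visible must be >= 1")
        if self.co_migration_tol < 0:
            raise ValueError("co_migration_tol must be >= 0")


@dataclass(frozen=True)
class RflpPattern:
    """Visible band pattern of one digest: bands sorted descending."""

    bands: tuple[int, ...]
    enzyme: str
    region: str = ""
    species: str | None = None
    source_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if list(self.bands) != sorted(self.bands, reverse=True):
            object.__setattr__(self, "bands",
                               tuple(sorted(self.bands, reverse=True)))


def to_visible_bands(result: DigestResult, gel: GelModel = GelModel(),
                     region: str = "", species: str | None = None) -> RflpPattern:
    """Apply the gel model to a digest: drop invisible fragments, then merge
    co-migrating ones (single linkage) to a single band at the rounded mean.
    """
    visible = sorted(f for f in result.fragments if f >= gel.min_visible)
    if not visible:
        raise EmptyPattern(
            f"all fragments of {result.amplicon_id!r}/{result.enzyme} are "
            f"below {gel.min_visible} bp")
    bands: list[int] = []
    cluster = [visible[0]]
    for f in visible[1:]:
        if f - cluster[-1] <= gel.co_migration_tol:
            cluster.append(f)
        else:
            bands.append(math.floor(sum(cluster) / len(cluster) + 0.5))
            cluster = [f]
    bands.append(math.floor(sum(cluster) / len(cluster) + 0.5))
    return RflpPattern(bands=tuple(sorted(bands, reverse=True)),
                       enzyme=result.enzyme, region=region, species=species,
                       source_ids=(result.amplicon_id,))


def patterns_equal(a: RflpPattern, b: RflpPattern,
                   gel: GelModel = GelModel()) -> bool:
    """Band-for-band equality under the gel's co-migration tolerance.

    Reflexive and symmetric but *not* transitive (tolerances chain), hence
    catalogue grouping uses leader clustering rather than exact partitioning.
    """
    if a.enzyme != b.enzyme or a.region != b.region:
        raise IncomparablePatterns(
            f"cannot compare {a.enzyme}/{a.region or '?'} with "
            f"{b.enzyme}/{b.region or '?'} patterns")
    if len(a.bands) != len(b.bands):
        return False
    return all(abs(x - y) <= gel.co_migration_tol
               for x, y in zip(a.bands, b.bands))


@dataclass
class CatalogEntry:
    pattern: RflpPattern
    members: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def representative(self) -> str:
        return self.members[0]


@dataclass
class PatternCatalog:
    """Distinct band patterns per species under one gel model and enzyme."""

    enzyme: str
    region: str
    gel: GelModel
    by_species: dict[str, list[CatalogEntry]] = field(default_factory=dict)

    def pattern_counts(self) -> dict[str, int]:
        return {sp: len(entries) for sp, entries in self.by_species.items()}

    def totals(self) -> dict[str, int]:
        return {sp: sum(e.n_members for e in entries)
                for sp, entries in self.by_species.items()}

    def all_entries(self) -> list[tuple[str, int, CatalogEntry]]:
        return [(sp, i, e) for sp, entries in sorted(self.by_species.items())
                for i, e in enumerate(entries, 1)]


def group_patterns(labeled: list[tuple[str, DigestResult]],
                   gel: GelModel = GelModel(),
                   region: str = "") -> PatternCatalog:
    """Group digests into unique per-species patterns by leader clustering.

    ``labeled`` is ``[(species, digest), ...]`` from one gene region and one
    enzyme; within each species, a digest joins the first catalogued pattern
    it equals under :func:`patterns_equal`, else founds a new one.
    """
    enzymes = {d.enzyme for _, d in labeled}
    if len(enzymes) > 1:
        raise IncomparablePatterns(
            f"catalogue mixes enzymes {sorted(enzymes)}")
    catalog = PatternCatalog(enzyme=enzymes.pop() if enzymes else "",
                             region=region, gel=gel)
    for species, digest in labeled:
        pattern = to_visible_bands(digest, gel, region=region, species=species)
        entries = catalog.by_species.setdefault(species, [])
        for entry in entries:
            if patterns_equal(entry.pattern, pattern, gel):
                entry.members.append(digest.amplicon_id)
                break
        else:
            entries.append(CatalogEntry(pattern=pattern,
                                        members=[digest.amplicon_id]))
    return catalog


def catalog_to_tsv(catalog: PatternCatalog) -> str:
    lines = [
        f"# enzyme={catalog.enzyme} region={catalog.region} "
        f"min_visible={catalog.gel.min_visible} "
        f"tol={catalog.gel.co_migration_tol}",
        "species\tpattern_index\tbands\tn_members\trepresentative_id",
    ]
    for sp, i, entry in catalog.all_entries():
        bands = ",".join(map(str, entry.pattern.bands))
        lines.append(f"{sp}\t{i}\t{bands}\t{entry.n_members}"
                     f"\t{entry.representative}")
    return "\n".join(lines) + "\n"


_CATALOG_META = re.compile(
    r"^# enzyme=(\S*) region=(\S*) min_visible=(\d+) tol=(\d+)$")


def catalog_from_tsv(text: str) -> PatternCatalog:
    """Inverse of :func:`catalog_to_tsv` (members beyond the representative
    are not recorded in the TSV, so counts collapse to representatives)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty catalogue file")
    meta = _CATALOG_META.match(lines[0])
    if meta:
        enzyme, region = meta[1], meta[2]
        gel = GelModel(min_visible=int(meta[3]), co_migration_tol=int(meta[4]))
        lines = lines[1:]
    else:
        enzyme, region, gel = "", "", GelModel()
    catalog = PatternCatalog(enzyme=enzyme, region=region, gel=gel)
    for ln in lines:
        if ln.startswith("species\t"):
            continue
        sp, _idx, bands, n_members, rep = ln.split("\t")
        pattern = RflpPattern(
            bands=tuple(int(b) for b in bands.split(",")),
            enzyme=enzyme, region=region, species=sp, source_ids=(rep,))
        entry = CatalogEntry(pattern=pattern, members=[rep])
        entry.members += [f"{rep}+{k}" for k in range(1, int(n_members))]
        catalog.by_species.setdefault(sp, []).append(entry)
    return catalog


# --- virtual gel rendering -------------------------------------------------

_DEFAULT_LADDER = (500, 400, 300, 200, 100, 50)


def _migration(bp: int, lo: int, hi: int) -> float:
    """Relative migration in [0, 1]; larger fragments migrate less.

    Position is affine in log10(bp), anchored so ``hi`` maps to 0 (top of
    the gel) and ``lo`` to 1 (the dye front)."""
    span = math.log10(hi) - math.log10(lo)
    return (math.log10(hi) - math.log10(bp)) / span


def render_gel_text(patterns: list[RflpPattern],
                    ladder: tuple[int, ...] = _DEFAULT_LADDER,
                    height: int = 20) -> str:
    """ASCII rendering: one column per lane, ladder lane first."""
    if not patterns:
        raise ValueError("need at least one pattern to render")
    lanes = [sorted(ladder, reverse=True)] + \
            [sorted(p.bands, reverse=True) for p in patterns]
    all_bp = [b for lane in lanes for b in lane]
    lo, hi = min(all_bp), max(all_bp)
    if lo == hi:
        lo = max(1, lo - 1)
    grid = [[" " * 6 for _ in lanes] for _ in range(height)]
    for li, lane in enumerate(lanes):
        for bp in lane:
            row = min(height - 1, int(round(_migration(bp, lo, hi) * (height - 1))))
            grid[row][li] = f"{bp:>5}-" if li == 0 else " ====="
    header = "  ".join(["ladder"] +
                       [f"lane{j}" for j in range(1, len(patterns) + 1)])
    body = "\n".join("  ".join(row) for row in grid)
    return header + "\n" + body + "\n"


def render_gel_svg(patterns: list[RflpPattern],
                   ladder: tuple[int, ...] = _DEFAULT_LADDER,
                   width_per_lane: int = 60, height: int = 400) -> str:
    """Deterministic SVG 1.1 virtual gel: band y-position affine in log10(bp)."""
    if not patterns:
        raise ValueError("need at least one pattern to render")
    lanes: list[tuple[str, list[int]]] = [("ladder", sorted(ladder, reverse=True))]
    for j, p in enumerate(patterns, 1):
        label = p.species or f"lane{j}"
        lanes.append((label, sorted(p.bands, reverse=True)))
    all_bp = [b for _, lane in lanes for b in lane]
    lo, hi = min(all_bp), max(all_bp)
    if lo == hi:
        lo = max(1, lo - 1)
    margin_top, margin_bot = 30, 20
    usable = height - margin_top - margin_bot
    w = width_per_lane * len(lanes) + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{height}">',
        f'<rect x="0" y="0" width="{w}" height="{height}" fill="#202020"/>',
    ]
    for li, (label, lane) in enumerate(lanes):
        x = 10 + li * width_per_lane
        parts.append(
            f'<text x="{x + 20}" y="18" fill="#eeeeee" font-size="10" '
            f'text-anchor="middle">{label}</text>')
        for bp in lane:
            y = margin_top + _migration(bp, lo, hi) * usable
            colour = "#bbbbbb" if li == 0 else "#f0f0f0"
            parts.append(
                f'<rect x="{x}" y="{y:.1f}" width="{width_per_lane - 20}" '
                f'height="3" fill="{colour}"/>')
            if li == 0:
                parts.append(
                    f'<text x="{x + width_per_lane - 16}" y="{y + 4:.1f}" '
                    f'fill="#bbbbbb" font-size="8">{bp}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
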