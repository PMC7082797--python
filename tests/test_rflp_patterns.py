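import numpy as np
import pytest

import rflpkit as rk
from rflpkit.digestion import DigestResult
from rflpkit.rflp_patterns import (GelModel, RflpPattern,
                                   catalog_from_tsv, catalog_to_tsv,
                                   group_patterns, patterns_equal,
                                   render_gel_svg, render_gel_text,
                                   to_visible_bands)


def digest(fragments, ident="d", enzyme="DraI"):
    frags = tuple(sorted(fragments, reverse=True))
    n_cuts = len(frags) - 1
    # synthesise consistent cut positions for the fragment multiset
    cuts = tuple(np.cumsum(sorted(fragments))[:-1]) if n_cuts else ()
    return DigestResult(amplicon_id=ident, enzyme=enzyme, fragments=frags,
                        cut_positions=tuple(int(c) for c in cuts),
                        length=sum(fragments))


def pattern(bands, enzyme="DraI", region="16S", species=None):
    return RflpPattern(bands=tuple(bands), enzyme=enzyme, region=region,
                       species=species)


class TestVisibleBands:
    def test_all_visible_none_comigrate(self):
        assert to_visible_bands(digest([200, 150, 88]),
                                GelModel()).bands == (200, 150, 88)

    def test_invisible_dropped_and_equal_merged(self):
        assert to_visible_bands(digest([100, 100, 38]),
                                GelModel()).bands == (100,)

    def test_single_linkage_merge_at_rounded_mean(self):
        d = digest([160, 158, 60])
        assert to_visible_bands(d, GelModel(co_migration_tol=5)).bands == \
            (159, 60)
        assert to_visible_bands(d, GelModel(co_migration_tol=1)).bands == \
            (160, 158, 60)

    def test_all_invisible_raises(self):
        with pytest.raises(rk.EmptyPattern):
            to_visible_bands(digest([30, 8]), GelModel())


class TestPatternsEqual:
    def test_identity(self, gel):
        assert patterns_equal(pattern([438]), pattern([438]), gel)

    def test_within_tolerance(self):
        a, b = pattern([200, 150, 88]), pattern([203, 149, 86])
        assert patterns_equal(a, b, GelModel(co_migration_tol=5))
        assert not patterns_equal(a, b, GelModel(co_migration_tol=1))

    def test_band_count_mismatch(self, gel):
        assert not patterns_equal(pattern([200, 150]),
                                  pattern([200, 150, 88]), gel)

    def test_enzyme_mismatch_is_incomparable(self, gel):
        with pytest.raises(rk.IncomparablePatterns):
            patterns_equal(pattern([438], enzyme="DraI"),
                           pattern([438], enzyme="AluI"), gel)

    def test_symmetry_not_transitivity(self):
        gel = GelModel(co_migration_tol=5)
        a, b, c = pattern([100]), pattern([104]), pattern([108])
        assert patterns_equal(a, b, gel) == patterns_equal(b, a, gel) is True
        assert patterns_equal(b, c, gel)
        assert not patterns_equal(a, c, gel)  # tolerance does not chain


class TestGroupPatterns:
    def test_single_sequence(self, gel):
        catalog = group_patterns([("H. flava", digest([438]))], gel)
        assert catalog.pattern_counts() == {"H. flava": 1}

    def test_planted_counts_recovered(self, gel):
        labeled = []
        for i in range(10):
            labeled.append(("A", digest([200, 150, 88], f"a{i}")))
            labeled.append(("B", digest([438] if i % 2 else [300, 138],
                                        f"b{i}")))
            labeled.append(("C", digest([250, 188], f"c{i}")))
        catalog = group_patterns(labeled, gel)
        assert catalog.pattern_counts() == {"A": 1, "B": 2, "C": 1}
        assert catalog.totals() == {"A": 10, "B": 10, "C": 10}

    def test_leader_clustering_keeps_first_representative(self, gel):
        labeled = [("X", digest([100], "first")),
                   ("X", digest([104], "joins-first")),
                   ("X", digest([108], "new-leader"))]
        catalog = group_patterns(labeled, gel)
        entries = catalog.by_species["X"]
        assert [e.representative for e in entries] == ["first", "new-leader"]
        assert entries[0].members == ["first", "joins-first"]

    def test_mixed_enzymes_rejected(self, gel):
        with pytest.raises(rk.IncomparablePatterns):
            group_patterns([("A", digest([438], enzyme="DraI")),
                            ("A", digest([438], enzyme="AluI"))], gel)

    def test_tol_zero_partitions_by_exact_multiset(self):
        gel = GelModel(min_visible=1, co_migration_tol=0)
        rng = np.random.default_rng(3)
        multisets = [tuple(sorted(rng.integers(1, 300, size=k),
                                  reverse=True))
                     for k in (1, 2, 2, 3, 4)]
        labeled = [("S", digest(list(ms), f"s{i}-{j}"))
                   for i, ms in enumerate(multisets) for j in range(3)]
        catalog = group_patterns(labeled, gel)
        assert len(catalog.by_species["S"]) == len(set(multisets))

    @pytest.mark.parametrize("seed", range(10))
    def test_pattern_count_nonincreasing_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        labeled = []
        for i in range(30):
            k = rng.integers(1, 5)
            frags = [int(f) for f in rng.integers(40, 400, size=k)]
            labeled.append(("S", digest(frags, f"s{i}")))
        previous = None
        for tol in range(0, 11):
            gel = GelModel(co_migration_tol=tol)
            count = len(group_patterns(labeled, gel).by_species["S"])
            if previous is not None:
                assert count <= previous
            previous = count


class TestCatalogTsv:
    def test_roundtrip_structure(self, gel):
        labeled = [("A", digest([200, 150, 88], "a1")),
                   ("B", digest([438], "b1"))]
        catalog = group_patterns(labeled, gel, region="16S")
        again = catalog_from_tsv(catalog_to_tsv(catalog))
        assert again.enzyme == catalog.enzyme
        assert again.gel == catalog.gel
        assert {sp: [e.pattern.bands for e in entries]
                for sp, entries in again.by_species.items()} == \
            {sp: [e.pattern.bands for e in entries]
             for sp, entries in catalog.by_species.items()}


class TestRenderGel:
    def test_single_band_position_between_ladder_marks(self):
        text = render_gel_text([pattern([438])], ladder=(500, 400, 300, 200, 100))
        rows = text.splitlines()[1:]
        def row_of(token):
            return next(i for i, r in enumerate(rows) if token in r)
        assert row_of(" 500-") <= row_of("=====") <= row_of(" 400-")

    def test_determinism_and_band_order_canonicalization(self):
        a = render_gel_svg([pattern([300, 100])])
        b = render_gel_svg([pattern([100, 300])])
        assert a == b
        # two identical sample lanes render two bands each
        assert render_gel_svg([pattern([300, 100])] * 2).count(
            'fill="#f0f0f0"') == 4

    def test_migration_monotone_in_size(self):
        svg = render_gel_svg([pattern([400, 200, 100])], ladder=(500, 50))
        import re
        ys = [float(m) for m in
              re.findall(r'<rect x="70" y="([\d.]+)"', svg)]
        assert ys == sorted(ys)  # 400 highest, 100 lowest

    def test_empty_lane_list_rejected(self):
        with pytest.raises(ValueError):
            render_gel_text([])
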