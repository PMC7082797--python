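import numpy as np
import pytest

import rflpkit as rk
from rflpkit.key_builder import (KeyFeature, apply_key, build_key, format_key,
                                 format_key_canonical, parse_key)
from rflpkit.rflp_patterns import GelModel, group_patterns

from test_rflp_patterns import digest


def catalog_of(planted, gel=None, n_each=3):
    """planted: list of (species, fragment list); returns a catalogue."""
    gel = gel or GelModel()
    labeled = [(sp, digest(frags, f"{sp}-{i}"))
               for sp, frags in planted for i in range(n_each)]
    return group_patterns(labeled, gel, region="16S")


class TestBuildKey:
    def test_two_pattern_key_uses_largest_band_threshold(self):
        key = build_key(catalog_of([("A", [438]), ("B", [300, 138])]))
        assert len(key.couplets) == 1
        # count split ties with the size split at min-branch 1; band count
        # has priority, but both patterns differ in count AND size; the
        # chosen feature must classify both correctly either way
        assert apply_key(key, [438]).species == "A"
        assert apply_key(key, [300, 138]).species == "B"

    def test_shared_pattern_across_species_rejected(self):
        with pytest.raises(rk.IndistinguishableSpecies) as exc:
            build_key(catalog_of([("H. longicornis", [160, 150, 128]),
                                  ("H. asiatica", [160, 150, 128])]))
        assert {exc.value.species_a, exc.value.species_b} == \
            {"H. longicornis", "H. asiatica"}

    def test_near_identical_patterns_rejected_under_tolerance(self):
        with pytest.raises(rk.IndistinguishableSpecies):
            build_key(catalog_of([("A", [300, 138]), ("B", [302, 136])]))

    def test_breadth_first_numbering_with_back_refs(self):
        key = build_key(catalog_of([
            ("A", [438]), ("B", [300, 138]),
            ("C", [200, 150, 88]), ("D", [100, 90, 80, 88, 80]),
        ]))
        numbers = [c.number for c in key.couplets]
        assert numbers == sorted(numbers)
        assert key.couplets[0].back_ref is None
        for c in key.couplets[1:]:
            assert c.back_ref is not None and c.back_ref < c.number

    def test_multiple_patterns_per_species_each_get_a_leaf(self):
        key = build_key(catalog_of([
            ("H. juxtakochi", [260, 178]), ("H. juxtakochi", [438]),
            ("H. longicornis", [160, 150, 128]),
        ]))
        assert apply_key(key, [260, 178]).species == "H. juxtakochi"
        assert apply_key(key, [438]).species == "H. juxtakochi"
        assert apply_key(key, [160, 150, 128]).species == "H. longicornis"

    @pytest.mark.parametrize("seed", range(30))
    def test_self_consistency_on_random_catalogs(self, seed):
        """Every training pattern classifies back to its own species."""
        gel = GelModel()
        config = rk.random_discriminable_config(seed, n_species=4)
        labeled = [(sp, digest(frags, f"{sp}-{pi}"))
                   for sp, pats in config.planted_patterns.items()
                   for pi, frags in enumerate(pats)]
        catalog = group_patterns(labeled, gel, region="16S")
        key = build_key(catalog)
        for sp, _i, entry in catalog.all_entries():
            result = apply_key(key, list(entry.pattern.bands))
            assert result.species == sp, (sp, entry.pattern.bands)

    def test_robustness_to_small_band_shifts(self):
        """With generous margins, perturbing bands by tol-1 bp leaves every
        classification unchanged."""
        gel = GelModel(co_migration_tol=5)
        planted = [("A", [438]), ("B", [300, 138]),
                   ("C", [250, 188]), ("D", [150, 148, 140])]
        catalog = catalog_of(planted, gel)
        key = build_key(catalog)
        for sp, _i, entry in catalog.all_entries():
            for delta in (-4, 4):
                shifted = [b + delta for b in entry.pattern.bands]
                assert apply_key(key, shifted).species == sp


class TestApplyKey:
    def test_published_leporispalustris_two_band_pattern(self, na16s):
        result = apply_key(na16s, [430, 120])
        assert result.species == "H. leporispalustris"
        assert result.trace == (1, 3)

    def test_published_longicornis_three_band_pattern(self, na16s):
        result = apply_key(na16s, [160, 150, 128])
        assert result.species == "H. longicornis"
        assert result.trace == (1, 2, 5)

    def test_published_chordeilis_and_juxtakochi(self, na16s):
        assert apply_key(na16s, [270, 168]).species == "H. chordeilis"
        assert apply_key(na16s, [260, 178, 120]).species == "H. juxtakochi"
        assert apply_key(na16s, [180, 160, 90]).species == "H. juxtakochi"

    def test_single_visible_band_is_undetermined(self, na16s):
        result = apply_key(na16s, [410, 28])  # 28 bp runs off the gel
        assert result.species is None
        assert result.stalled_at == 1
        assert result.trace == (1,)

    def test_gap_between_couplet3_thresholds_is_undetermined(self, na16s):
        result = apply_key(na16s, [350, 88])  # 300-400 bp two-band gap
        assert result.species is None
        assert result.stalled_at == 3

    def test_near_threshold_ambiguity_warning(self, na16s):
        result = apply_key(na16s, [404, 120])
        assert result.species == "H. leporispalustris"
        assert any("404" in w for w in result.warnings)


class TestFeatureSemantics:
    @pytest.mark.parametrize("feature,bands,expected", [
        (KeyFeature("band_count_gt", 2), (100, 90, 80), True),
        (KeyFeature("band_count_eq", 2), (100, 90), True),
        (KeyFeature("band_count_eq", 2), (100,), False),
        (KeyFeature("nth_band_gt", 200, rank=1), (438,), True),
        (KeyFeature("nth_band_gt", 200, rank=2), (438,), False),  # no band 2
        (KeyFeature("has_band_near", 160, rank=1), (158, 90), True),
        (KeyFeature("has_band_near", 160), (300, 161, 90), True),
        (KeyFeature("no_band_near", 160), (300, 161, 90), False),
    ])
    def test_evaluate(self, feature, bands, expected):
        assert feature.evaluate(bands, default_tol=5) is expected

    def test_complement_is_logical_negation(self):
        rng = np.random.default_rng(0)
        features = [KeyFeature("band_count_gt", 2),
                    KeyFeature("nth_band_gt", 200, rank=1),
                    KeyFeature("has_band_near", 160, rank=2)]
        for feature in features:
            comp = feature.complement()
            for _ in range(200):
                bands = tuple(sorted(
                    (int(b) for b in rng.integers(40, 500,
                                                  rng.integers(1, 5))),
                    reverse=True))
                assert comp.evaluate(bands, 5) == \
                    (not feature.evaluate(bands, 5))


class TestSerialization:
    def test_builtin_key_has_five_couplets(self, na16s):
        assert len(na16s.couplets) == 5
        assert na16s.enzyme == "DraI"
        assert na16s.species() == {"H. leporispalustris", "H. chordeilis",
                                   "H. juxtakochi", "H. longicornis"}

    def test_pretty_and_canonical_roundtrip_builtin(self, na16s):
        assert parse_key(format_key(na16s)) == na16s
        assert parse_key(format_key_canonical(na16s)) == na16s

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_random_keys(self, seed):
        config = rk.random_discriminable_config(seed, n_species=3)
        labeled = [(sp, digest(frags, f"{sp}-{pi}"))
                   for sp, pats in config.planted_patterns.items()
                   for pi, frags in enumerate(pats)]
        key = build_key(group_patterns(labeled, GelModel(), region="16S"))
        assert parse_key(format_key(key)) == key
        assert parse_key(format_key_canonical(key)) == key

    def test_empty_text_raises(self):
        with pytest.raises(rk.KeyParseError):
            parse_key("")

    def test_malformed_couplet_reports_line(self):
        text = ("# key=k enzyme=DraI region=16S min_visible=40 tol=5\n"
                "1 count>2 -> 2 | count==2 -> 3\n"
                "2(1) garbage here\n")
        with pytest.raises(rk.KeyParseError) as exc:
            parse_key(text)
        assert exc.value.line == 3

    def test_cycle_rejected(self):
        text = ("# key=k enzyme=DraI region=16S min_visible=40 tol=5\n"
                "1 count>2 -> 2 | count==2 -> 2\n"
                "2(1) band1>200 -> 1 | band1<200 -> X\n")
        with pytest.raises(ValueError, match="cycle"):
            parse_key(text)

    def test_dangling_reference_rejected(self):
        text = ("# key=k enzyme=DraI region=16S min_visible=40 tol=5\n"
                "1 count>2 -> 9 | count==2 -> X\n")
        with pytest.raises(ValueError, match="missing couplet"):
            parse_key(text)
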