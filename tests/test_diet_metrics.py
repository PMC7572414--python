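import numpy as np
import pandas as pd
import pytest

from pelagidiet.diet_metrics import (BiomassLookup, FishRecord, classify_stage,
                                     composition_summary, compute_sfd,
                                     counts_to_biomass)


class TestStageClassification:
    @pytest.mark.parametrize("species, length, expected", [
        ("anchovy", 10.9, "juvenile"),
        ("anchovy", 11.0, "adult"),     # boundary is adult (strict <)
        ("sardine", 12.9, "juvenile"),
        ("sardine", 13.0, "adult"),
    ])
    def test_thresholds(self, species, length, expected):
        assert classify_stage(species, length) == expected

    def test_unknown_species_and_bad_length(self):
        with pytest.raises(ValueError, match="species"):
            classify_stage("herring", 10.0)
        with pytest.raises(ValueError):
            classify_stage("anchovy", 0.0)

    def test_fish_record_derives_stage(self):
        fr = FishRecord("f1", "sardine", "GSA07", "s1", 42.5, 50.0, 12.0)
        assert fr.stage == "juvenile"
        with pytest.raises(ValueError, match="inconsistent"):
            FishRecord("f2", "sardine", "GSA07", "s1", 42.5, 50.0, 12.0,
                       stage="adult")


@pytest.fixture()
def flat_lookup(toy_gut):
    _, _, groups, weights = toy_gut
    return BiomassLookup.flat(weights, groups)


class TestSFD:
    def _fish(self, length=10.0):
        return FishRecord("f1", "anchovy", "GSA07", "s1", 42.5, 50.0, length)

    def test_empty_stomach_is_zero(self, flat_lookup):
        row = pd.Series({"copepod_sp": 0, "krill_sp": 0, "mollusc_sp": 0})
        assert compute_sfd(row, self._fish(), flat_lookup).sfd == 0.0

    def test_hand_arithmetic(self):
        # 2 prey x 5 mg each / 100 mm = 0.1 mg/mm
        lookup = BiomassLookup.flat({"krill_sp": 5.0})
        row = pd.Series({"krill_sp": 2})
        assert compute_sfd(row, self._fish(10.0), lookup).sfd \
            == pytest.approx(0.1, abs=1e-12)

    def test_invariant_to_taxon_split(self):
        lookup = BiomassLookup.flat({"a": 2.0, "a1": 2.0, "a2": 2.0})
        whole = compute_sfd(pd.Series({"a": 6}), self._fish(), lookup).sfd
        split = compute_sfd(pd.Series({"a1": 4, "a2": 2}), self._fish(),
                            lookup).sfd
        assert whole == pytest.approx(split, abs=1e-12)

    def test_adults_feed_more_than_juveniles_in_synthetic_study(self, study):
        lookup = BiomassLookup.flat(study.biomass_mg.to_dict())
        vals = {"adult": [], "juvenile": []}
        for r in study.fish.itertuples():
            fr = FishRecord(r.fish_id, r.species, r.area, r.site_id,
                            r.latitude, r.depth, r.total_length)
            vals[fr.stage].append(
                compute_sfd(study.gut_counts.loc[r.fish_id], fr, lookup).sfd)
        assert np.mean(vals["adult"]) > np.mean(vals["juvenile"])


class TestBiomassConversion:
    def test_elementwise_product(self):
        lookup = BiomassLookup.flat({"x": 0.005})
        out = counts_to_biomass(pd.DataFrame({"x": [3, 0]}), lookup)
        assert out["x"].tolist() == pytest.approx([0.015, 0.0])

    def test_fallback_chain_resolves_and_logs(self):
        values = {("genus", "Calanus"): 0.07, ("group", "Calanoids"): 0.05}
        ranks = {"Calanus mystery": {"species": "Calanus mystery",
                                     "genus": "Calanus", "group": "Calanoids"},
                 "Unknown calanoid": {"group": "Calanoids"}}
        lookup = BiomassLookup(values, ranks)
        assert lookup.unit_weight("Calanus mystery") == 0.07
        assert lookup.provenance["Calanus mystery"] == "genus"
        assert lookup.unit_weight("Unknown calanoid") == 0.05
        assert lookup.provenance["Unknown calanoid"] == "group"

    def test_unresolvable_taxon_names_offender(self):
        lookup = BiomassLookup.flat({"known": 1.0})
        with pytest.raises(KeyError, match="mystery"):
            lookup.unit_weight("mystery")

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError):
            BiomassLookup.flat({"x": 0.0})


class TestComposition:
    def test_single_fish_percentages(self):
        counts = pd.DataFrame({"cop": [3], "kri": [1]}, index=["f1"])
        fish = pd.DataFrame({"fish_id": ["f1"], "species": ["anchovy"],
                             "area": ["A"], "site_id": ["s1"]})
        groups = {"cop": "Calanoids", "kri": "Euphausiacea"}
        n = composition_summary(counts, fish, groups, level="N")
        vals = n.set_index("group")["pct_N"]
        assert vals["Calanoids"] == pytest.approx(75.0)
        assert vals["Euphausiacea"] == pytest.approx(25.0)
        lookup = BiomassLookup.flat({"cop": 0.005, "kri": 5.0})
        b = composition_summary(counts, fish, groups, level="B",
                                biomass_lookup=lookup)
        assert b.set_index("group")["pct_B"]["Euphausiacea"] \
            == pytest.approx(100 * 5 / 5.015, abs=1e-9)

    def test_fo_fraction_of_fish(self):
        counts = pd.DataFrame({"cop": [1] * 2 + [0] * 8},
                              index=[f"f{i}" for i in range(10)])
        fish = pd.DataFrame({"fish_id": counts.index, "species": "anchovy",
                             "area": "A", "site_id": "s1"})
        fo = composition_summary(counts, fish, {"cop": "Calanoids"}, level="FO")
        assert fo["pct_FO"].iloc[0] == pytest.approx(20.0)

    def test_percentages_sum_to_100_and_permutation_invariance(
            self, toy_gut, flat_lookup, rng):
        counts, fish, groups, _ = toy_gut
        for level, lk in (("N", None), ("B", flat_lookup)):
            out = composition_summary(counts, fish, groups, level=level,
                                      biomass_lookup=lk)
            assert out[f"pct_{level}"].sum() == pytest.approx(100.0, abs=1e-9)
        perm = rng.permutation(counts.index)
        shuffled = composition_summary(counts.loc[perm], fish, groups, level="N")
        base = composition_summary(counts, fish, groups, level="N")
        pd.testing.assert_frame_equal(
            shuffled.sort_values("group").reset_index(drop=True),
            base.sort_values("group").reset_index(drop=True))

    def test_fo_equals_presence_reduction(self, toy_gut):
        counts, fish, groups, _ = toy_gut
        fo_counts = composition_summary(counts, fish, groups, level="FO")
        fo_pres = composition_summary((counts > 0).astype(int), fish, groups,
                                      level="FO")
        pd.testing.assert_frame_equal(fo_counts, fo_pres)

    def test_parasite_taxa_rejected(self, toy_gut):
        counts, fish, _, _ = toy_gut
        groups = {"copepod_sp": "Calanoids", "krill_sp": "parasite",
                  "mollusc_sp": "Mollusca"}
        with pytest.raises(ValueError, match="parasite"):
            composition_summary(counts, fish, groups, level="N")

    def test_empty_stratum_omitted_with_warning(self):
        counts = pd.DataFrame({"cop": [0, 3]}, index=["f1", "f2"])
        fish = pd.DataFrame({"fish_id": ["f1", "f2"], "species": "anchovy",
                             "area": ["empty", "full"], "site_id": "s1"})
        with pytest.warns(UserWarning, match="empty"):
            out = composition_summary(counts, fish, {"cop": "Calanoids"},
                                      level="N")
        assert set(out["area"]) == {"full"}
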