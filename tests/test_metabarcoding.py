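import numpy as np
import pandas as pd
import pytest

from pelagidiet.metabarcoding import (OTUTable, filter_otu_table,
                                      occurrence_summary, read_biom_tsv,
                                      write_biom_tsv)


def make_table(counts: pd.DataFrame, taxonomy=None, marker="COI", hosts=None):
    tax = pd.Series(taxonomy if taxonomy is not None
                    else {o: f"Animalia;Calanoids;sp {o}" for o in counts.index})
    host = pd.Series(hosts if hosts is not None
                     else {s: "anchovy" for s in counts.columns})
    return OTUTable(counts, tax, marker, host)


class TestFilterCascade:
    def test_global_threshold_is_strict(self):
        # dataset total 100,000 reads: 4 reads = 0.004% removed, 5 = 0.005% kept
        counts = pd.DataFrame(
            {"s1": [94991, 0, 0], "s2": [5000, 5, 4]},
            index=["big", "at", "below"]).astype(int)
        filtered, log = filter_otu_table(make_table(counts))
        assert "below" not in filtered.counts.index
        assert "at" in filtered.counts.index
        assert filtered.counts.loc["at", "s2"] == 5  # 5/5005 ~ 0.1% > 0.01%
        assert log.to_frame().iloc[0]["otus_removed"] == 1

    def test_per_sample_threshold_is_strict(self):
        # sample of 10,000 reads: a 1-read cell is exactly 0.01% -> kept
        counts = pd.DataFrame({"s1": [9999, 1]},
                              index=["big", "tiny"]).astype(int)
        filtered, _ = filter_otu_table(make_table(counts))
        assert filtered.counts.loc["tiny", "s1"] == 1
        # but in the 50k sample a 4-read cell (0.008%) is zeroed
        counts2 = pd.DataFrame({"s1": [49_996, 4]}, index=["big", "mt"]).astype(int)
        f2, _ = filter_otu_table(make_table(counts2))
        assert "mt" not in f2.counts.index  # zeroed then dropped as empty

    def test_predator_otus_zeroed_only_in_matching_host(self):
        counts = pd.DataFrame({"anch_s": [10_000, 500], "sard_s": [10_000, 500]},
                              index=["prey", "pred"]).astype(int)
        tax = {"prey": "Animalia;Calanoids;Calanus",
               "pred": "Animalia;Actinopterygii;Engraulis encrasicolus"}
        hosts = {"anch_s": "anchovy", "sard_s": "sardine"}
        filtered, _ = filter_otu_table(make_table(counts, tax, hosts=hosts))
        assert filtered.counts.loc["pred", "anch_s"] == 0
        assert filtered.counts.loc["pred", "sard_s"] == 500

    def test_low_read_sample_drop_is_coi_only(self):
        counts = pd.DataFrame({"ok": [10_000], "low": [15]}, index=["o1"]).astype(int)
        tax = {"o1": "Animalia;Calanoids;Calanus"}
        coi, _ = filter_otu_table(make_table(counts, tax))
        assert list(coi.counts.columns) == ["ok"]
        d_tax = {"o1": "Bacillariophyta;Fam;Genus sp"}
        rbcl, _ = filter_otu_table(make_table(counts, d_tax, marker="rbcL"))
        assert list(rbcl.counts.columns) == ["ok", "low"]

    def test_unassigned_dropped_for_coi_nondiatom_for_rbcl(self):
        counts = pd.DataFrame({"s": [5000, 5000, 5000]},
                              index=["a", "b", "c"]).astype(int)
        tax = {"a": "Animalia;Calanoids;Calanus", "b": "unassigned",
               "c": "Bacillariophyta;Fam;Diatom sp"}
        coi, _ = filter_otu_table(make_table(counts, tax))
        assert set(coi.counts.index) == {"a", "c"}
        rbcl, _ = filter_otu_table(make_table(counts, tax, marker="rbcL"))
        assert set(rbcl.counts.index) == {"c"}

    def test_idempotence(self, study):
        once, _ = filter_otu_table(study.otu_coi)
        twice, _ = filter_otu_table(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_reads_monotone_nonincreasing(self, study):
        filtered, log = filter_otu_table(study.otu_coi)
        assert filtered.total_reads <= study.otu_coi.total_reads
        assert (log.to_frame()[["otus_removed", "samples_removed",
                                "reads_removed"]] >= 0).all().all()

    def test_reordering_commutes_with_filters(self, study, rng):
        base, _ = filter_otu_table(study.otu_coi)
        t = study.otu_coi
        perm_o = rng.permutation(t.counts.index)
        perm_s = rng.permutation(t.counts.columns)
        shuffled = OTUTable(t.counts.loc[perm_o, perm_s], t.taxonomy,
                            t.marker, t.host_species)
        filt, _ = filter_otu_table(shuffled)
        pd.testing.assert_frame_equal(
            filt.counts.sort_index(axis=0).sort_index(axis=1),
            base.counts.sort_index(axis=0).sort_index(axis=1))

    def test_empty_result_returned_not_raised(self):
        counts = pd.DataFrame({"s": [3]}, index=["only"]).astype(int)
        tax = {"only": "unassigned"}
        filtered, log = filter_otu_table(make_table(counts, tax))
        assert filtered.counts.size == 0
        assert len(log.steps) == 5

    def test_negative_threshold_rejected(self, study):
        with pytest.raises(ValueError):
            filter_otu_table(study.otu_coi, global_min_frac=-0.1)

    def test_mistag_sensitivity_on_synthetic_truth(self, study):
        filtered, _ = filter_otu_table(study.otu_coi)
        cells = study.ground_truth.mistag_cells
        removed = sum(
            1 for (o, s, _r) in cells
            if o not in filtered.counts.index or s not in filtered.counts.columns
            or filtered.counts.loc[o, s] == 0)
        assert removed / len(cells) >= 0.95


class TestOccurrence:
    def _meta(self, samples, area="A", species="anchovy"):
        return pd.DataFrame({
            "species": species, "area": area,
            "site_id": ["s1"] * len(samples)}, index=samples)

    def test_simple_percentage(self):
        counts = pd.DataFrame(np.zeros((1, 10), dtype=int),
                              index=["t1"], columns=[f"f{i}" for i in range(10)])
        counts.iloc[0, :2] = 100
        table = make_table(counts)
        occ = occurrence_summary(table, self._meta(counts.columns))
        assert occ.loc[occ.taxon.str.contains("t1"), "FO"].iloc[0] == 20.0

    def test_diatom_percentile_merge_matches_union_oracle(self):
        # occurrences 50, 30, 10, 5, 2 % over 100 samples
        samples = [f"f{i}" for i in range(100)]
        occ_pct = [50, 30, 10, 5, 2]
        counts = pd.DataFrame(0, index=[f"d{i}" for i in range(5)],
                              columns=samples, dtype=int)
        for i, p in enumerate(occ_pct):
            counts.iloc[i, :p] = 100
        tax = {f"d{i}": f"Bacillariophyta;Fam;Species {i}" for i in range(5)}
        table = make_table(counts, tax, marker="rbcL")
        occ = occurrence_summary(table, self._meta(samples),
                                 diatom_percentile=70)
        # brute-force oracle: taxa strictly below the interpolated 70th
        # percentile of the non-zero occurrence vector merge by presence union
        thr = np.percentile(occ_pct, 70)
        merged_taxa = [i for i, p in enumerate(occ_pct) if p < thr]
        union = (counts.iloc[merged_taxa] > 0).any(axis=0).mean() * 100
        row = occ.loc[occ.taxon == "Other diatom groups", "FO"]
        assert len(row) == 1 and row.iloc[0] == pytest.approx(union)
        kept = occ.loc[occ.taxon != "Other diatom groups", "taxon"]
        assert sorted(kept) == [f"Species {i}" for i, p in enumerate(occ_pct)
                                if p >= thr]

    def test_all_zero_taxon_excluded_from_percentile(self):
        samples = [f"f{i}" for i in range(10)]
        counts = pd.DataFrame(0, index=["d0", "dz"], columns=samples, dtype=int)
        counts.iloc[0, :5] = 10
        tax = {"d0": "Bacillariophyta;Fam;Sp zero",
               "dz": "Bacillariophyta;Fam;Sp silent"}
        occ = occurrence_summary(make_table(counts, tax, marker="rbcL"),
                                 self._meta(samples))
        assert occ.loc[occ.taxon == "Sp zero", "FO"].iloc[0] == 50.0

    def test_missing_species_rank_reported_as_diatom_remains(self):
        samples = ["f0", "f1"]
        counts = pd.DataFrame([[5, 5]], index=["d0"], columns=samples).astype(int)
        occ = occurrence_summary(
            make_table(counts, {"d0": "Bacillariophyta;;"}, marker="rbcL"),
            self._meta(samples))
        assert set(occ.taxon) == {"Diatom remains"}


def test_biom_tsv_roundtrip(tmp_path, study):
    p = tmp_path / "otu.tsv"
    write_biom_tsv(study.otu_coi, p)
    back = read_biom_tsv(p, "COI", study.otu_coi.host_species)
    pd.testing.assert_frame_equal(back.counts, study.otu_coi.counts)
    pd.testing.assert_series_equal(back.taxonomy, study.otu_coi.taxonomy,
                                   check_names=False)
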