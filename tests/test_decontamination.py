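from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from preydna.data_model import (
    FilterConfig,
    PreyDnaError,
    ReadMatrix,
    ResolvedTaxon,
    TaxonomyTable,
    TaxonSampleTable,
    ValidationError,
)
from preydna.decontamination import (
    collapse_to_taxa,
    estimate_tag_jump_rate,
    merge_primer_sets,
    negative_control_filter,
    remove_excluded_taxa,
    remove_nontarget,
    replicate_consistency_filter,
    resolve_taxonomy,
    run_cascade,
    tag_jump_filter,
    to_presence,
)
from preydna.synthetic_data import SimConfig, simulate_experiment
from conftest import SMALL_CONFIG
from _utils import make_meta


def _rm(counts, columns, asvs=None, primer="Leray", rep=1):
    asvs = asvs or [f"a{i}" for i in range(len(counts))]
    return ReadMatrix(
        counts=pd.DataFrame(np.asarray(counts, dtype="int64"),
                            index=asvs, columns=columns),
        primer_set=primer, replicate=rep,
    )


def _tst(counts, columns, taxa=None, rank="species", primer="Leray",
         rep=None, phyla=None, mock=()):
    taxa = taxa or [f"Tax {i}" for i in range(len(counts))]
    keys = [f"{rank}:{t}" for t in taxa]
    return TaxonSampleTable(
        counts=pd.DataFrame(np.asarray(counts, dtype="int64"),
                            index=keys, columns=columns),
        taxa={k: ResolvedTaxon(rank=rank, label=t)
              for k, t in zip(keys, taxa)},
        provenance=(primer,),
        replicate=rep,
        taxon_phylum={k: (phyla[i] if phyla else "Arthropoda")
                      for i, k in enumerate(keys)},
        mock_taxa=frozenset(f"{rank}:{t}" for t in mock),
    )


def _tax_table(rows):
    """rows: asv -> (species_conf, genus_conf, family_conf, order_conf[,
    labels dict])."""
    data = {}
    for asv, spec in rows.items():
        sp, ge, fa, od = spec[:4]
        labels = spec[4] if len(spec) > 4 else {}
        data[asv] = {
            "kingdom_label": "Animalia", "phylum_label": "Arthropoda",
            "order_label": labels.get("order", "Diptera"),
            "family_label": labels.get("family", "Fam"),
            "genus_label": labels.get("genus", "Gen"),
            "species_label": labels.get("species", f"Sp {asv}"),
            "kingdom_conf": 1.0, "phylum_conf": 1.0,
            "order_conf": od, "family_conf": fa,
            "genus_conf": ge, "species_conf": sp,
            "is_mock": labels.get("is_mock", False),
        }
    return TaxonomyTable(table=pd.DataFrame.from_dict(data, orient="index"))


class TestNegativeControlFilter:
    META = make_meta([
        ("b1", "negative_control", "NA"), ("b2", "negative_control", "NA"),
        ("s1", "specimen", "female"), ("s2", "specimen", "female"),
        ("s3", "specimen", "male"),
    ])

    def test_max_over_blanks_rule(self):
        m = _rm([[2, 5, 4, 5, 80]], ["b1", "b2", "s1", "s2", "s3"])
        out = negative_control_filter(m, self.META)
        assert out.counts.loc["a0", ["s1", "s2", "s3"]].tolist() == [0, 0, 80]
        # blanks retained untouched
        assert out.counts.loc["a0", ["b1", "b2"]].tolist() == [2, 5]

    def test_all_zero_blanks_is_identity(self):
        m = _rm([[0, 0, 4, 5, 80]], ["b1", "b2", "s1", "s2", "s3"])
        out = negative_control_filter(m, self.META)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_no_negatives_passthrough_with_warning(self):
        meta = make_meta([("s1", "specimen", "female")])
        m = _rm([[3]], ["s1"])
        with pytest.warns(UserWarning, match="no negative controls"):
            out = negative_control_filter(m, meta)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_contaminant_specificity_vs_prey_sensitivity(self):
        # contaminant ASV: present in blanks at similar level to specimens;
        # true prey ASV: abundant in specimens, absent from blanks
        rng = np.random.default_rng(8)
        n_spec = 40
        contam = rng.poisson(5, size=n_spec)
        prey = 50 + rng.poisson(200, size=n_spec)
        counts = np.vstack([
            np.concatenate([[6, 4], contam]),
            np.concatenate([[0, 0], prey]),
        ])
        cols = ["b1", "b2"] + [f"s{i}" for i in range(n_spec)]
        meta = make_meta(
            [("b1", "negative_control", "NA"), ("b2", "negative_control", "NA")]
            + [(f"s{i}", "specimen", "female") for i in range(n_spec)]
        )
        out = negative_control_filter(_rm(counts, cols), meta)
        spec_cols = cols[2:]
        contam_removed = (out.counts.loc["a0", spec_cols] == 0).mean()
        prey_removed = (out.counts.loc["a1", spec_cols] == 0).mean()
        assert contam_removed > 0.5
        assert prey_removed == 0.0
        assert contam_removed > prey_removed


class TestResolveTaxonomy:
    CFG = FilterConfig()

    def test_species_accepted_at_top(self):
        tax = _tax_table({"a0": (0.50, 0.60, 0.70, 0.90)})
        res = resolve_taxonomy(tax, self.CFG)
        assert res["a0"].rank == "species"

    def test_all_thresholds_just_violated_discards(self):
        tax = _tax_table({"a0": (0.44, 0.39, 0.29, 0.19)})
        assert resolve_taxonomy(tax, self.CFG)["a0"] is None

    def test_demotes_to_genus(self):
        tax = _tax_table({"a0": (0.10, 0.45, 0.8, 0.9)})
        r = resolve_taxonomy(tax, self.CFG)["a0"]
        assert (r.rank, r.label) == ("genus", "Gen")

    def test_missing_label_demotes_further(self):
        tax = _tax_table({"a0": (0.50, 0.60, 0.70, 0.90, {"species": ""})})
        r = resolve_taxonomy(tax, self.CFG)["a0"]
        assert r.rank == "genus"

    def test_boundary_equality_accepts(self):
        tax = _tax_table({"a0": (0.45, 0.45, 0.45, 0.45)})
        assert resolve_taxonomy(tax, self.CFG)["a0"].rank == "species"


class TestCollapse:
    def test_sums_same_taxon(self):
        m = _rm([[3], [4]], ["s1"], asvs=["a0", "a1"])
        tax = _tax_table({"a0": (0.9, 0.9, 0.9, 0.9, {"species": "X"}),
                          "a1": (0.9, 0.9, 0.9, 0.9, {"species": "X"})})
        res = resolve_taxonomy(tax, FilterConfig())
        t = collapse_to_taxa(m, res, tax)
        assert t.counts.loc["species:X", "s1"] == 7

    def test_injective_resolution_is_relabeling(self):
        m = _rm([[3, 1], [4, 9]], ["s1", "s2"], asvs=["a0", "a1"])
        tax = _tax_table({"a0": (0.9, 0.9, 0.9, 0.9, {"species": "X"}),
                          "a1": (0.9, 0.9, 0.9, 0.9, {"species": "Y"})})
        t = collapse_to_taxa(m, resolve_taxonomy(tax, FilterConfig()), tax)
        assert sorted(t.counts.to_numpy().ravel()) == sorted(
            m.counts.to_numpy().ravel())

    def test_column_sums_conserved_for_retained(self):
        m = _rm([[3, 1], [4, 9], [5, 5]], ["s1", "s2"],
                asvs=["a0", "a1", "a2"])
        tax = _tax_table({"a0": (0.9, 0.9, 0.9, 0.9, {"species": "X"}),
                          "a1": (0.9, 0.9, 0.9, 0.9, {"species": "X"}),
                          "a2": (0.1, 0.1, 0.1, 0.1)})  # discarded
        t = collapse_to_taxa(m, resolve_taxonomy(tax, FilterConfig()), tax)
        retained = m.counts.loc[["a0", "a1"]].sum(axis=0)
        pd.testing.assert_series_equal(t.counts.sum(axis=0), retained,
                                       check_names=False)


class TestReplicateFilter:
    def test_single_replicate_support_removed(self):
        r1 = _tst([[10]], ["s1"], rep=1)
        r2 = _tst([[0]], ["s1"], rep=2)
        out = replicate_consistency_filter(r1, r2)
        assert out.counts.iloc[0, 0] == 0

    def test_both_positive_summed(self):
        r1 = _tst([[10]], ["s1"], rep=1)
        r2 = _tst([[1]], ["s1"], rep=2)
        assert replicate_consistency_filter(r1, r2).counts.iloc[0, 0] == 11

    def test_identical_replicates_double(self):
        r1 = _tst([[5, 0], [2, 3]], ["s1", "s2"], rep=1)
        r2 = _tst([[5, 0], [2, 3]], ["s1", "s2"], rep=2)
        out = replicate_consistency_filter(r1, r2)
        expected = 2 * r1.counts
        pd.testing.assert_frame_equal(out.counts, expected)

    def test_bad_replicate_labels_error(self):
        r1 = _tst([[1]], ["s1"], rep=1)
        r2 = _tst([[1]], ["s1"], rep=1)
        with pytest.raises(ValidationError, match="replicate labels"):
            replicate_consistency_filter(r1, r2)


class TestRemoveNontarget:
    def test_fungal_removed(self):
        t = _tst([[5], [7]], ["s1"], taxa=["Bug", "Mould"],
                 phyla=["Arthropoda", "Ascomycota"])
        out = remove_nontarget(t, FilterConfig())
        assert list(out.counts.index) == ["species:Bug"]

    def test_all_arthropod_unchanged(self):
        t = _tst([[5], [7]], ["s1"])
        out = remove_nontarget(t, FilterConfig())
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_retained_fraction_bookkeeping(self):
        t = _tst([[90], [10]], ["s1"], taxa=["Bug", "Mould"],
                 phyla=["Arthropoda", "Ascomycota"])
        out = remove_nontarget(t, FilterConfig())
        assert out.total_reads() / t.total_reads() == pytest.approx(0.9)


class TestTagJumpEstimator:
    META = make_meta([("k1", "mock", "NA"), ("s1", "specimen", "female")])

    def test_printed_mock_read_ratio(self):
        # 1,866 stray reads out of 359,600 total mock reads -> 0.52%
        t = _tst([[357_734, 0], [1_866, 50]], ["k1", "s1"],
                 taxa=["MockBug", "Stray"], mock=("MockBug",))
        rate = estimate_tag_jump_rate(t, self.META, t.mock_taxa)
        assert rate == pytest.approx(1_866 / 359_600)
        assert round(100 * rate, 2) == 0.52

    def test_pure_mock_rate_zero(self):
        t = _tst([[100, 0]], ["k1", "s1"], taxa=["MockBug"], mock=("MockBug",))
        assert estimate_tag_jump_rate(t, self.META, t.mock_taxa) == 0.0

    def test_zero_mock_reads_error(self):
        t = _tst([[0, 5]], ["k1", "s1"], taxa=["MockBug"], mock=("MockBug",))
        with pytest.raises(PreyDnaError, match="zero reads"):
            estimate_tag_jump_rate(t, self.META, t.mock_taxa)

    def test_no_mock_sample_error(self):
        t = _tst([[5]], ["s1"])
        with pytest.raises(PreyDnaError, match="no mock sample"):
            estimate_tag_jump_rate(t, self.META, t.mock_taxa)

    def test_recovers_simulated_rate_within_3_sd(self, default_experiment):
        cfg = SimConfig(seed=42)
        tax = default_experiment["taxonomy"]
        meta = default_experiment["meta"]
        mock_asvs = tax.mock_asvs()
        for m in default_experiment["datasets"].values():
            est = estimate_tag_jump_rate(m, meta, mock_asvs)
            total = int(m.counts["MOCK01"].sum())
            sd = np.sqrt(cfg.tag_jump_rate * (1 - cfg.tag_jump_rate) / total)
            assert abs(est - cfg.tag_jump_rate) < 3 * sd

    def test_consistency_improves_with_depth(self):
        errs = []
        for depth in (800, 20_000):
            es = []
            for s in range(3):
                c = SimConfig(n_female=30, n_male=20, n_taxa=40,
                              reads_per_sample=depth, seed=300 + s)
                d, t, m, _ = simulate_experiment(c)
                mock_asvs = t.mock_asvs()
                est = np.mean([estimate_tag_jump_rate(d[k], m, mock_asvs)
                               for k in d])
                es.append(abs(est - c.tag_jump_rate))
            errs.append(np.mean(es))
        assert errs[1] < errs[0]


class TestTagJumpFilter:
    def test_strict_boundary(self):
        t = _tst([[9], [10], [981]], ["s1"], taxa=["A", "B", "C"])
        out = tag_jump_filter(t, 0.01)  # threshold = 10
        assert out.counts["s1"].tolist() == [0, 10, 981]

    def test_rate_zero_identity(self):
        t = _tst([[1, 3], [0, 9]], ["s1", "s2"])
        pd.testing.assert_frame_equal(tag_jump_filter(t, 0.0).counts, t.counts)

    def test_bad_rate(self):
        with pytest.raises(ValidationError):
            tag_jump_filter(_tst([[1]], ["s1"]), 1.5)

    def test_removes_strays_more_than_true_cells(self, default_experiment):
        # ground-truth confusion counts on the simulated merged tables
        truth = default_experiment["truth"]
        tax = default_experiment["taxonomy"]
        meta = default_experiment["meta"]
        cfg = FilterConfig()
        from preydna.decontamination import (collapse_to_taxa,
                                             resolve_taxonomy)
        res = resolve_taxonomy(tax, cfg)
        coll = collapse_to_taxa(default_experiment["datasets"][("Leray", 1)],
                                res, tax)
        spec = list(truth.presence.columns)
        sub = coll.counts.reindex(index=truth.presence.index,
                                  columns=spec, fill_value=0)
        truly = truth.presence.to_numpy().astype(bool)
        present = sub.to_numpy() > 0
        filtered = tag_jump_filter(coll, 0.005)
        sub2 = filtered.counts.reindex(index=truth.presence.index,
                                       columns=spec, fill_value=0)
        removed = present & ~(sub2.to_numpy() > 0)
        stray_cells = present & ~truly
        true_cells = present & truly
        frac_stray = removed[stray_cells].mean()
        frac_true = removed[true_cells].mean()
        assert frac_stray > frac_true


class TestMergeAndExclude:
    def test_union_keeps_single_set_taxon(self):
        a = _tst([[3]], ["s1"], taxa=["OnlyA"], primer="Leray")
        b = _tst([[4]], ["s1"], taxa=["OnlyB"], primer="ANML")
        out = merge_primer_sets(a, b)
        assert out.counts.loc["species:OnlyA", "s1"] == 3
        assert out.counts.loc["species:OnlyB", "s1"] == 4
        assert out.provenance == ("Leray", "ANML")

    def test_identical_tables_doubled(self):
        a = _tst([[3, 0], [1, 2]], ["s1", "s2"])
        b = _tst([[3, 0], [1, 2]], ["s1", "s2"], primer="ANML")
        out = merge_primer_sets(a, b)
        pd.testing.assert_frame_equal(out.counts, 2 * a.counts)

    def test_presence_is_or_of_patterns(self):
        a = _tst([[3, 0]], ["s1", "s2"])
        b = _tst([[0, 2]], ["s1", "s2"], primer="ANML")
        out = merge_primer_sets(a, b)
        assert (out.counts.to_numpy() > 0).tolist() == [[True, True]]

    def test_sample_mismatch_error(self):
        a = _tst([[1]], ["s1"])
        b = _tst([[1]], ["s9"], primer="ANML")
        with pytest.raises(ValidationError, match="different samples"):
            merge_primer_sets(a, b)

    def test_exclusion_taxon_removed(self):
        t = _tst([[5], [9]], ["s1"], taxa=["Arrenurus reflexus", "Prey"])
        out = remove_excluded_taxa(t, FilterConfig())
        assert list(out.counts.index) == ["species:Prey"]

    def test_mock_taxa_removed(self):
        t = _tst([[5], [9]], ["s1"], taxa=["MockBug", "Prey"],
                 mock=("MockBug",))
        out = remove_excluded_taxa(t, FilterConfig())
        assert list(out.counts.index) == ["species:Prey"]

    def test_no_exclusions_identity(self):
        t = _tst([[5], [9]], ["s1"])
        out = remove_excluded_taxa(t, FilterConfig(exclusion_taxa=()))
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_excluding_everything_warns(self):
        t = _tst([[5]], ["s1"], taxa=["Arrenurus reflexus"])
        with pytest.warns(UserWarning, match="all taxa"):
            out = remove_excluded_taxa(t, FilterConfig())
        assert out.counts.shape[0] == 0


class TestToPresence:
    META = make_meta([
        ("s1", "specimen", "female"), ("s2", "specimen", "female"),
        ("s3", "specimen", "male"), ("k1", "mock", "NA"),
    ])

    def test_binarise(self):
        t = _tst([[0, 1, 999]], ["s1", "s2", "s3"])
        pm = to_presence(t, self.META)
        assert pm.values.loc["species:Tax 0"].tolist() == [1, 1]
        assert pm.specimens == ["s2", "s3"]

    def test_idempotent(self):
        t = _tst([[0, 1, 5]], ["s1", "s2", "s3"])
        pm1 = to_presence(t, self.META)
        again = _tst([pm1.values.iloc[0].tolist()], pm1.specimens)
        pm2 = to_presence(again, self.META)
        pd.testing.assert_frame_equal(pm1.values, pm2.values)

    def test_mock_columns_dropped(self):
        t = _tst([[4, 4, 4, 900]], ["s1", "s2", "s3", "k1"])
        pm = to_presence(t, self.META)
        assert "k1" not in pm.specimens

    def test_sample_positive_only_for_excluded_taxon_dropped(self):
        t = _tst([[5, 0], [0, 3]], ["s1", "s2"],
                 taxa=["Arrenurus reflexus", "Prey"])
        out = remove_excluded_taxa(t, FilterConfig())
        pm = to_presence(out, self.META)
        assert pm.specimens == ["s2"]
        assert "s1" in pm.dropped_samples


class TestRunCascade:
    def test_clean_simulation_exact_recovery(self, filter_config):
        cfg = SimConfig(seed=7).clean()
        datasets, tax, meta, truth = simulate_experiment(cfg)
        pm, report = run_cascade(datasets, tax, meta, filter_config)
        rec = pm.values.reindex(index=truth.presence.index,
                                columns=truth.presence.columns, fill_value=0)
        assert (rec.to_numpy() == truth.presence.to_numpy()).all()

    def test_default_simulation_jaccard_pinned(self, default_experiment):
        truth = default_experiment["truth"]
        pm = default_experiment["presence"]
        rec = pm.values.reindex(index=truth.presence.index,
                                columns=truth.presence.columns, fill_value=0)
        a = rec.to_numpy().astype(bool)
        b = truth.presence.to_numpy().astype(bool)
        jaccard = (a & b).sum() / (a | b).sum()
        # regression threshold computed once from this frozen seed (0.993)
        assert jaccard > 0.95

    def test_report_totals_non_increasing_premerge(self, default_experiment):
        report = default_experiment["report"]
        per_key = {}
        for s in report.stages:
            key = (s["primer_set"], s["replicate"])
            if s["stage"] in ("merge_primer_sets", "remove_excluded_taxa",
                              "to_presence"):
                continue
            per_key.setdefault(key, []).append(s["reads_specimens"])
        for key, totals in per_key.items():
            assert all(a >= b for a, b in zip(totals, totals[1:])), key

    def test_tag_jump_rates_reported(self, default_experiment):
        rates = default_experiment["report"].tag_jump_rates
        assert set(rates) == {"Leray", "ANML"}
        assert all(0 <= r < 0.05 for r in rates.values())

    def test_all_zero_matrices_give_empty_presence(self, filter_config):
        cfg = replace(SMALL_CONFIG, seed=3)
        datasets, tax, meta, _ = simulate_experiment(cfg)
        zeroed = {
            k: m.copy_with(m.counts * 0) for k, m in datasets.items()
        }
        with pytest.warns(UserWarning):
            pm, report = run_cascade(zeroed, tax, meta, filter_config)
        assert pm.values.shape[1] == 0

    def test_missing_replicate_errors(self, filter_config):
        datasets, tax, meta, _ = simulate_experiment(SMALL_CONFIG)
        partial = {k: v for k, v in datasets.items() if k != ("Leray", 2)}
        with pytest.raises(ValidationError, match="replicate 2"):
            run_cascade(partial, tax, meta, filter_config)

    def test_filters_are_pointwise_non_increasing(self, default_experiment):
        # spot-check on one dataset: every per-cell count after the negative
        # filter is <= before
        m = default_experiment["datasets"][("Leray", 1)]
        out = negative_control_filter(m, default_experiment["meta"])
        assert (out.counts.to_numpy() <= m.counts.to_numpy()).all()
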