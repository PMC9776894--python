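"""Lipidomics post-processing: quantification, normalization, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lysoquant.lipidomics import (
    LipidTable,
    aggregate_classes,
    differential_lipids,
    double_bond_profile,
    drug_uptake,
    filter_low_abundance,
    lipid_category,
    quantify_absolute,
    to_molpct,
)
from lysoquant.simulate import LipidSimParams, generate_lipidome


def _molpct(table):
    return to_molpct(quantify_absolute(table))


class TestQuantifyAbsolute:
    def test_recovers_true_quantities_exactly(self, small_lipid_table):
        table, true_mol = small_lipid_table
        mol = quantify_absolute(table)
        assert np.allclose(mol.data, true_mol, rtol=1e-12)

    def test_species_equal_to_is_gets_is_amount(self, small_lipid_table):
        table, _ = small_lipid_table
        table.data.loc["PC 34:1"] = table.is_intensity.loc["PC"]
        mol = quantify_absolute(table)
        assert np.allclose(mol.data.loc["PC 34:1"], table.is_amount["PC"])

    def test_zero_intensity_gives_zero_mol(self, small_lipid_table):
        table, _ = small_lipid_table
        table.data.loc["LPC 16:0"] = 0.0
        assert np.allclose(quantify_absolute(table).data.loc["LPC 16:0"], 0.0)

    def test_missing_class_standard_excludes_species(self, small_lipid_table):
        table, _ = small_lipid_table
        table.is_intensity = table.is_intensity.drop("LPC")
        table.is_amount = table.is_amount.drop("LPC")
        mol = quantify_absolute(table)
        assert "LPC 16:0" not in mol.data.index
        assert mol.provenance["unquantified_species"] == ["LPC 16:0"]


class TestToMolpct:
    def test_columns_sum_to_100(self, small_lipid_table):
        table, _ = small_lipid_table
        pct = _molpct(table)
        assert np.allclose(pct.data.sum(axis=0), 100.0, atol=1e-9)

    def test_two_equal_species_split_50_50(self):
        species = pd.DataFrame(
            {"class": ["PC", "PE"], "carbons": [34, 34], "double_bonds": [1, 1]},
            index=["PC 34:1", "PE 34:1"],
        )
        table = LipidTable(
            data=pd.DataFrame({"s1": [3.0, 3.0]}, index=species.index),
            species=species,
            samples=pd.DataFrame({"group": ["a"], "batch": ["b1"], "replicate": [1]},
                                 index=["s1"]),
            unit="mol",
        )
        assert np.allclose(to_molpct(table).data["s1"], [50.0, 50.0])

    def test_zero_sample_rejected_by_name(self):
        species = pd.DataFrame(
            {"class": ["PC"], "carbons": [34], "double_bonds": [1]}, index=["PC 34:1"]
        )
        table = LipidTable(
            data=pd.DataFrame({"bad": [0.0]}, index=species.index),
            species=species,
            samples=pd.DataFrame({"group": ["a"], "batch": ["b1"], "replicate": [1]},
                                 index=["bad"]),
            unit="mol",
        )
        with pytest.raises(ValueError, match="bad"):
            to_molpct(table)


class TestFilterLowAbundance:
    def _table(self, values_by_species, groups=("a", "a", "b", "b")):
        idx = list(values_by_species)
        species = pd.DataFrame(
            {"class": "PC", "carbons": 34, "double_bonds": 1}, index=idx
        )
        cols = [f"s{i}" for i in range(len(groups))]
        data = pd.DataFrame(
            {c: [values_by_species[sp][i] for sp in idx] for i, c in enumerate(cols)},
            index=idx,
        )
        samples = pd.DataFrame(
            {"group": groups, "batch": "b1", "replicate": 1}, index=cols
        )
        return LipidTable(data=data, species=species, samples=samples, unit="mol%")

    def test_below_threshold_everywhere_excluded(self):
        t = self._table({"PC 34:1": [0.00005] * 4, "PC 34:2": [1.0] * 4})
        out, removed = filter_low_abundance(t)
        assert removed == ["PC 34:1"]

    def test_retained_if_any_group_passes(self):
        t = self._table({"PC 34:1": [0.00005, 0.00005, 0.5, 0.5]})
        out, removed = filter_low_abundance(t)
        assert removed == []

    def test_zero_threshold_is_identity(self):
        t = self._table({"PC 34:1": [0.00005] * 4, "PC 34:2": [1.0] * 4})
        out, removed = filter_low_abundance(t, threshold=0.0)
        assert removed == [] and len(out.data) == 2

    def test_idempotent_and_monotone(self):
        t = self._table(
            {"PC 34:1": [5e-5] * 4, "PC 34:2": [5e-4] * 4, "PC 34:3": [1.0] * 4}
        )
        once, removed1 = filter_low_abundance(t, threshold=1e-4)
        twice, removed2 = filter_low_abundance(once, threshold=1e-4)
        assert removed2 == [] and set(once.data.index) == set(twice.data.index)
        stricter, removed3 = filter_low_abundance(t, threshold=1e-3)
        assert set(removed1) <= set(removed3)


class TestDifferentialLipids:
    def test_noiseless_planted_doubling_is_exact(self):
        params = LipidSimParams(
            groups=("vehicle", "UA"),
            planted_effects={"UA": [("SM", 1.0)]},
            noise_cv=0.0,
            batch_log2_sd=0.0,
            n_subthreshold=0,
            seed=5,
        )
        table, truth = generate_lipidome(params)
        res = differential_lipids(_molpct(table), "vehicle", "UA")
        sm = res.loc[table.species["class"] == "SM"]
        # mol% renormalization shifts everything by the same sample factor
        offset = res["log2fc"].drop(sm.index).median()
        assert np.allclose(sm["log2fc"] - offset, 1.0, atol=1e-9)
        assert (sm["pvalue"] < 1e-10).all()

    def test_multiplicative_batch_effect_does_not_bias_log2fc(self):
        # noiseless, balanced: batch factors cancel exactly in the fitted
        # group means
        params = LipidSimParams(
            groups=("vehicle", "UA"),
            planted_effects={"UA": [("SM", 1.0)]},
            noise_cv=0.0,
            batch_log2_sd=1.0,  # batch swings up to ~2x
            n_subthreshold=0,
            seed=6,
        )
        table, _ = generate_lipidome(params)
        mol = quantify_absolute(table)  # absolute scale: no renormalization
        res = differential_lipids(mol, "vehicle", "UA")
        sm = res.loc[table.species["class"] == "SM"]
        rest = res.drop(sm.index)
        assert np.allclose(sm["log2fc"], 1.0, atol=1e-9)
        assert np.allclose(rest["log2fc"], 0.0, atol=1e-9)

    def test_matches_per_species_lstsq_oracle(self):
        params = LipidSimParams(
            groups=("vehicle", "UA"), planted_effects={}, noise_cv=0.15, seed=7,
            classes={"PC": (10, 60.0), "SM": (10, 40.0)}, n_subthreshold=0,
        )
        table, _ = generate_lipidome(params)
        pct = _molpct(table)
        res = differential_lipids(pct, "vehicle", "UA")
        meta = pct.samples
        group = (meta["group"] == "UA").astype(float).to_numpy()
        batches = pd.get_dummies(meta["batch"], drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones(len(meta)), group, batches])
        for sp in pct.data.index:
            y = pct.data.loc[sp, meta.index].to_numpy()
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = X.shape[0] - X.shape[1]
            sigma2 = float(rss[0]) / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            p = 2 * sps.t.sf(abs(t), dof)
            assert res.loc[sp, "t"] == pytest.approx(t, rel=1e-9)
            assert res.loc[sp, "pvalue"] == pytest.approx(p, rel=1e-9)

    def test_rank_deficient_design_rejected(self):
        params = LipidSimParams(
            groups=("vehicle", "UA"), planted_effects={}, n_batches=1,
            noise_cv=0.1, seed=8, n_subthreshold=0,
        )
        table, _ = generate_lipidome(params)
        pct = _molpct(table)
        # make batch coincide with group -> confounded
        pct.samples["batch"] = pct.samples["group"]
        with pytest.raises(ValueError, match="confounded"):
            differential_lipids(pct, "vehicle", "UA")

    def test_too_few_replicates_rejected(self):
        params = LipidSimParams(
            groups=("vehicle", "UA"), planted_effects={}, n_batches=1,
            n_replicates=1, noise_cv=0.1, seed=9, n_subthreshold=0,
        )
        table, _ = generate_lipidome(params)
        with pytest.raises(ValueError, match="replicates"):
            differential_lipids(_molpct(table), "vehicle", "UA")


class TestAggregation:
    def test_class_sum_worked_example(self):
        species = pd.DataFrame(
            {"class": ["SM", "SM", "PC"], "carbons": [34, 36, 34],
             "double_bonds": [1, 1, 1]},
            index=["SM 34:1", "SM 36:1", "PC 34:1"],
        )
        table = LipidTable(
            data=pd.DataFrame({"s1": [1.0, 2.0, 97.0]}, index=species.index),
            species=species,
            samples=pd.DataFrame({"group": ["a"], "batch": ["b1"], "replicate": [1]},
                                 index=["s1"]),
            unit="mol%",
        )
        agg = aggregate_classes(table)
        assert agg.data.loc["SM", "s1"] == pytest.approx(3.0)

    def test_classes_partition_total(self):
        table, _ = generate_lipidome(LipidSimParams(seed=10))
        pct = _molpct(table)
        agg = aggregate_classes(pct)
        assert np.allclose(agg.data.sum(axis=0), 100.0, atol=1e-9)

    def test_lyso_category_equals_brute_force_class_sum(self):
        lyso_classes = ["LPA", "LPC", "LPE", "LPG", "LPI", "LPS", "LPC O-", "LPE O-"]
        assert all(lipid_category(c) == "lysoGPL" for c in lyso_classes)
        table, _ = generate_lipidome(LipidSimParams(seed=10))
        pct = _molpct(table)
        cat = aggregate_classes(pct, level="category")
        brute = pct.data.loc[pct.species["class"].isin(lyso_classes)].sum(axis=0)
        assert np.allclose(cat.data.loc["lysoGPL"], brute, rtol=1e-12)


class TestDoubleBondProfile:
    def _two_species(self):
        species = pd.DataFrame(
            {"class": ["PC", "PC"], "carbons": [34, 34], "double_bonds": [1, 2]},
            index=["PC 34:1", "PC 34:2"],
        )
        return LipidTable(
            data=pd.DataFrame({"s1": [30.0, 30.0]}, index=species.index),
            species=species,
            samples=pd.DataFrame({"group": ["a"], "batch": ["b1"], "replicate": [1]},
                                 index=["s1"]),
            unit="mol%",
        )

    def test_worked_two_species_example(self):
        dist, mean_db = double_bond_profile(self._two_species(), "diacylGPL")
        assert dist["s1"].to_dict() == {1: 50.0, 2: 50.0}
        assert mean_db["s1"] == pytest.approx(1.5)

    def test_single_species_mean(self):
        t = self._two_species()
        t.data.loc["PC 34:1"] = 0.0
        t.species.loc["PC 34:2", "double_bonds"] = 3
        _, mean_db = double_bond_profile(t, "diacylGPL")
        assert mean_db["s1"] == pytest.approx(3.0)

    def test_matches_brute_force_weighted_average(self):
        table, _ = generate_lipidome(LipidSimParams(seed=12))
        pct = _molpct(table)
        dist, mean_db = double_bond_profile(pct, "diacylGPL")
        sel = pct.species["category"] == "diacylGPL"
        for s in pct.data.columns[:6]:
            w = pct.data.loc[sel, s]
            db = pct.species.loc[sel, "double_bonds"]
            assert mean_db[s] == pytest.approx((w * db).sum() / w.sum(), rel=1e-12)
        assert np.allclose(dist.sum(axis=0), 100.0, atol=1e-9)

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError):
            double_bond_profile(self._two_species(), "sterol")


class TestDrugUptake:
    def test_worked_examples(self):
        out = drug_uptake(
            pd.Series({"s1": 500.0}), pd.Series({"s1": 500.0}), 2.0,
            pd.Series({"s1": 1000.0}),
        )
        assert out["s1"] == pytest.approx(2.0 / 1000.0)
        out0 = drug_uptake(
            pd.Series({"s1": 0.0}), pd.Series({"s1": 500.0}), 2.0,
            pd.Series({"s1": 1000.0}),
        )
        assert out0["s1"] == pytest.approx(0.0)

    def test_doubling_lipid_halves_uptake(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(5)]
        drug = pd.Series(rng.uniform(100, 500, 5), index=idx)
        is_int = pd.Series(rng.uniform(400, 600, 5), index=idx)
        total = pd.Series(rng.uniform(500, 1500, 5), index=idx)
        u1 = drug_uptake(drug, is_int, 2.0, total)
        u2 = drug_uptake(drug, is_int, 2.0, 2.0 * total)
        assert np.allclose(u2, u1 / 2.0)


class TestCsvRoundTrip:
    def test_write_read_preserves_everything(self, small_lipid_table, tmp_path):
        table, _ = small_lipid_table
        table.to_csv(tmp_path / "species.csv", tmp_path / "samples.csv")
        back = LipidTable.from_csv(tmp_path / "species.csv", tmp_path / "samples.csv")
        assert np.allclose(back.data, table.data)
        assert list(back.species["class"]) == list(table.species["class"])
        assert np.allclose(back.is_intensity, table.is_intensity)
        assert np.allclose(back.is_amount, table.is_amount)
        assert list(back.samples["group"]) == list(table.samples["group"])
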