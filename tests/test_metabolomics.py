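import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypoxdep.metabolomics import (
    anova_contrasts,
    default_contrasts,
    impute_below_detection,
    normalize_protein,
    relative_log2,
)
from hypoxdep.simulate import MetaboliteTable, SimulationConfig, generate_metabolites


def _table(abundance, detected, genotypes=("control",), replicates=None, protein=None):
    """Build a small MetaboliteTable; columns grouped per genotype x oxygen."""
    abundance = pd.DataFrame(abundance)
    detected = pd.DataFrame(detected, index=abundance.index, columns=abundance.columns)
    n_cols = abundance.shape[1]
    groups = [(g, o) for g in genotypes for o in ("normoxia", "hypoxia")]
    replicates = replicates or n_cols // len(groups)
    rows = []
    for i, col in enumerate(abundance.columns):
        g, o = groups[i // replicates]
        rows.append(
            {"sample_id": col, "genotype": g, "oxygen": o, "replicate": i % replicates + 1}
        )
    samples = pd.DataFrame(rows)
    protein = pd.Series(
        protein if protein is not None else 1.0, index=abundance.columns, name="protein_mass"
    )
    return MetaboliteTable(
        abundance=abundance.where(detected),
        detected=detected,
        samples=samples,
        protein_mass=protein,
    )


class TestImputation:
    def test_fully_undetected_group_gets_global_minimum(self):
        # compound c1's hypoxia group (3 cols) all undetected; global min
        # detected value anywhere in the table is 12.0
        abundance = pd.DataFrame(
            {
                "s1": [50.0, 12.0],
                "s2": [60.0, 13.0],
                "s3": [55.0, 14.0],
                "s4": [np.nan, 20.0],
                "s5": [np.nan, 21.0],
                "s6": [np.nan, 22.0],
            },
            index=["c1", "c2"],
        )
        detected = ~abundance.isna()
        table = _table(abundance, detected, replicates=3)
        out = impute_below_detection(table)
        assert (out.abundance.loc["c1", ["s4", "s5", "s6"]] == 12.0).all()

    def test_partially_detected_group_gets_compound_minimum(self):
        abundance = pd.DataFrame(
            {
                "s1": [50.0, 5.0],
                "s2": [30.0, 6.0],
                "s3": [np.nan, 7.0],
                "s4": [40.0, 8.0],
                "s5": [np.nan, 9.0],
                "s6": [45.0, 10.0],
            },
            index=["c1", "c2"],
        )
        detected = ~abundance.isna()
        table = _table(abundance, detected, replicates=3)
        out = impute_below_detection(table)
        # compound minimum among detected values of c1 is 30.0
        assert out.abundance.loc["c1", "s3"] == 30.0
        assert out.abundance.loc["c1", "s5"] == 30.0

    def test_detected_entries_never_change(self):
        cfg = SimulationConfig(n_compounds=30, seed=12)
        table, _ = generate_metabolites(cfg)
        out = impute_below_detection(table)
        det = table.detected.to_numpy()
        np.testing.assert_array_equal(
            out.abundance.to_numpy()[det], table.abundance.to_numpy()[det]
        )
        assert "imputed" in out.processing

    def test_never_below_global_detected_minimum(self):
        cfg = SimulationConfig(n_compounds=50, seed=13, detection_floor=8.0)
        table, _ = generate_metabolites(cfg)
        out = impute_below_detection(table)
        global_min = np.nanmin(table.abundance.to_numpy()[table.detected.to_numpy()])
        assert np.nanmin(out.abundance.to_numpy()) >= global_min - 1e-12
        assert not out.abundance.isna().any(axis=None)

    def test_entire_table_undetected_rejected(self):
        abundance = pd.DataFrame({"s1": [np.nan], "s2": [np.nan]}, index=["c1"])
        detected = pd.DataFrame(False, index=["c1"], columns=["s1", "s2"])
        table = _table(abundance, detected, replicates=1)
        with pytest.raises(ValueError, match="below detection"):
            impute_below_detection(table)


class TestNormalizeProtein:
    def test_unit_protein_is_identity(self):
        abundance = pd.DataFrame({"s1": [10.0], "s2": [20.0]}, index=["c1"])
        table = _table(abundance, abundance.notna(), replicates=1)
        out = normalize_protein(table)
        pd.testing.assert_frame_equal(out.abundance, table.abundance)

    def test_divides_by_sample_protein(self):
        abundance = pd.DataFrame({"s1": [100.0], "s2": [100.0]}, index=["c1"])
        table = _table(abundance, abundance.notna(), replicates=1, protein=[2.0, 1.0])
        out = normalize_protein(table)
        assert out.abundance.loc["c1", "s1"] == 50.0
        assert out.abundance.loc["c1", "s2"] == 100.0

    def test_nonpositive_protein_rejected(self):
        abundance = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["c1"])
        table = _table(abundance, abundance.notna(), replicates=1, protein=[0.0, 1.0])
        with pytest.raises(ValueError, match="protein"):
            normalize_protein(table)


class TestRelativeLog2:
    def _processed(self):
        abundance = pd.DataFrame(
            {
                "s1": [10.0, 8.0],
                "s2": [10.0, 8.0],
                "s3": [20.0, 2.0],
                "s4": [20.0, 2.0],
            },
            index=["c1", "c2"],
        )
        return _table(abundance, abundance.notna(), replicates=2).copy_with(
            abundance, "imputed"
        )

    def test_reference_column_is_zero_and_ratios_logged(self):
        out = relative_log2(self._processed())
        assert (out["control_normoxia"] == 0).all()
        assert out.loc["c1", "control_hypoxia"] == pytest.approx(1.0)  # doubled
        assert out.loc["c2", "control_hypoxia"] == pytest.approx(-2.0)  # quartered

    def test_requires_imputed_table(self):
        abundance = pd.DataFrame({"s1": [np.nan, 1.0], "s2": [2.0, 1.0]}, index=["c1", "c2"])
        table = _table(abundance, abundance.notna(), replicates=1)
        with pytest.raises(ValueError, match="imputed"):
            relative_log2(table)

    def test_missing_reference_group_rejected(self):
        table = self._processed()
        with pytest.raises(ValueError, match="reference"):
            relative_log2(table, reference=("double_mutant", "normoxia"))


class TestAnovaContrasts:
    def _two_group_table(self, a, b):
        abundance = pd.DataFrame(
            {f"s{i}": [v] for i, v in enumerate(list(a) + list(b))}, index=["c1"]
        )
        return _table(abundance, abundance.notna(), replicates=len(a)).copy_with(
            abundance, "imputed"
        )

    def test_identical_group_means_give_p_one(self):
        table = self._two_group_table([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        out = anova_contrasts(table)
        assert out.loc[0, "anova_F"] == pytest.approx(0.0)
        assert out.loc[0, "anova_p"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_textbook_anova_and_scipy(self):
        # {1,2,3} vs {2,3,4}: SS_between=1.5, SS_within=4, F=1.5 on (1,4) df
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        table = self._two_group_table(np.exp2(a), np.exp2(b))  # anova works on log2
        out = anova_contrasts(table)
        assert out.loc[0, "anova_F"] == pytest.approx(1.5)
        f_ref, p_ref = stats.f_oneway(a, b)
        assert out.loc[0, "anova_F"] == pytest.approx(f_ref)
        assert out.loc[0, "anova_p"] == pytest.approx(p_ref)
        # with two groups the contrast t-test is the pooled two-sample t
        t_ref, tp_ref = stats.ttest_ind(a, b)
        assert out.loc[0, "p_value"] == pytest.approx(tp_ref)

    def test_planted_shift_has_minimum_contrast_p(self):
        cfg = SimulationConfig(
            n_compounds=25,
            seed=14,
            met_fraction_shifted=0.0,
            genotypes=("control",),
            met_cv=0.15,
        )
        table, truth = generate_metabolites(cfg)
        # plant one strongly hypoxia-shifted compound by hand
        h_cols = [
            r["sample_id"]
            for _, r in table.samples.iterrows()
            if r["oxygen"] == "hypoxia"
        ]
        abundance = table.abundance.copy()
        abundance.loc["compound_000", h_cols] *= 8.0
        table = MetaboliteTable(
            abundance=abundance,
            detected=table.detected,
            samples=table.samples,
            protein_mass=table.protein_mass,
        )
        processed = normalize_protein(impute_below_detection(table))
        out = anova_contrasts(processed)
        contrast = out[out["contrast"] == "control_normoxia_vs_control_hypoxia"]
        best = contrast.sort_values("p_value").iloc[0]
        assert best["compound"] == "compound_000"

    def test_q_values_bh_within_contrast(self):
        cfg = SimulationConfig(n_compounds=20, seed=15, genotypes=("control",))
        table, _ = generate_metabolites(cfg)
        processed = normalize_protein(impute_below_detection(table))
        out = anova_contrasts(processed)
        from statsmodels.stats.multitest import multipletests

        for _, grp in out.groupby("contrast"):
            expected = multipletests(grp["p_value"], method="fdr_bh")[1]
            np.testing.assert_allclose(grp["q_value"], expected)

    def test_requires_imputed_table(self):
        cfg = SimulationConfig(n_compounds=10, seed=16)
        table, _ = generate_metabolites(cfg)
        assert table.abundance.isna().any(axis=None)  # censoring present
        with pytest.raises(ValueError, match="imputed"):
            anova_contrasts(table)

    def test_single_replicate_group_rejected(self):
        abundance = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["c1"])
        table = _table(abundance, abundance.notna(), replicates=1).copy_with(
            abundance, "imputed"
        )
        with pytest.raises(ValueError, match="replicates"):
            anova_contrasts(table)

    def test_default_contrasts_cover_design(self):
        cfg = SimulationConfig(n_compounds=5, seed=17)
        table, _ = generate_metabolites(cfg)
        contrasts = default_contrasts(table)
        # one N-vs-H contrast per genotype + control-vs-mutant within oxygen
        assert (("control", "normoxia"), ("control", "hypoxia")) in contrasts
        assert (("control", "hypoxia"), ("hif_mutant", "hypoxia")) in contrasts
        assert len(contrasts) == 4 + 6
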