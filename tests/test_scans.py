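import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from epigx import scans
from epigx.scans import ProximityRule, adjust_pvalues
from epigx.synthdata import SimConfig, simulate_cohort


def _sm_fit(y, cols):
    X = sm.add_constant(np.column_stack([np.asarray(c, float) for c in cols]))
    return sm.OLS(np.asarray(y, float), X, missing="drop").fit()


@pytest.fixture(scope="module")
def cohort(planted_cohort):
    cfg, samples, meth, geno, truth = planted_cohort
    df = samples.included
    target = meth.values[cfg.target_probe_id]
    trow = meth.manifest.set_index("probe_id").loc[cfg.target_probe_id]
    rule = ProximityRule(int(trow["chrom"]), int(trow["pos"]))
    return cfg, samples, meth, geno, df, target, rule


class TestOracleEquivalence:
    """Every scan must reproduce one-at-a-time reference OLS fits."""

    def test_ewas_single_probe(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.ewas_scan(meth, samples).set_index("feature_id")
        probe = meth.probe_ids[3]
        ref = _sm_fit(df["hba1c"], [meth.values[probe].loc[df["sample_id"]],
                                    df["age"], df["sex"], df["bmi"]])
        row = res.loc[probe]
        assert row["coef_meth"] == pytest.approx(ref.params[1], abs=1e-8)
        assert row["focal_p"] == pytest.approx(ref.pvalues[1], abs=1e-8)
        assert row["adj_r2"] == pytest.approx(ref.rsquared_adj, abs=1e-8)

    def test_meqtl_many_snps(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.meqtl_scan(target, geno, samples, rule).set_index("feature_id")
        rng = np.random.default_rng(1)
        for snp in rng.choice(geno.snp_ids, 25, replace=False):
            ref = _sm_fit(target.loc[df["sample_id"]],
                          [geno.dosages[snp].loc[df["sample_id"]], df["age"]])
            row = res.loc[snp]
            assert row["coef_snp"] == pytest.approx(ref.params[1], abs=1e-8)
            assert row["focal_p"] == pytest.approx(ref.pvalues[1], abs=1e-8)
            assert row["adj_r2"] == pytest.approx(ref.rsquared_adj, abs=1e-8)

    def test_gxe_interaction_term(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.gxe_scan(target, geno, samples).set_index("feature_id")
        snp = "snp_00020"
        g = geno.dosages[snp].loc[df["sample_id"]].to_numpy()
        h = df["hba1c"].to_numpy()
        ref = _sm_fit(target.loc[df["sample_id"]].to_numpy(),
                      [g * h, g, h, df["age"].to_numpy()])
        row = res.loc[snp]
        assert row["coef_snp:hba1c"] == pytest.approx(ref.params[1], abs=1e-8)
        assert row["focal_p"] == pytest.approx(ref.pvalues[1], abs=1e-8)

    def test_gxmeth_full_model(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.gxmeth_scan(target, geno, samples).set_index("feature_id")
        snp = "snp_00030"
        g = geno.dosages[snp].loc[df["sample_id"]]
        mt = target.loc[df["sample_id"]]
        ref = _sm_fit(df["hba1c"],
                      [mt * g, g, mt, df["age"], df["sex"], df["bmi"]])
        row = res.loc[snp]
        assert row["coef_meth:snp"] == pytest.approx(ref.params[1], abs=1e-8)
        assert row["focal_p"] == pytest.approx(ref.pvalues[1], abs=1e-8)
        assert row["p_snp"] == pytest.approx(ref.pvalues[2], abs=1e-8)


class TestScanBehaviour:
    def test_planted_target_ranks_first_in_ewas(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.ewas_scan(meth, samples)
        assert res.iloc[0]["feature_id"] == cfg.target_probe_id

    def test_planted_meqtl_and_interactions_detected(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        meqtl = scans.meqtl_scan(target, geno, samples, rule).set_index("feature_id")
        assert meqtl.loc["snp_00010", "focal_p"] < 1e-3
        gxe = scans.gxe_scan(target, geno, samples)
        assert list(gxe["feature_id"]).index("snp_00020") < 5
        gxm = scans.gxmeth_scan(target, geno, samples).set_index("feature_id")
        assert gxm.loc["snp_00030", "bonferroni_p"] < 0.05

    def test_constant_probe_flagged_not_crashing(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        vals = meth.values.copy()
        vals[vals.columns[0]] = 0.5
        from epigx.dataio import MethylationMatrix
        meth2 = MethylationMatrix(vals, meth.manifest)
        res = scans.ewas_scan(meth2, samples).set_index("feature_id")
        row = res.loc[vals.columns[0]]
        assert row["focal_p"] == 1.0 and row["flag"] == "constant focal term"

    def test_output_sorted_by_focal_p(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.meqtl_scan(target, geno, samples, rule)
        p = res["focal_p"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_polymorphic_is_family_restricted_ewas(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        poly = scans.polymorphic_scan(meth, samples)
        flagged = meth.manifest.loc[meth.manifest["polymorphic"], "probe_id"]
        assert set(poly["feature_id"]) == set(flagged)
        full = scans.ewas_scan(meth, samples).set_index("feature_id")
        sub = poly.set_index("feature_id")
        for pid in sub.index:
            assert sub.loc[pid, "focal_p"] == pytest.approx(
                full.loc[pid, "focal_p"], abs=1e-12)
        # q-values recomputed within the restricted family
        np.testing.assert_allclose(
            sub["q_value"].to_numpy(),
            adjust_pvalues(sub["focal_p"].to_numpy(), "bh"),
        )

    def test_no_polymorphic_probes_warns_empty(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        from epigx.dataio import MethylationMatrix
        man = meth.manifest.copy()
        man["polymorphic"] = False
        with pytest.warns(UserWarning):
            out = scans.polymorphic_scan(MethylationMatrix(meth.values, man),
                                         samples)
        assert out.empty

    def test_n_used_reflects_missing_dosages(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        dos = geno.dosages.copy()
        dos.iloc[:10, 0] = np.nan
        from epigx.dataio import GenotypeMatrix
        geno2 = GenotypeMatrix(dos, geno.manifest)
        res = scans.meqtl_scan(target, geno2, samples, rule).set_index("feature_id")
        assert res.loc[dos.columns[0], "n_used"] == len(df) - 10


class TestProximity:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            (1, 145_441_552 + 999_999, "cis"),
            (1, 145_441_552 - 999_999, "cis"),
            (1, 145_441_552 + 1_000_000, "cis"),    # inclusive boundary
            (1, 145_441_552 + 1_000_001, "long_cis"),
            (2, 145_441_552, "trans"),
        ],
    )
    def test_window_classification(self, chrom, pos, expected):
        rule = ProximityRule(1, 145_441_552)
        assert rule.classify(chrom, pos) == expected

    def test_partition_exhaustive_and_exclusive(self, cohort):
        cfg, samples, meth, geno, df, target, rule = cohort
        res = scans.meqtl_scan(target, geno, samples, rule)
        assert set(res["proximity"]) <= {"cis", "long_cis", "trans"}
        assert res["proximity"].notna().all()


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03])

    def test_bonferroni_definition(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.3, 0.4], "bonferroni"), [0.6, 0.8])

    def test_holm_step_down_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.04], "holm"), [0.03, 0.04, 0.04])

    @pytest.mark.parametrize("method", ["bh", "bonferroni", "holm"])
    def test_single_p_unchanged_and_clipping(self, method):
        np.testing.assert_allclose(adjust_pvalues([0.2], method), [0.2])
        assert (adjust_pvalues([0.9, 0.95, 0.99], method) <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "sidak")


def test_manhattan_plot_writes_png(tmp_path, cohort):
    cfg, samples, meth, geno, df, target, rule = cohort
    res = scans.meqtl_scan(target, geno, samples, rule)
    out = tmp_path / "man.png"
    scans.manhattan_plot(res, geno.manifest, out, alpha_line=1e-4)
    assert out.stat().st_size > 0
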