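import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ampliquant import curves, quant


def igi(gene="g", amp=100, e=1.0, ct=25.0):
    return quant.InterGeneInput(gene, amp, e, ct)


class TestPfaffl:
    def test_sample_equal_to_control_mean_gives_one(self):
        inp = quant.PfafflInput(0.93, 0.95, 24.0, 24.0, 20.0, 20.0)
        assert quant.pfaffl_ratio(inp) == 1.0

    def test_three_cycle_shift_with_perfect_doubling_gives_eight(self):
        inp = quant.PfafflInput(1.0, 1.0, 27.0, 24.0, 20.0, 20.0)
        assert quant.pfaffl_ratio(inp) == pytest.approx(8.0, rel=1e-12)

    def test_efficiency_corrected_hand_example(self):
        # 1.9**2 / 2**1 = 1.805
        inp = quant.PfafflInput(0.9, 1.0, 26.0, 24.0, 21.0, 20.0)
        assert quant.pfaffl_ratio(inp) == pytest.approx(1.805, rel=1e-12)

    def test_censored_ct_propagates_as_nan(self):
        inp = quant.PfafflInput(1.0, 1.0, float("nan"), 24.0, 20.0, 20.0)
        assert math.isnan(quant.pfaffl_ratio(inp))

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            quant.PfafflInput(1.5, 1.0, 24.0, 24.0, 20.0, 20.0)


class TestAggregateReplicates:
    def test_mean_over_technical_wells(self):
        tab = pd.DataFrame(
            dict(
                well=["w1", "w2", "w3"],
                gene=["g"] * 3,
                sample_id=["s"] * 3,
                ct_b=[20.0, 21.0, 22.0],
                censored=[False, False, False],
            )
        )
        out = quant.aggregate_replicates(tab)
        assert out.loc[0, "ct"] == pytest.approx(21.0)
        assert out.loc[0, "n_wells"] == 3

    def test_censored_wells_excluded(self):
        tab = pd.DataFrame(
            dict(
                well=["w1", "w2"],
                gene=["g", "g"],
                sample_id=["s", "s"],
                ct_b=[20.0, float("nan")],
                censored=[False, True],
            )
        )
        out = quant.aggregate_replicates(tab)
        assert out.loc[0, "ct"] == pytest.approx(20.0)
        assert out.loc[0, "n_wells"] == 1

    def test_fully_censored_sample_kept_with_missing_ct(self):
        tab = pd.DataFrame(
            dict(
                well=["w1"],
                gene=["g"],
                sample_id=["s"],
                ct_b=[float("nan")],
                censored=[True],
            )
        )
        out = quant.aggregate_replicates(tab)
        assert len(out) == 1 and math.isnan(out.loc[0, "ct"])


class TestNormalizeExpression:
    @pytest.fixture()
    def measurements(self):
        # two genes, two samples; sample s2 has target 2 cycles earlier
        rows = [
            ("tar", "s1", 26.0), ("tar", "s2", 24.0),
            ("Eef1a1", "s1", 20.0), ("Eef1a1", "s2", 20.0),
        ]
        return pd.DataFrame(rows, columns=["gene", "sample_id", "ct"])

    def test_control_sample_ratio_is_one(self, measurements):
        out = quant.normalize_expression(
            measurements, {"tar": 1.0, "Eef1a1": 1.0},
            control_samples=["s1"],
        ).set_index(["gene", "sample_id"])["ratio"]
        assert out[("tar", "s1")] == pytest.approx(1.0)
        assert out[("tar", "s2")] == pytest.approx(4.0)

    def test_housekeeping_as_target_is_one_everywhere(self, measurements):
        out = quant.normalize_expression(
            measurements, {"tar": 1.0, "Eef1a1": 1.0},
            control_samples=["s1"],
        )
        hk = out[out["gene"] == "Eef1a1"]["ratio"]
        np.testing.assert_allclose(hk, 1.0)

    def test_missing_housekeeping_sample_excluded(self, measurements):
        m = measurements.copy()
        m.loc[
            (m["gene"] == "Eef1a1") & (m["sample_id"] == "s2"), "ct"
        ] = float("nan")
        out = quant.normalize_expression(
            m, {"tar": 1.0, "Eef1a1": 1.0}, control_samples=["s1"]
        )
        assert out.attrs["excluded_samples"] == ["s2"]
        assert "s2" not in set(out["sample_id"])

    def test_empty_control_group_rejected(self, measurements):
        with pytest.raises(ValueError, match="control"):
            quant.normalize_expression(
                measurements, {"tar": 1.0, "Eef1a1": 1.0}, control_samples=[]
            )


class TestIntergeneRatio:
    def test_identical_inputs_give_one(self):
        assert quant.intergene_ratio(igi(), igi()) == 1.0

    def test_reduces_to_efficiency_power_of_delta_ct(self):
        x, y = igi(ct=24.0), igi(ct=27.0)
        assert quant.intergene_ratio(x, y) == pytest.approx(8.0, rel=1e-12)

    def test_amplicon_correction_biglycan_decorin(self):
        # equal Ct and efficiency: ratio is the inverse amplicon ratio
        bgn = igi("Bgn", amp=112, ct=25.0)
        dcn = igi("Dcn", amp=81, ct=25.0)
        assert quant.intergene_ratio(bgn, dcn) == pytest.approx(
            81.0 / 112.0, rel=1e-12
        )

    @given(
        e=st.floats(0.5, 1.0),
        ct_x=st.floats(15.0, 35.0),
        ct_y=st.floats(15.0, 35.0),
    )
    def test_equal_amplicon_equal_efficiency_reduction(self, e, ct_x, ct_y):
        x, y = igi(e=e, ct=ct_x), igi(e=e, ct=ct_y)
        expected = (1.0 + e) ** (ct_y - ct_x)
        assert quant.intergene_ratio(x, y) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        amp_x=st.integers(50, 250),
        amp_y=st.integers(50, 250),
        amp_z=st.integers(50, 250),
        e_x=st.floats(0.7, 1.0),
        e_y=st.floats(0.7, 1.0),
        e_z=st.floats(0.7, 1.0),
        ct_x=st.floats(15.0, 35.0),
        ct_y=st.floats(15.0, 35.0),
        ct_z=st.floats(15.0, 35.0),
    )
    def test_reciprocity_and_transitivity(
        self, amp_x, amp_y, amp_z, e_x, e_y, e_z, ct_x, ct_y, ct_z
    ):
        x = igi("x", amp_x, e_x, ct_x)
        y = igi("y", amp_y, e_y, ct_y)
        z = igi("z", amp_z, e_z, ct_z)
        assert quant.intergene_ratio(x, y) * quant.intergene_ratio(
            y, x
        ) == pytest.approx(1.0, rel=1e-12)
        assert quant.intergene_ratio(x, z) == pytest.approx(
            quant.intergene_ratio(x, y) * quant.intergene_ratio(y, z),
            rel=1e-12,
        )

    def test_censored_ct_gives_nan(self):
        assert math.isnan(quant.intergene_ratio(igi(ct=float("nan")), igi()))


class TestRelativeAbundance:
    def test_two_identical_genes_split_evenly(self):
        panel = [igi("a"), igi("b")]
        shares = quant.relative_abundance(panel, quant.GeneSet("s", ("a", "b")))
        np.testing.assert_allclose(shares, [0.5, 0.5])

    def test_single_gene_share_is_one(self):
        shares = quant.relative_abundance([igi("a")], quant.GeneSet("s", ("a",)))
        assert shares["a"] == pytest.approx(1.0)

    def test_known_proportions_recovered(self):
        # T0 proportional to p via Ct = -log2(p) + const (equal amp, E=1)
        props = {"a": 0.6, "b": 0.3, "c": 0.1}
        panel = [igi(g, ct=25.0 - math.log2(p)) for g, p in props.items()]
        shares = quant.relative_abundance(
            panel, quant.GeneSet("s", tuple(props))
        )
        for g, p in props.items():
            assert shares[g] == pytest.approx(p, rel=1e-12)

    def test_shares_sum_to_one_and_anchor_invariant(self):
        panel = [igi("a", 100, 0.9, 24.0), igi("b", 150, 1.0, 28.0),
                 igi("c", 81, 0.85, 30.0)]
        gs = quant.GeneSet("s", ("a", "b", "c"))
        for anchor in ("a", "b", "c"):
            shares = quant.relative_abundance(panel, gs, anchor=anchor)
            assert shares.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(
                shares, quant.relative_abundance(panel, gs), rtol=1e-12
            )

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            quant.relative_abundance([igi("a")], quant.GeneSet("s", ("a", "b")))


class TestEcmMmpRatio:
    def test_identical_sets_give_one(self):
        panel = [igi("a"), igi("b", amp=150, ct=27.0)]
        gs = quant.GeneSet("both", ("a", "b"))
        assert quant.ecm_mmp_ratio(panel, gs, gs) == pytest.approx(1.0)

    def test_doubling_numerator_set_doubles_ratio(self):
        ecm = quant.GeneSet("ecm", ("a", "b"))
        mmp = quant.GeneSet("mmp", ("c",))
        panel = [igi("a", ct=24.0), igi("b", ct=26.0), igi("c", ct=25.0)]
        r1 = quant.ecm_mmp_ratio(panel, ecm, mmp)
        # one cycle earlier at E=1 doubles every ECM gene's T0
        panel2 = [igi("a", ct=23.0), igi("b", ct=25.0), igi("c", ct=25.0)]
        r2 = quant.ecm_mmp_ratio(panel2, ecm, mmp)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_default_sets_match_study_panel(self, primer_records):
        panel_genes = {r.gene for r in primer_records}
        assert set(quant.ECM.members) <= panel_genes
        assert set(quant.MMPS.members) <= panel_genes
        assert set(quant.ECM.members) == (
            set(quant.COLLAGENS.members)
            | {"Fn1"}
            | set(quant.PROTEOGLYCANS.members)
        )


class TestTimecourseNormalize:
    @pytest.fixture()
    def group_values(self):
        return pd.DataFrame(
            dict(
                gene=["g"] * 3,
                treatment_ng_per_ml=[0.0] * 3,
                timepoint_h=[0.0, 24.0, 48.0],
                share=[0.2, 0.4, 0.1],
            )
        )

    def test_reference_timepoint_maps_to_one(self, group_values):
        out = quant.timecourse_normalize(group_values)
        assert out.loc[out["timepoint_h"] == 0, "share_vs_0h"].iloc[0] == 1.0

    def test_doubling_vs_reference(self, group_values):
        out = quant.timecourse_normalize(group_values)
        assert out.loc[out["timepoint_h"] == 24, "share_vs_0h"].iloc[
            0
        ] == pytest.approx(2.0)

    def test_missing_reference_rejected(self, group_values):
        with pytest.raises(ValueError, match="reference"):
            quant.timecourse_normalize(
                group_values[group_values["timepoint_h"] > 0]
            )


@pytest.fixture(scope="module")
def processed(mini_study, mini_well_table):
    design, _, sheet, truth = mini_study
    eff = curves.summarize_gene_efficiency(mini_well_table)
    meas = quant.aggregate_replicates(mini_well_table)
    return design, sheet, truth, eff, meas


class TestEndToEndMiniStudy:
    """Noiseless study without biological noise: exact parameter recovery."""

    def test_gene_efficiencies_recovered(self, processed):
        design, _, truth, eff, _ = processed
        merged = eff.merge(truth.per_gene, on="gene")
        np.testing.assert_allclose(merged["efficiency"], merged["e0"], atol=1e-9)

    def test_fold_changes_match_effect_table(self, processed):
        design, sheet, _, eff, meas = processed
        control = sheet.loc[sheet["timepoint_h"] == 0, "sample_id"].unique()
        ratios = quant.normalize_expression(
            meas, eff, control_samples=list(control)
        )
        for r in ratios.itertuples():
            expected = design.effect(
                r.gene, r.treatment_ng_per_ml, r.timepoint_h
            )
            assert r.ratio == pytest.approx(expected, rel=1e-9)

    def test_intergene_ratios_match_truth(self, processed):
        design, _, truth, eff, meas = processed
        amplicons = {g.symbol: g.amplicon_len for g in design.genes}
        ab = quant.sample_abundance_table(meas, eff, amplicons)
        wide = ab.pivot_table(
            index="sample_id", columns="gene", values="rel_t0"
        )
        tw = truth.per_sample.pivot_table(
            index="sample_id", columns="gene", values="t0"
        )
        est = wide["Scx"] / wide["Eef1a1"]
        tru = tw["Scx"] / tw["Eef1a1"]
        np.testing.assert_allclose(est, tru, rtol=1e-9)
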