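"""Charge collapsing, form compositions, variant proportions, mark marks."""

import numpy as np
import pandas as pd
import pytest

from histoptm import quantify as q
from histoptm.errors import InvalidDataError, SchemaError, UndefinedRatioError


def area_df(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "peptide_sequence", "modifications", "charge", "area"]
    )


class TestCollapseChargeStates:
    def test_sums_across_charges(self):
        t = area_df([("s1", "PEPR", "", 2, 100.0), ("s1", "PEPR", "", 3, 50.0)])
        out = q.collapse_charge_states(t)
        assert len(out) == 1 and out["area"].iloc[0] == 150.0

    def test_single_charge_identity(self):
        t = area_df([("s1", "PEPR", "K1ac", 2, 42.0)])
        out = q.collapse_charge_states(t)
        assert out["area"].iloc[0] == 42.0 and out["form_id"].iloc[0] == "K1ac"

    def test_missing_plus_observed_is_observed(self):
        t = area_df([("s1", "PEPR", "", 2, np.nan), ("s1", "PEPR", "", 3, 50.0)])
        out = q.collapse_charge_states(t)
        assert out["area"].iloc[0] == 50.0

    def test_all_missing_stays_missing(self):
        t = area_df([("s1", "PEPR", "", 2, np.nan), ("s1", "PEPR", "", 3, np.nan)])
        out = q.collapse_charge_states(t)
        assert np.isnan(out["area"].iloc[0])

    def test_negative_area_rejected(self):
        with pytest.raises(InvalidDataError):
            q.collapse_charge_states(area_df([("s1", "PEPR", "", 2, -1.0)]))

    def test_form_id_token_order_canonicalized(self):
        t = area_df(
            [("s1", "PEPR", "K12ac;K8ac", 2, 10.0), ("s1", "PEPR", "K8ac;K12ac", 3, 5.0)]
        )
        out = q.collapse_charge_states(t)
        assert len(out) == 1 and out["form_id"].iloc[0] == "K8ac;K12ac"


@pytest.fixture()
def region_table(peptide_map_bundle):
    pmap, _, _ = peptide_map_bundle
    seq = "KSAPATGGVKKPHR"
    t = area_df(
        [
            ("s1", seq, "", 2, 50.0),
            ("s1", seq, "K27me1", 2, 850.0),
            ("s1", seq, "K27me2", 2, 100.0),
        ]
    )
    return q.collapse_charge_states(t), pmap


class TestFormRelativeAbundance:
    def test_normalization_to_percent(self, region_table):
        collapsed, pmap = region_table
        forms = q.form_relative_abundance(collapsed, pmap)
        got = forms.set_index("form_id")["percent"]
        assert got["unmodified"] == pytest.approx(5.0)
        assert got["K27me1"] == pytest.approx(85.0)
        assert got["K27me2"] == pytest.approx(10.0)

    def test_single_form_is_100(self, peptide_map_bundle):
        pmap, _, _ = peptide_map_bundle
        collapsed = q.collapse_charge_states(
            area_df([("s1", "KSAPATGGVKKPHR", "", 2, 7.0)])
        )
        forms = q.form_relative_abundance(collapsed, pmap)
        assert forms["percent"].iloc[0] == pytest.approx(100.0)

    def test_missing_form_stays_missing(self, peptide_map_bundle):
        pmap, _, _ = peptide_map_bundle
        collapsed = q.collapse_charge_states(
            area_df(
                [
                    ("s1", "KSAPATGGVKKPHR", "", 2, 75.0),
                    ("s1", "KSAPATGGVKKPHR", "K27me1", 2, np.nan),
                    ("s1", "KSAPATGGVKKPHR", "K27me2", 2, 25.0),
                ]
            )
        )
        forms = q.form_relative_abundance(collapsed, pmap)
        got = forms.set_index("form_id")["percent"]
        assert np.isnan(got["K27me1"])
        # observed forms close to 100 without the missing one
        assert got["unmodified"] + got["K27me2"] == pytest.approx(100.0)

    def test_unknown_sequence_rejected(self, peptide_map_bundle):
        pmap, _, _ = peptide_map_bundle
        collapsed = q.collapse_charge_states(area_df([("s1", "NOTAPEPTIDEK", "", 2, 1.0)]))
        with pytest.raises(SchemaError):
            q.form_relative_abundance(collapsed, pmap)

    def test_permutation_invariance(self, peptide_map_bundle):
        pmap, _, _ = peptide_map_bundle
        rows = [
            ("s1", "KSAPATGGVKKPHR", "", 2, 50.0),
            ("s1", "KSAPATGGVKKPHR", "K27me1", 2, 850.0),
            ("s1", "KSAPATGGVKKPHR", "K27me2", 2, 100.0),
        ]
        a = q.form_relative_abundance(q.collapse_charge_states(area_df(rows)), pmap)
        b = q.form_relative_abundance(
            q.collapse_charge_states(area_df(rows[::-1])), pmap
        )
        key = ["sample_id", "form_id"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


class TestVariantProportions:
    def test_forced_by_construction(self, peptide_map_bundle, family_of_group):
        pmap, _, _ = peptide_map_bundle
        from histoptm.synthetic_data import VARIANT_REGION_PEPTIDE as V

        collapsed = q.collapse_charge_states(
            area_df(
                [
                    ("s1", V["H2A.Z.9"], "", 2, 670.0),
                    ("s1", V["H2A.Z.8"], "", 2, 70.0),
                    ("s1", V["H2A.Z.11"], "", 2, 260.0),
                ]
            )
        )
        props = q.variant_proportions(collapsed, pmap, family_of_group, "H2A.Z")
        got = props.set_index("variant")["percent"]
        assert got["H2A.Z.9"] == pytest.approx(67.0)
        assert got["H2A.Z.8"] == pytest.approx(7.0)
        assert got["H2A.Z.11"] == pytest.approx(26.0)

    def test_modification_states_summed_before_mean(
        self, peptide_map_bundle, family_of_group
    ):
        pmap, _, _ = peptide_map_bundle
        from histoptm.synthetic_data import VARIANT_REGION_PEPTIDE as V

        collapsed = q.collapse_charge_states(
            area_df(
                [
                    ("s1", V["H3.1"], "", 2, 40.0),
                    ("s1", V["H3.1"], "K27me1", 2, 35.0),
                    ("s1", V["H3.3"], "", 2, 25.0),
                ]
            )
        )
        props = q.variant_proportions(collapsed, pmap, family_of_group, "H3")
        got = props.set_index("variant")["percent"]
        assert got["H3.1"] == pytest.approx(75.0)
        assert got["H3.3"] == pytest.approx(25.0)

    def test_equal_areas_symmetric(self, peptide_map_bundle, family_of_group):
        pmap, _, _ = peptide_map_bundle
        from histoptm.synthetic_data import VARIANT_REGION_PEPTIDE as V

        collapsed = q.collapse_charge_states(
            area_df([("s1", V[v], "", 2, 10.0) for v in ("H2A.Z.9", "H2A.Z.8", "H2A.Z.11")])
        )
        props = q.variant_proportions(collapsed, pmap, family_of_group, "H2A.Z")
        assert np.allclose(props["percent"], 100 / 3)

    def test_excluded_variant_never_appears(self, peptide_map_bundle, family_of_group):
        pmap, _, _ = peptide_map_bundle
        from histoptm.synthetic_data import VARIANT_REGION_PEPTIDE as V

        collapsed = q.collapse_charge_states(
            area_df(
                [
                    ("s1", V["H2A.W.6"], "", 2, 80.0),
                    ("s1", V["H2A.W.7"], "", 2, 20.0),
                ]
            )
        )
        props = q.variant_proportions(collapsed, pmap, family_of_group, "H2A.W")
        assert set(props["variant"]) == {"H2A.W.6", "H2A.W.7"}


class TestVariantPairRatio:
    @pytest.mark.parametrize(
        "pa,pb,expected", [(75.0, 25.0, 3.0), (44.4, 55.6, 0.7986), (50.0, 50.0, 1.0)]
    )
    def test_ratio_values(self, pa, pb, expected):
        props = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "family": ["H3", "H3"],
                "variant": ["H3.1", "H3.3"],
                "percent": [pa, pb],
            }
        )
        out = q.variant_pair_ratio(props, "H3.1", "H3.3")
        assert out["ratio"].iloc[0] == pytest.approx(expected, abs=0.01)

    def test_zero_denominator_rejected(self):
        props = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "family": ["H3", "H3"],
                "variant": ["H3.1", "H3.3"],
                "percent": [100.0, 0.0],
            }
        )
        with pytest.raises(UndefinedRatioError):
            q.variant_pair_ratio(props, "H3.1", "H3.3")


class TestMarkLevelAbundance:
    def test_all_unmodified(self):
        mix = q.VariantMixture(0.3, 0.7)
        out = q.mark_level_abundance({"unmodified": 100.0}, {"unmodified": 100.0}, mix)
        assert out["unmodified"] == pytest.approx(100.0)

    def test_single_shared_mark(self):
        mix = q.VariantMixture(0.5, 0.5)
        out = q.mark_level_abundance({"K27me1": 100.0}, {"K27me1": 100.0}, mix)
        assert out["K27me1"] == pytest.approx(100.0)

    def test_mixture_weighted_split(self):
        mix = q.VariantMixture(0.5, 0.5)
        out = q.mark_level_abundance({"K27me1": 100.0}, {"K36me1": 100.0}, mix)
        assert out["K27me1"] == pytest.approx(50.0)
        assert out["K36me1"] == pytest.approx(50.0)

    def test_comodified_form_counts_once_per_mark(self):
        # oracle: hand-weighted sum under the stated contribution rule
        mix = q.VariantMixture(1.0, 0.0)
        out = q.mark_level_abundance(
            {"K27me1;K36me1": 50.0, "unmodified": 50.0}, {"unmodified": 100.0}, mix
        )
        # contributions: K27me1 50, K36me1 50, unmodified 50 -> renormalized /150
        assert out["K27me1"] == pytest.approx(100 * 50 / 150)
        assert out["K36me1"] == pytest.approx(100 * 50 / 150)
        assert out["unmodified"] == pytest.approx(100 * 50 / 150)

    def test_non_k27_k36_mods_fold_into_unmodified(self):
        mix = q.VariantMixture(1.0, 0.0)
        out = q.mark_level_abundance(
            {"K37me1": 40.0, "K27me1": 60.0}, {"unmodified": 100.0}, mix
        )
        assert out["unmodified"] == pytest.approx(40.0)
        assert out["K27me1"] == pytest.approx(60.0)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(InvalidDataError):
            q.VariantMixture(1.2, -0.2)


class TestScaleInvariance:
    def test_compositions_invariant_to_area_scaling(self, peptide_map_bundle):
        pmap, _, _ = peptide_map_bundle
        rows = [
            ("s1", "KSAPATGGVKKPHR", "", 2, 50.0),
            ("s1", "KSAPATGGVKKPHR", "K27me1", 2, 850.0),
        ]
        scaled = [(s, p, m, c, a * 1e6) for s, p, m, c, a in rows]
        a = q.form_relative_abundance(q.collapse_charge_states(area_df(rows)), pmap)
        b = q.form_relative_abundance(q.collapse_charge_states(area_df(scaled)), pmap)
        assert np.allclose(a["percent"], b["percent"])
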