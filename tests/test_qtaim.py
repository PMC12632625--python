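"""Bond-critical-point energetics and interaction classification."""

import numpy as np
import pandas as pd
import pytest

from hostguest import (
    afonin_energy,
    annotate_table,
    gen_bcp_table,
    hayashi_class,
    interaction_inventory,
    jeffrey_energetic,
    jeffrey_geometric,
    local_h,
    type_interaction,
    virial_g,
)
from hostguest.qtaim import parse_bond_label
from hostguest.refdata import bcp_fluorine_table, bcp_hbond_table


class TestVirial:
    def test_trivial_point(self):
        assert virial_g(0.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "lap,v,g_expected,h_expected",
        [
            (35.62e-3, -5.20e-3, 7.05e-3, 1.85e-3),   # electrostatic portal H-bond
            (92.25e-3, -23.90e-3, 23.48e-3, -0.42e-3),  # partially covalent H-bond
        ],
    )
    def test_kinetic_and_total_energy_densities(self, lap, v, g_expected, h_expected):
        g = virial_g(lap, v)
        assert g == pytest.approx(g_expected, abs=5e-6)
        assert local_h(v, g) == pytest.approx(h_expected, abs=5e-6)

    def test_local_h_balance_point(self):
        assert local_h(-3.0e-3, 3.0e-3) == 0.0

    def test_negative_kinetic_density_warns(self):
        with pytest.warns(UserWarning):
            virial_g(-40.0e-3, 5.0e-3)


class TestAfonin:
    def test_intercept_at_zero_v(self):
        assert afonin_energy(0.0) == pytest.approx(0.33 * 4.184, abs=1e-9)

    def test_positive_v_warns(self):
        with pytest.warns(UserWarning):
            afonin_energy(2.0e-3)

    @pytest.mark.parametrize(
        "v,expected", [(-23.90e-3, 18.63), (-4.2e-3, 4.4), (-21.70e-3, 17.04)]
    )
    def test_published_rows(self, v, expected):
        assert afonin_energy(v) == pytest.approx(expected, abs=0.05)

    def test_affine_and_decreasing(self):
        vs = np.linspace(-30e-3, -1e-3, 7)  # V increasing toward 0
        es = np.array([afonin_energy(v) for v in vs])
        assert np.all(np.diff(es) < 0)
        slopes = np.diff(es) / np.diff(vs)
        assert np.allclose(slopes, slopes[0], rtol=1e-12)


class TestClassifiers:
    @pytest.mark.parametrize(
        "lap,h,expected",
        [
            (35.62e-3, 1.86e-3, "pCS"),
            (92.25e-3, -0.40e-3, "rCS"),
            (26.9e-3, 1.3e-3, "pCS"),
            (-10.0e-3, -5.0e-3, "SS"),
        ],
    )
    def test_hayashi(self, lap, h, expected):
        assert hayashi_class(lap, h) == expected

    @pytest.mark.parametrize(
        "d,angle,expected",
        [
            (2.42, 126.94, "Weak"),
            (1.90, 171.27, "Moderate"),
            (2.15, 145.56, "Moderate"),
            (1.2, 170.0, "Strong"),
            (3.5, 120.0, "Weak (d > 3.2 Å)"),
        ],
    )
    def test_jeffrey_geometric(self, d, angle, expected):
        assert jeffrey_geometric(d, angle) == expected

    def test_jeffrey_geometric_validates_angle(self):
        with pytest.raises(ValueError):
            jeffrey_geometric(2.0, 210.0)

    @pytest.mark.parametrize(
        "e,expected",
        [(14.68, "Weak"), (17.01, "Moderate"), (5.12, "Weak"),
         (16.7, "Moderate"), (80.0, "Strong")],
    )
    def test_jeffrey_energetic(self, e, expected):
        assert jeffrey_energetic(e) == expected

    def test_scale_invariance_of_classification(self):
        # the class depends only on signs and thresholds in a common unit
        for factor in (1.0, 1e3):
            assert hayashi_class(35.62e-3 * factor, 1.86e-3 * factor) == "pCS"
            assert hayashi_class(92.25e-3 * factor, -0.40e-3 * factor) == "rCS"


class TestInteractionTyping:
    def test_rule_table(self):
        assert type_interaction("N", True, "O", ("piperazine_n",)) == "ionic_hbond"
        assert type_interaction("N", True, "O") == "hbond"
        assert type_interaction("C", True, "F") == "fluorine_contact"
        assert type_interaction("H", False, "H") == "dihydrogen"
        assert type_interaction("C", False, "O") == "n_pi_star"
        assert type_interaction("C", True, "S") == "other"

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            type_interaction("Xx", False, "O")

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("[O1]1⋯HN4", ("O", True, "N")),
            ("[O1]3⋯FC2′", ("O", False, "F")),
            ("C2′F⋯HeC2", ("F", True, "C")),
            ("garbage", None),
        ],
    )
    def test_bond_label_parsing(self, label, expected):
        assert parse_bond_label(label) == expected


class TestAnnotateTable:
    def test_hbond_table_rederivation(self):
        # re-derive H and E from the printed (lap, V); both are tabulated to
        # two decimals, so agreement is expected within 0.05 in their units
        ann = annotate_table(bcp_hbond_table())
        assert np.all(np.abs(ann["H"] - ann["H_published"]) <= 0.05)
        assert np.all(np.abs(ann["E"] - ann["E_published"]) <= 0.05)
        for col in ("GC", "EC", "HC"):
            assert (ann[col] == ann[f"{col}_published"]).all()
        assert (ann["itype"] == "ionic_hbond").all()

    def test_fluorine_table_rederivation(self):
        # the fluorine-contact table prints densities to one decimal in
        # 10^-3 au, so rounding alone moves derived H/E by up to ~0.09
        ann = annotate_table(bcp_fluorine_table())
        assert np.all(np.abs(ann["H"] - ann["H_published"]) <= 0.09)
        assert np.all(np.abs(ann["E"] - ann["E_published"]) <= 0.09)
        assert (ann["EC"] == "Weak").all()
        assert (ann["HC"] == "pCS").all()
        assert (ann["itype"] == "fluorine_contact").all()

    def test_idempotent_and_order_equivariant(self):
        tbl = bcp_hbond_table()
        once = annotate_table(tbl)
        twice = annotate_table(once)
        pd.testing.assert_frame_equal(once, twice)
        perm = tbl.sample(frac=1.0, random_state=7)
        ann_perm = annotate_table(perm).sort_index()
        pd.testing.assert_frame_equal(
            ann_perm, annotate_table(tbl), check_like=True
        )

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="V"):
            annotate_table(pd.DataFrame({"rho": [1.0], "lap": [2.0]}))

    def test_virial_violation_flagged(self):
        tbl = pd.DataFrame(
            {"rho": [9.0, 9.0], "lap": [35.62, 35.62], "V": [-5.2, -5.2],
             "G": [7.05, 9.0]}  # second row breaks the identity
        )
        ann = annotate_table(tbl)
        assert list(ann["virial_flag"]) == [False, True]

    def test_inventory_counts_by_type(self):
        ann = annotate_table(bcp_hbond_table())
        inv = interaction_inventory(ann)
        assert inv["count"].sum() == len(ann)
        assert set(inv["itype"]) == {"ionic_hbond"}


class TestPlantAndRecover:
    def test_full_recovery_of_planted_labels(self):
        syn = gen_bcp_table(500, seed=11)
        ann = annotate_table(syn.table)
        assert (ann["HC"] == syn.truth["HC"]).all()
        assert (ann["EC"] == syn.truth["EC"]).all()
        assert (ann["GC"] == syn.truth["GC"]).all()

    def test_virial_identity_exact_on_generated_rows(self):
        syn = gen_bcp_table(200, seed=5)
        lap = syn.table["lap"].to_numpy() * 1e-3
        v = syn.table["V"].to_numpy() * 1e-3
        g = np.array([virial_g(l, vv) for l, vv in zip(lap, v)])
        assert np.max(np.abs(0.25 * lap - (2 * g + v))) < 1e-15
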