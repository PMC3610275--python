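import numpy as np
import pytest

from gpcrgeom._geom import rotation_about_axis
from gpcrgeom.bw_numbering import BWMap
from gpcrgeom.interaction_geometry import (
    HBondCriteria,
    apply_amide_flip,
    assess_amide_flip,
    hbond_verdict,
    measure_pair,
    network_scan,
    table1_report,
)
from gpcrgeom.structure_io import Atom, Residue, StructureModel
from gpcrgeom.synthetic_structures import build_hbond_fixture


def fixture_map(donor_pos="6.47", acceptor_pos="7.45"):
    return BWMap(entries={("A", 1): donor_pos, ("A", 2): acceptor_pos})


class TestMeasurePair:
    def test_engineered_exact_geometry(self):
        model = build_hbond_fixture("CYS", "ASN", 3.0, 180.0)
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g.da_distance == pytest.approx(3.0, abs=1e-6)
        assert g.cb_d_a_angle == pytest.approx(180.0, abs=1e-6)
        assert g.donor_atom == "SG"
        assert g.acceptor_atom == "OD1"
        assert g.facing_group == "CO"

    def test_table_row_like_geometry(self):
        model = build_hbond_fixture("CYS", "ASN", 3.8, 84.5)
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g.da_distance == pytest.approx(3.8, abs=1e-6)
        assert g.cb_d_a_angle == pytest.approx(84.5, abs=1e-6)
        assert g.is_hbond

    def test_long_distance_not_hbond(self):
        model = build_hbond_fixture("CYS", "THR", 8.8, 100.0)
        g = measure_pair(model, fixture_map("6.47", "7.44"), "6.47", "7.44")
        assert g.da_distance == pytest.approx(8.8, abs=1e-6)
        assert not g.is_hbond

    def test_nearer_amide_atom_chosen(self):
        model = build_hbond_fixture("CYS", "ASN", 3.5, 90.0)
        res = model.residue("A", 2)
        donor_sg = model.residue("A", 1).atom("SG").coords
        d_od1 = np.linalg.norm(res.atom("OD1").coords - donor_sg)
        d_nd2 = np.linalg.norm(res.atom("ND2").coords - donor_sg)
        assert d_od1 < d_nd2
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g.acceptor_atom == "OD1"
        # after flipping the amide the other atom faces the donor
        apply_amide_flip(model, "A", 2)
        g2 = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g2.acceptor_atom == "ND2"
        assert g2.facing_group == "NH2"

    def test_distance_symmetry(self):
        model = build_hbond_fixture("THR", "SER", 3.1, 120.0)
        bw = fixture_map("6.47", "7.45")
        g_fwd = measure_pair(model, bw, "6.47", "7.45")
        g_rev = measure_pair(model, bw, "7.45", "6.47")
        assert g_fwd.da_distance == pytest.approx(g_rev.da_distance, abs=1e-9)

    def test_rigid_motion_invariance(self):
        model = build_hbond_fixture("CYS", "ASN", 3.8, 84.5)
        rot = rotation_about_axis([0.2, 1.0, -0.7], 61.0)
        for res in model.iter_residues():
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + np.array([9.0, -2.0, 4.0])
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g.da_distance == pytest.approx(3.8, abs=1e-9)
        assert g.cb_d_a_angle == pytest.approx(84.5, abs=1e-9)

    def test_unmapped_position_error(self):
        model = build_hbond_fixture("CYS", "ASN", 3.8, 84.5)
        with pytest.raises(LookupError):
            measure_pair(model, fixture_map(), "6.47", "2.50")


class TestHbondVerdict:
    def test_sulfur_donor_cutoffs(self):
        assert hbond_verdict(3.8, "S")
        assert hbond_verdict(4.3, "S")
        assert not hbond_verdict(4.4, "S")

    def test_sulfur_donor_ignores_angle(self):
        model = build_hbond_fixture("CYS", "ASN", 3.8, 30.0)
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g.is_hbond

    def test_oxygen_donor_cutoffs(self):
        model = build_hbond_fixture("THR", "ASN", 3.2, 120.2)
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert g.is_hbond
        far = build_hbond_fixture("THR", "ASN", 3.7, 120.2)
        assert not measure_pair(far, fixture_map(), "6.47", "7.45").is_hbond

    def test_oxygen_donor_angle_floor(self):
        model = build_hbond_fixture("THR", "ASN", 3.2, 45.0)
        g = measure_pair(model, fixture_map(), "6.47", "7.45")
        assert not g.is_hbond

    def test_configurable_criteria(self):
        crit = HBondCriteria(s_donor_max_distance=3.0)
        assert not hbond_verdict(3.8, "S", crit)


class TestAmideFlip:
    def test_nearby_thiol_prefers_deposited(self):
        model = build_hbond_fixture("CYS", "ASN", 3.5, 90.0)
        flip = assess_amide_flip(model, fixture_map(), "7.45", environment_radius=8.0)
        assert flip.score_deposited == 1
        assert flip.score_flipped == 0
        assert flip.preferred == "deposited"

    def test_isolated_amide_is_tie(self):
        res = Residue(
            res_name="ASN",
            res_seq=1,
            chain_id="A",
            atoms=[
                Atom("N", "N", [0, 0, 0]),
                Atom("CA", "C", [1.5, 0, 0]),
                Atom("CB", "C", [2.0, 1.4, 0]),
                Atom("CG", "C", [3.5, 1.4, 0]),
                Atom("OD1", "O", [4.1, 2.4, 0]),
                Atom("ND2", "N", [4.1, 0.3, 0]),
            ],
        )
        model = StructureModel(model_id=1, chains={"A": [res]})
        bw = BWMap(entries={("A", 1): "7.45"})
        flip = assess_amide_flip(model, bw, "7.45")
        assert flip.score_deposited == 0
        assert flip.score_flipped == 0
        assert flip.preferred == "tie"

    def test_flip_involution(self):
        model = build_hbond_fixture("CYS", "ASN", 3.5, 90.0)
        before = assess_amide_flip(model, fixture_map(), "7.45")
        apply_amide_flip(model, "A", 2)
        after = assess_amide_flip(model, fixture_map(), "7.45")
        assert after.score_deposited == before.score_flipped
        assert after.score_flipped == before.score_deposited

    def test_non_amide_position_rejected(self):
        model = build_hbond_fixture("CYS", "THR", 3.5, 90.0)
        with pytest.raises(ValueError):
            assess_amide_flip(model, fixture_map("6.47", "7.44"), "7.44")

    def test_incomplete_amide_rejected(self):
        model = build_hbond_fixture("CYS", "ASN", 3.5, 90.0)
        res = model.residue("A", 2)
        res.atoms = [a for a in res.atoms if a.name != "ND2"]
        with pytest.raises(LookupError):
            assess_amide_flip(model, fixture_map(), "7.45")


def _three_residue_chain_model():
    """Cys1 -SG- 3.0 A -OD1- Asn2 -ND2- 3.0 A -OD1- Asn3 chain."""
    model = build_hbond_fixture("CYS", "ASN", 3.0, 120.0)
    asn2 = model.residue("A", 2)
    nd2 = asn2.atom("ND2").coords
    direction = nd2 - asn2.atom("CG").coords
    direction /= np.linalg.norm(direction)
    od1_3 = nd2 + 3.0 * direction
    cg_3 = od1_3 + 1.23 * direction
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    nd2_3 = cg_3 + 1.35 * (0.5 * direction + 0.866 * perp)
    cb_3 = cg_3 + 1.51 * direction
    ca_3 = cb_3 + 1.53 * direction
    asn3 = Residue(
        res_name="ASN",
        res_seq=3,
        chain_id="A",
        atoms=[
            Atom("OD1", "O", od1_3),
            Atom("CG", "C", cg_3),
            Atom("ND2", "N", nd2_3),
            Atom("CB", "C", cb_3),
            Atom("CA", "C", ca_3),
        ],
    )
    model.chains["A"].append(asn3)
    return model


class TestNetworkScan:
    def test_engineered_chain_has_two_edges(self):
        model = _three_residue_chain_model()
        bw = BWMap(
            entries={("A", 1): "6.47", ("A", 2): "7.45", ("A", 3): "7.49"}
        )
        report = network_scan(model, bw, ["6.47", "7.45", "7.49"])
        assert report.present_pairs == ["6.47-7.45", "7.45-7.49"]
        assert report.absent_pairs == ["6.47-7.49"]

    def test_every_pair_classified_exactly_once(self):
        model = _three_residue_chain_model()
        bw = BWMap(
            entries={("A", 1): "6.47", ("A", 2): "7.45", ("A", 3): "7.49"}
        )
        report = network_scan(model, bw, ["6.47", "7.45", "7.49"])
        labels = sorted(report.present_pairs + report.absent_pairs)
        assert labels == ["6.47-7.45", "6.47-7.49", "7.45-7.49"]

    def test_cutoff_monotonicity(self):
        model = _three_residue_chain_model()
        bw = BWMap(
            entries={("A", 1): "6.47", ("A", 2): "7.45", ("A", 3): "7.49"}
        )
        tight = network_scan(
            model, bw, ["6.47", "7.45", "7.49"],
            criteria=HBondCriteria(s_donor_max_distance=2.0),
        )
        loose = network_scan(
            model, bw, ["6.47", "7.45", "7.49"],
            criteria=HBondCriteria(s_donor_max_distance=5.0),
        )
        assert set(tight.present_pairs) <= set(loose.present_pairs)

    def test_water_bridge_detection(self):
        model = _three_residue_chain_model()
        sg = model.residue("A", 1).atom("SG").coords
        od1 = model.residue("A", 2).atom("OD1").coords
        midpoint = 0.5 * (sg + od1)
        water = Residue(
            res_name="HOH",
            res_seq=401,
            chain_id="A",
            atoms=[Atom("O", "O", midpoint)],
            is_hetero=True,
        )
        model.chains["A"].append(water)
        bw = BWMap(entries={("A", 1): "6.47", ("A", 2): "7.45"})
        report = network_scan(model, bw, ["6.47", "7.45"], water_bridges=True)
        assert any(
            {a, b} == {"6.47", "7.45"} for a, b, _ in report.water_bridges
        )


class TestTable1Report:
    def test_rows_and_formatting(self):
        close = build_hbond_fixture("CYS", "ASN", 3.8, 84.5)
        far = build_hbond_fixture("CYS", "ASN", 4.4, 81.2)
        entries = [
            {
                "structure": m,
                "bw_map": fixture_map(),
                "donor_pos": "6.47",
                "acceptor_pos": "7.45",
                "label": label,
            }
            for m, label in ((close, "INV"), (far, "AGO"))
        ]
        df = table1_report(entries)
        assert list(df["error"]) == ["", ""]
        assert list(df["da_distance"]) == ["3.8", "4.4"]
        assert list(df["is_hbond"]) == [True, False]
        assert list(df["facing"]) == ["CO", "CO"]
        assert list(df["pair"]) == ["C6.47-N7.45", "C6.47-N7.45"]

    def test_empty_entries(self):
        df = table1_report([])
        assert len(df) == 0

    def test_row_errors_collected(self):
        model = build_hbond_fixture("CYS", "ASN", 3.8, 84.5)
        df = table1_report(
            [
                {
                    "structure": model,
                    "anchors": {"6.50": ("A", 99)},
                    "donor_pos": "6.47",
                    "acceptor_pos": "7.45",
                    "label": "broken",
                }
            ]
        )
        assert len(df) == 1
        assert df.loc[0, "error"] != ""
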