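"""Structure reading, Calpha distances, reach annotation, dynamics calls."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qxlms.diff_stats import DifferentialResult
from qxlms.struct_map import (
    CATEGORIES,
    DistanceAnnotation,
    ModelError,
    StructureModel,
    annotate_link_distances,
    ca_distance,
    classify_all,
    classify_dynamics,
    read_structure,
)
from qxlms.synthetic_data import _build_structure, rigid_transform_model
from qxlms.xlink_io import LinkSpecies, ResidueRef


def toy_model(coords, model_id="toy", protein_id="P1", atom="CA"):
    residues = [
        (num, "LYS", [(atom, tuple(pos))]) for num, pos in sorted(coords.items())
    ]
    return StructureModel(
        model_id=model_id,
        structure=_build_structure(model_id, residues),
        chain_map={protein_id: "A"},
        offsets={protein_id: 0},
    )


def ref(index, protein="P1"):
    return ResidueRef(protein, index, "K")


class TestReadStructure:
    def test_three_residue_pdb(self, tmp_path):
        model = toy_model({1: (0, 0, 0), 2: (3, 0, 0), 3: (0, 4, 0)})
        path = tmp_path / "toy.pdb"
        model.structure.write_pdb(str(path))
        loaded = read_structure(path, chain_map={"P1": "A"})
        assert loaded.chains() == ["A"]
        assert ca_distance(loaded, ref(2), ref(3)) == pytest.approx(5.0)

    def test_mmcif_gives_identical_coordinates(self, tmp_path):
        # integer-millangstrom coordinates survive both formats exactly
        model = toy_model({1: (0.125, 0, 0), 2: (3.5, 0, 0), 3: (0, 4.25, 1)})
        pdb, cif = tmp_path / "toy.pdb", tmp_path / "toy.cif"
        model.structure.write_pdb(str(pdb))
        model.structure.make_mmcif_document().write_file(str(cif))
        from_pdb = read_structure(pdb, chain_map={"P1": "A"})
        from_cif = read_structure(cif, chain_map={"P1": "A"})
        for index in (1, 2, 3):
            np.testing.assert_allclose(
                from_pdb.ca_position(ref(index)),
                from_cif.ca_position(ref(index)),
                atol=1e-12,
            )

    def test_unparseable_file_errors(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ModelError):
            read_structure(bad)

    def test_configured_chain_absent_errors(self, tmp_path):
        model = toy_model({1: (0, 0, 0), 2: (3, 0, 0)})
        path = tmp_path / "toy.pdb"
        model.structure.write_pdb(str(path))
        with pytest.raises(ModelError, match="chain 'B'"):
            read_structure(path, chain_map={"P1": "B"})

    def test_missing_ca_atoms_fail_lookup(self):
        model = toy_model({1: (0, 0, 0)}, atom="CB")
        with pytest.raises(KeyError, match="CA"):
            model.ca_position(ref(1))

    def test_numbering_offset_applied(self):
        model = toy_model({101: (0, 0, 0), 105: (3, 4, 0)})
        model.offsets["P1"] = 100
        assert ca_distance(model, ref(1), ref(5)) == pytest.approx(5.0)


class TestDistances:
    def test_same_residue_distance_zero(self):
        model = toy_model({1: (1, 2, 3)})
        assert ca_distance(model, ref(1), ref(1)) == 0.0

    def test_3_4_5_triangle(self):
        model = toy_model({1: (0, 0, 0), 2: (3, 4, 0)})
        assert ca_distance(model, ref(1), ref(2)) == 5.0

    def test_rigid_motion_leaves_distances_unchanged(self):
        rng = np.random.default_rng(0)
        coords = {i: rng.uniform(-50, 50, 3) for i in range(1, 12)}
        model = toy_model(coords)
        rotation = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        moved = rigid_transform_model(model, rotation, np.array([20.0, -7.0, 3.0]))
        for i in range(1, 11):
            d0 = ca_distance(model, ref(i), ref(i + 1))
            d1 = ca_distance(moved, ref(i), ref(i + 1))
            assert abs(d0 - d1) < 1e-9

    def test_hinge_truth_distances_match(self, hinge_pair):
        model_a, _model_b, truth = hinge_pair
        for (i, j), expected in truth.pair_distances.items():
            got = ca_distance(model_a, ref(i, "TOY_SYN"), ref(j, "TOY_SYN"))
            assert got == pytest.approx(expected, abs=1e-9)


def link(i, j, protein="P1", kind="interpeptide", **kw):
    return LinkSpecies(kind, ref(i, protein), ref(j, protein), **kw)


class TestAnnotate:
    @pytest.mark.parametrize(
        "distance, within", [(29.9, True), (30.0, True), (30.1, False)]
    )
    def test_reach_boundary_inclusive_at_30(self, distance, within):
        model = toy_model({1: (0, 0, 0), 2: (distance, 0, 0)})
        (ann,) = annotate_link_distances([link(1, 2)], [model])
        assert ann.mapped
        assert ann.d_ca == pytest.approx(distance)
        assert ann.within_reach is within

    def test_monolinks_are_skipped(self):
        model = toy_model({1: (0, 0, 0)})
        mono = LinkSpecies("monolink", ref(1))
        assert annotate_link_distances([mono], [model]) == []

    def test_unmapped_site_flagged_not_raised(self):
        model = toy_model({1: (0, 0, 0), 2: (10, 0, 0)})
        (ann,) = annotate_link_distances([link(1, 99)], [model])
        assert not ann.mapped and ann.d_ca is None and ann.within_reach is None

    def test_link_to_protein_absent_from_model_is_unmapped(self):
        model = toy_model({1: (0, 0, 0), 2: (10, 0, 0)})
        other = LinkSpecies("interpeptide", ref(1), ref(5, "P9"))
        (ann,) = annotate_link_distances([other], [model])
        assert not ann.mapped

    def test_ambiguous_site_uses_minimum_distance(self):
        # K206/K207-style alternates: reachable via the nearer candidate
        model = toy_model({1: (0, 0, 0), 206: (40, 0, 0), 207: (25, 0, 0)})
        ambiguous = link(1, 206, site_b_alternates=(ref(207),))
        (ann,) = annotate_link_distances([ambiguous], [model])
        assert ann.d_ca == pytest.approx(25.0)
        assert ann.within_reach


def diff_result(key, direction="increase", significant=True):
    fc = {"increase": 4.0, "decrease": 0.25, "none": 1.0}[direction]
    return DifferentialResult(
        key=key, label="L", link_kind="interpeptide", fold_change=fc,
        p_value=0.001 if significant else 0.7, direction=direction,
        significant=significant, n_control=3, n_treated=3, t_stat=9.9, df=4,
    )


def annotation(key, model_id, d_ca, reach=30.0):
    mapped = d_ca is not None
    return DistanceAnnotation(
        link_key=key, model_id=model_id, d_ca=d_ca,
        within_reach=(d_ca <= reach) if mapped else None, mapped=mapped,
    )


class TestClassification:
    KEY = ("interpeptide", "P1:K1", "P1:K2")
    ROLES = {"S1": "primary", "S1_mava": "primary", "BH": "alternate"}

    def call(self, direction, significant, d_primary, d_alternate=None):
        anns = [
            annotation(self.KEY, "S1", d_primary),
            annotation(self.KEY, "S1_mava", d_primary),
        ]
        if d_alternate is not None:
            anns.append(annotation(self.KEY, "BH", d_alternate))
        return classify_dynamics(
            diff_result(self.KEY, direction, significant), anns, self.ROLES
        )

    def test_increase_within_reach_is_stabilized_state(self):
        # e.g. a converter-L50 link growing without a distance change
        assert self.call("increase", True, 15.0).category == "stabilized_state"

    def test_increase_beyond_reach_but_alternate_in_reach_is_alternate_state(self):
        # e.g. an RLC-loop1 link reachable only with a bent lever
        call = self.call("increase", True, 45.0, d_alternate=20.0)
        assert call.category == "alternate_state_sampling"

    def test_increase_beyond_reach_everywhere_is_increased_dynamics(self):
        call = self.call("increase", True, 45.0, d_alternate=50.0)
        assert call.category == "increased_dynamics"

    def test_decrease_beyond_reach_is_lost_exploratory(self):
        # e.g. an ELC-NTD exploratory link suppressed by the drug
        assert self.call("decrease", True, 45.0).category == "lost_exploratory"

    def test_decrease_within_reach_is_redistribution(self):
        assert self.call("decrease", True, 12.0).category == "redistribution"

    def test_not_significant_is_no_change(self):
        assert self.call("increase", False, 15.0).category == "no_change"

    def test_unmapped_everywhere_is_unannotated(self):
        anns = [annotation(self.KEY, m, None) for m in ("S1", "S1_mava")]
        call = classify_dynamics(diff_result(self.KEY), anns, self.ROLES)
        assert call.category == "unannotated"

    def test_every_call_lands_in_exactly_one_category(self):
        seen = set()
        for direction in ("increase", "decrease"):
            for significant in (True, False):
                for d_primary in (15.0, 45.0, None):
                    for d_alternate in (20.0, 50.0, None):
                        anns = [
                            annotation(self.KEY, "S1", d_primary),
                            annotation(self.KEY, "S1_mava", d_primary),
                        ]
                        if d_alternate is not None:
                            anns.append(annotation(self.KEY, "BH", d_alternate))
                        call = classify_dynamics(
                            diff_result(self.KEY, direction, significant),
                            anns, self.ROLES,
                        )
                        assert call.category in CATEGORIES
                        seen.add(call.category)
        assert {"stabilized_state", "increased_dynamics",
                "alternate_state_sampling", "lost_exploratory",
                "redistribution", "no_change", "unannotated"} <= seen

    def test_category_counts_invariant_to_link_order(self):
        keys = [("interpeptide", f"P1:K{i}", f"P1:K{i + 10}") for i in range(6)]
        diffs = [
            diff_result(k, d)
            for k, d in zip(keys, ["increase", "decrease", "increase",
                                   "decrease", "increase", "none"])
        ]
        anns = [annotation(k, "S1", 15.0 if i % 2 else 45.0)
                for i, k in enumerate(keys)]
        forward = classify_all(diffs, anns, {"S1": "primary"})
        backward = classify_all(diffs[::-1], anns[::-1], {"S1": "primary"})
        count = lambda calls: sorted(c.category for c in calls)
        assert count(forward) == count(backward)
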