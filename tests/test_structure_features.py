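import math

import numpy as np
import pandas as pd
import pytest

from phosfam.errors import ValidationError
from phosfam.hotspot_stats import HotspotRegion
from phosfam.structure_features import (
    ResidueAnnotation,
    StructureModel,
    annotate_residues,
    annotations_frame,
    column_map_from_row,
    filter_structures,
    kabsch_rmsd,
    map_hotspot_to_structure,
    matched_ca,
    select_representative,
)
from _oracles import grid_search_rmsd_2d, random_rotation


def make_model(
    structure_id,
    n=10,
    numbers=None,
    coords=None,
    columns=None,
    sequence=None,
):
    sequence = sequence or "A" * n
    n = len(sequence)
    if coords is None:
        coords = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    m = StructureModel(
        structure_id=structure_id,
        model_sequence=sequence,
        residue_numbers=tuple(numbers or range(1, n + 1)),
        ca_coords=coords,
    )
    m.column_of_residue = columns if columns is not None else {
        i + 1: i + 1 for i in range(n)
    }
    return m


class TestFilterStructures:
    def test_short_models_removed_at_70_percent(self):
        models = [make_model("a", 100), make_model("b", 95), make_model("c", 60)]
        kept = filter_structures(models)
        assert [m.structure_id for m in kept] == ["a", "b"]

    def test_two_residue_gap_removed(self):
        gappy = make_model("g", numbers=[1, 2, 5, 6, 7], sequence="AAAAA")
        ok = make_model("o", numbers=[1, 2, 4, 5, 6], sequence="AAAAA")
        kept = filter_structures([gappy, ok])
        assert [m.structure_id for m in kept] == ["o"]

    def test_single_model_kept(self):
        m = make_model("solo", 30)
        assert filter_structures([m]) == [m]

    def test_order_independent(self):
        models = [make_model("a", 100), make_model("b", 60), make_model("c", 95)]
        fwd = {m.structure_id for m in filter_structures(models)}
        rev = {m.structure_id for m in filter_structures(models[::-1])}
        assert fwd == rev

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            filter_structures([])


class TestKabschRmsd:
    def test_identical_coordinates(self, rng):
        pts = rng.normal(size=(12, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_rigid_motion(self, rng):
        pts = rng.normal(size=(15, 3)) * 5
        R = random_rotation(rng)
        moved = pts @ R.T + np.array([4.0, -2.0, 9.0])
        assert kabsch_rmsd(pts, moved) <= 1e-9

    def test_reflection_not_allowed(self, rng):
        # chiral point set mirrored: proper rotations cannot reach RMSD 0
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(pts, mirrored) > 0.1

    def test_symmetry(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_against_rotation_grid_oracle(self):
        # unit square with one corner displaced by 1 A along +x (planar)
        A = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        B = A.copy()
        B[2, 0] += 1.0
        expected = grid_search_rmsd_2d(A, B)
        assert kabsch_rmsd(A, B) == pytest.approx(expected, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSelectRepresentative:
    def _cluster_models(self, rng):
        base = rng.normal(size=(20, 3)) * 4
        jitter = [base + rng.normal(scale=0.05, size=base.shape) for _ in range(3)]
        far = base + np.array([50.0, 0.0, 0.0]) + rng.normal(scale=8.0, size=base.shape)
        models = [
            make_model("near1", coords=jitter[0], sequence="A" * 20),
            make_model("near2", coords=jitter[1], sequence="A" * 20),
            make_model("near3", coords=jitter[2], sequence="A" * 20),
            make_model("outlier", coords=far, sequence="A" * 20),
        ]
        return models

    def test_representative_from_largest_cluster(self, rng):
        models = self._cluster_models(rng)
        rep = select_representative(models)
        assert rep.structure_id.startswith("near")

    def test_single_model_returned(self):
        m = make_model("solo", 10)
        assert select_representative([m]) is m

    def test_tie_between_singletons_goes_to_longer_model(self, rng):
        a = make_model("aaa", 12)
        cols_b = {i + 1: i + 1 for i in range(10)}
        b = make_model(
            "bbb",
            coords=np.column_stack(
                [3.8 * np.arange(10), 40.0 + np.arange(10) ** 1.3, np.zeros(10)]
            ),
            sequence="A" * 10,
            columns=cols_b,
        )
        rep = select_representative([a, b], cluster_cutoff=1.0)
        assert rep.structure_id == "aaa"


class TestAnnotate:
    def _features(self, n, contacts=None):
        return pd.DataFrame(
            {
                "residue_index": np.arange(1, n + 1),
                "rsa_percent": np.linspace(0, 100, n),
                "disordered": [i % 2 == 0 for i in range(n)],
                "catalytic": False,
                "interface_contact_count": contacts if contacts is not None else 0,
            }
        )

    def test_catalytic_residue_has_zero_distances(self):
        model = make_model("m", 10)
        ann = annotate_residues(model, self._features(10), catalytic=[4])
        assert ann[3].seq_dist_to_catalytic == 0
        assert ann[3].spatial_dist_to_catalytic == 0.0
        assert ann[3].catalytic

    def test_interface_threshold_is_ten_contacts(self):
        model = make_model("m", 2)
        feats = self._features(2, contacts=[10, 9])
        ann = annotate_residues(model, feats, catalytic=[])
        assert ann[0].interface and not ann[1].interface

    def test_sequence_distance_five_is_inclusive(self):
        model = make_model("m", 15)
        ann = annotate_residues(model, self._features(15), catalytic=[7])
        assert ann[11].seq_dist_to_catalytic == 5  # residue 12
        assert ann[11].within_5aa_catalytic
        assert not ann[12].within_5aa_catalytic  # residue 13, distance 6

    def test_no_catalytic_residues_leaves_distances_undefined(self):
        model = make_model("m", 5)
        ann = annotate_residues(model, self._features(5), catalytic=[])
        assert all(a.seq_dist_to_catalytic is None for a in ann)
        assert all(a.spatial_dist_to_catalytic is None for a in ann)
        assert not any(a.within_5A_catalytic for a in ann)

    def test_within_5A_implies_within_15A(self):
        model = make_model("m", 40)
        ann = annotate_residues(model, self._features(40), catalytic=[1, 25])
        assert any(a.within_5A_catalytic for a in ann)
        for a in ann:
            if a.within_5A_catalytic:
                assert a.within_15A_catalytic

    def test_spatial_distance_from_line_geometry(self):
        # CA trace at 3.8 A spacing: residue 1 to residue 3 is 7.6 A
        model = make_model("m", 5)
        ann = annotate_residues(model, self._features(5), catalytic=[1])
        assert ann[2].spatial_dist_to_catalytic == pytest.approx(7.6)

    def test_ca_mode_uses_alpha_carbons(self):
        model = make_model("m", 5)
        ann = annotate_residues(
            model, self._features(5), catalytic=[1], spatial_mode="ca"
        )
        assert ann[1].spatial_dist_to_catalytic == pytest.approx(3.8)

    def test_hotspot_flag_follows_column_map(self):
        model = make_model("m", 6)
        ann = annotate_residues(
            model, self._features(6), catalytic=[], hotspot_columns={2, 3}
        )
        assert [a.is_hotspot for a in ann] == [False, True, True, False, False, False]

    def test_annotations_frame_exports_distances(self):
        model = make_model("m", 4)
        ann = annotate_residues(model, self._features(4), catalytic=[2])
        df = annotations_frame(ann)
        assert df.loc[0, "seq_dist_to_catalytic"] == 1


class TestRegionMapping:
    def _region(self, start, end):
        return HotspotRegion("PF1", start, end, (start,), 1e-9, 3.0)

    def test_fully_mapped_region(self):
        model = make_model("m", 20)
        m = map_hotspot_to_structure(self._region(8, 14), model)
        assert m.covered and m.residues == tuple(range(8, 15))
        assert m.unmapped_columns == ()

    def test_region_in_structure_gap(self):
        model = make_model("m", 20, columns={i + 1: i + 30 for i in range(20)})
        m = map_hotspot_to_structure(self._region(8, 14), model)
        assert not m.covered
        assert m.unmapped_columns == tuple(range(8, 15))

    def test_half_covered_region(self):
        cols = {i + 1: i + 1 for i in range(10)}  # columns 1..10 resolved
        model = make_model("m", 10, columns=cols)
        m = map_hotspot_to_structure(self._region(8, 14), model)
        assert m.covered
        assert m.residues == (8, 9, 10)
        assert m.unmapped_columns == (11, 12, 13, 14)

    def test_column_map_from_row_requires_sequence_match(self):
        model = make_model("m", 3, sequence="MKS")
        with pytest.raises(ValidationError):
            column_map_from_row(model, "M-KT")
        column_map_from_row(model, "M-KS")
        assert model.column_of_residue == {1: 1, 2: 3, 3: 4}

    def test_matched_ca_uses_shared_columns(self):
        a = make_model("a", 6)
        b = make_model("b", 4, columns={1: 3, 2: 4, 3: 5, 4: 6})
        ca, cb = matched_ca(a, b)
        assert ca.shape == (4, 3)
        np.testing.assert_allclose(ca, a.ca_coords[2:6])
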