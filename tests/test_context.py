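"""Solvent accessibility, location classes and secondary structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oncostruct import (
    SyntheticSpec,
    classify_location,
    collapse_ss8,
    compute_sasa,
    generate_chain,
    read_dssp,
    read_structure,
    relative_accessibility,
    residue_context_table,
)
from oncostruct.context import MAX_ASA_SCALES, assign_ss_fallback


class TestSasa:
    def test_isolated_residue_is_fully_exposed(self, three_residue_pdb, tmp_path):
        """A lone residue's SASA reaches (or exceeds) the reference max ASA.

        The reference scale is defined in a Gly-X-Gly context, whose
        flanking backbone shields part of the residue, so a residue with
        no neighbours at all must score at least ~fully exposed.
        """
        text = three_residue_pdb.read_text().splitlines()
        lone = tmp_path / "lone.pdb"
        lone.write_text("\n".join(line for line in text if " ALA " in line) + "\nEND\n")
        model = read_structure(lone)
        sasa = compute_sasa(model)
        rsa = relative_accessibility(model, sasa)
        assert rsa["A"][0] >= 0.9

    def test_buried_residue_has_low_rsa(self):
        """A residue at the centre of a dense atomic shell has RSA < 0.1."""
        from oncostruct.synthetic import _model_from_coords

        rng = np.random.default_rng(0)
        shell = []
        # two concentric shells so probe-sized gaps are closed
        for radius, count in ((4.0, 120), (6.5, 260)):
            v = rng.normal(size=(count, 3))
            shell.append(radius * v / np.linalg.norm(v, axis=1, keepdims=True))
        coords = np.vstack([[[0.0, 0.0, 0.0]], *shell])
        model = _model_from_coords(
            coords, "A" * len(coords), plddt=90.0, structure_id="buried"
        )
        sasa = compute_sasa(model)
        rsa = relative_accessibility(model, sasa)
        assert rsa["A"][0] < 0.1

    def test_point_count_convergence(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        coarse = compute_sasa(model, n_points=960)["A"]
        fine = compute_sasa(model, n_points=1920)["A"]
        assert np.all(np.abs(fine - coarse) / np.maximum(fine, 1e-9) < 0.02)

    def test_rigid_motion_invariance(self, three_residue_pdb, tmp_path):
        from scipy.spatial.transform import Rotation

        model = read_structure(three_residue_pdb)
        base = compute_sasa(model)["A"]
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = model.atoms.copy()
        moved.coord = (model.atoms.coord @ rot.T + [5.0, -3.0, 9.0]).astype(np.float32)
        model.atoms = moved
        after = compute_sasa(model)["A"]
        assert np.all(np.abs(after - base) / np.maximum(base, 1e-9) < 0.01)

    def test_no_atoms_is_error(self, compact_model):
        import copy

        model = copy.copy(compact_model)
        model.atoms = None
        with pytest.raises(ValueError):
            compute_sasa(model)


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "rsa,expected",
        [
            (0.30, "interior"),
            (0.40, "interface"),
            (0.50, "surface"),
            (0.0, "interior"),
            (0.299, "interior"),
            (0.499, "interface"),
            (1.7, "surface"),
        ],
    )
    def test_band_boundaries(self, rsa, expected):
        assert classify_location(rsa) == expected

    def test_negative_rsa_is_error(self):
        with pytest.raises(ValueError):
            classify_location(-0.01)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
    def test_total_partition(self, rsa):
        assert classify_location(rsa) in {"interior", "interface", "surface"}


def _dssp_line(serial, resnum, chain, aa, ss):
    return f"{serial:5d}{resnum:5d} {chain} {aa}  {ss}"


DSSP_HEADER = [
    "==== Secondary Structure Definition by the program DSSP ====",
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
]


class TestReadDssp:
    def test_codes_collapse_to_three_states(self, tmp_path):
        lines = DSSP_HEADER + [
            _dssp_line(1, 1, "A", "M", "H"),
            _dssp_line(2, 2, "A", "K", "G"),
            _dssp_line(3, 3, "A", "L", "I"),
            _dssp_line(4, 4, "A", "V", "E"),
            _dssp_line(5, 5, "A", "F", "B"),
            _dssp_line(6, 6, "A", "T", "T"),
            _dssp_line(7, 7, "A", "S", " "),
        ]
        path = tmp_path / "toy.dssp"
        path.write_text("\n".join(lines) + "\n")
        frame = read_dssp(path)
        assert frame["ss_class"].tolist() == [
            "helix", "helix", "helix", "strand", "strand", "other", "other",
        ]
        assert frame["author_number"].tolist() == list(range(1, 8))

    def test_chain_breaks_skipped(self, tmp_path):
        lines = DSSP_HEADER + [
            _dssp_line(1, 1, "A", "M", "H"),
            _dssp_line(2, 0, "", "!", " "),
            _dssp_line(3, 1, "B", "K", "E"),
        ]
        path = tmp_path / "breaks.dssp"
        path.write_text("\n".join(lines) + "\n")
        frame = read_dssp(path)
        assert len(frame) == 2
        assert frame["chain_id"].tolist() == ["A", "B"]

    def test_malformed_file_is_parse_error(self, tmp_path):
        path = tmp_path / "junk.dssp"
        path.write_text("not dssp at all\n")
        with pytest.raises(ValueError):
            read_dssp(path)

    @pytest.mark.parametrize(
        "code,expected",
        [("H", "helix"), ("E", "strand"), ("T", "other"), ("-", "other")],
    )
    def test_collapse_mapping(self, code, expected):
        assert collapse_ss8(code) == expected


class TestSsFallback:
    def test_ideal_helix_called_helix(self):
        model = generate_chain(
            SyntheticSpec(n_residues=30, chain_geometry="ideal_helix", seed=0),
            "helix",
        )
        ss = assign_ss_fallback(model, "A")
        interior = ss[2:-2]
        assert np.mean([s == "helix" for s in interior]) >= 0.8

    def test_extended_strand_never_called_helix(self):
        model = generate_chain(
            SyntheticSpec(n_residues=30, chain_geometry="line", seed=0), "line"
        )
        ss = assign_ss_fallback(model, "A")
        assert "helix" not in ss

    def test_chain_shorter_than_window_is_all_other(self):
        model = generate_chain(SyntheticSpec(n_residues=5, seed=0), "tiny")
        model.chains["A"] = model.chains["A"][:3]
        assert assign_ss_fallback(model, "A") == ["other"] * 3


class TestContextTable:
    def test_columns_and_modes(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        frame = residue_context_table(model)
        assert len(frame) == 3
        assert set(frame["location"]) <= {"interior", "interface", "surface"}
        assert (frame["rsa_scale"] == "tien2013").all()
        alt = residue_context_table(model, interface_mode="delta_rsa")
        # single chain: no burial upon assembly, so nothing is interface
        assert "interface" not in set(alt["location"])

    def test_miller_scale_changes_rsa_only(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        tien = residue_context_table(model, scale="tien2013")
        miller = residue_context_table(model, scale="miller1987")
        np.testing.assert_allclose(tien["sasa"], miller["sasa"])
        assert (miller["rsa"] >= tien["rsa"]).all()  # Miller maxima are smaller

    def test_scales_cover_all_twenty_amino_acids(self):
        for scale in MAX_ASA_SCALES.values():
            assert set(scale) == set("ACDEFGHIKLMNPQRSTVWY")
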