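"""ΔΔG table reading, model averaging, SNV reachability and ΔΔG_rank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oncostruct import (
    VariantKey,
    average_over_models,
    ddg_rank,
    enumerate_snv_reachable,
    read_foldx_output,
)


def _key(pos, ref, alt, pid="P1"):
    return VariantKey(pid, pos, ref, alt)


class TestReadFoldx:
    def test_replicates_averaged(self, tmp_path):
        path = tmp_path / "foldx.txt"
        path.write_text("KA12G\t1.0\nKA12G\t1.2\nKA12G\t1.4\nLA3M\t0.7\n")
        raw = read_foldx_output(path, protein_id="P1")
        assert raw[_key(12, "K", "G")] == pytest.approx(1.2)
        assert raw[_key(3, "L", "M")] == pytest.approx(0.7)

    def test_generic_csv_dialect(self, tmp_path):
        path = tmp_path / "table.csv"
        path.write_text(
            "protein_id,position,ref_aa,alt_aa,ddg,replicate\n"
            "P1,5,A,G,0.4,1\nP1,5,A,G,0.8,2\n"
        )
        raw = read_foldx_output(path)
        assert raw[_key(5, "A", "G")] == pytest.approx(0.6)

    def test_inconsistent_reference_is_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("AA12G\t1.0\nGA12L\t1.0\n")
        with pytest.raises(ValueError, match="inconsistent"):
            read_foldx_output(path, protein_id="P1")


class TestAverageOverModels:
    def test_mean_over_models_containing_variant(self):
        maps = [
            {_key(1, "A", "G"): 1.0, _key(2, "K", "R"): 0.4},
            {_key(1, "A", "G"): 3.0},
            {_key(3, "L", "M"): 5.0},
        ]
        averaged, counts = average_over_models(maps)
        assert averaged[_key(1, "A", "G")] == pytest.approx(2.0)
        assert counts[_key(1, "A", "G")] == 2
        assert averaged[_key(2, "K", "R")] == pytest.approx(0.4)
        assert counts[_key(3, "L", "M")] == 1

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            average_over_models([])

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            average_over_models(
                [{_key(1, "A", "G", "P1"): 1.0}, {_key(1, "A", "G", "P2"): 1.0}]
            )


class TestSnvReachability:
    @pytest.mark.parametrize(
        "codon,expected",
        [
            ("GGA", {"R", "E", "A", "V"}),
            ("ATG", {"L", "V", "K", "T", "R", "I"}),
        ],
    )
    def test_known_codon_neighbourhoods(self, codon, expected):
        assert enumerate_snv_reachable(codon) == expected

    def test_reachable_set_excludes_self_and_stop(self):
        reachable = enumerate_snv_reachable("TGG")  # Trp
        assert "W" not in reachable
        assert reachable <= set("ACDEFGHIKLMNPQRSTVY")

    def test_amino_acid_mode_is_union_over_codons(self):
        by_aa = enumerate_snv_reachable("G")
        union = set()
        for codon in ("GGA", "GGC", "GGG", "GGT"):
            union |= enumerate_snv_reachable(codon)
        assert by_aa == union

    @pytest.mark.parametrize("bad", ["TAA", "XYZ", "B"])
    def test_invalid_input_is_error(self, bad):
        with pytest.raises(ValueError):
            enumerate_snv_reachable(bad)


class TestDdgRank:
    def test_four_variant_hand_ranked_table(self):
        raw = {
            _key(1, "A", "G"): 0.1,
            _key(2, "A", "G"): 0.5,
            _key(3, "A", "G"): -1.2,
            _key(4, "A", "G"): 2.0,
        }
        table = ddg_rank(raw)
        ranks = table.ranks()
        assert ranks[_key(1, "A", "G")] == pytest.approx(0.0)
        assert ranks[_key(2, "A", "G")] == pytest.approx(1 / 3)
        assert ranks[_key(3, "A", "G")] == pytest.approx(2 / 3)
        assert ranks[_key(4, "A", "G")] == pytest.approx(1.0)

    def test_tied_values_get_average_ranks(self):
        raw = {
            _key(1, "A", "G"): 1.0,
            _key(2, "A", "G"): 1.0,
            _key(3, "A", "G"): 2.0,
        }
        ranks = ddg_rank(raw).ranks()
        assert ranks[_key(1, "A", "G")] == pytest.approx(0.25)
        assert ranks[_key(2, "A", "G")] == pytest.approx(0.25)
        assert ranks[_key(3, "A", "G")] == pytest.approx(1.0)
        assert np.mean(list(ranks.values())) == pytest.approx(0.5, abs=1e-15)

    def test_fewer_than_two_variants_is_error(self):
        with pytest.raises(ValueError):
            ddg_rank({_key(1, "A", "G"): 1.0})

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=50,
        ),
        st.booleans(),
    )
    def test_mean_is_half_regardless_of_ties(self, values, force_ties):
        if force_ties:
            values = [round(v, 1) for v in values]
        raw = {_key(i + 1, "A", "G"): v for i, v in enumerate(values)}
        ranks = np.array(list(ddg_rank(raw).ranks().values()))
        assert abs(ranks.mean() - 0.5) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(0.01, 10, allow_nan=False),
            min_size=2,
            max_size=40,
            unique=True,
        )
    )
    def test_invariance_under_monotone_transform(self, values):
        raw = {_key(i + 1, "A", "G"): v for i, v in enumerate(values)}
        transformed = {k: np.expm1(v) for k, v in raw.items()}  # monotone on >0
        ranks_a = ddg_rank(raw).ranks()
        ranks_b = ddg_rank(transformed).ranks()
        for key in raw:
            assert ranks_a[key] == pytest.approx(ranks_b[key], abs=1e-12)

    def test_ranking_matches_brute_force_resort(self):
        """Average-tie ranks agree with an independent argsort-based oracle."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = np.round(rng.normal(scale=2.0, size=rng.integers(2, 50)), 1)
            raw = {_key(i + 1, "A", "G"): v for i, v in enumerate(values)}
            got = ddg_rank(raw).ranks()
            # oracle: position-average of sorted |ddg| duplicates
            abs_vals = np.abs(values)
            order = np.argsort(abs_vals, kind="stable")
            rank_of = np.empty(len(values))
            i = 0
            while i < len(values):
                j = i
                while (
                    j + 1 < len(values)
                    and abs_vals[order[j + 1]] == abs_vals[order[i]]
                ):
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    rank_of[order[k]] = avg
                i = j + 1
            expected = (rank_of - 1) / (len(values) - 1)
            for idx, key in enumerate(sorted(raw, key=lambda k: k.position)):
                assert got[key] == pytest.approx(expected[idx], abs=1e-12)

    def test_snv_reachable_restriction_drops_unreachable(self):
        raw = {
            _key(1, "W", "P"): 1.0,  # W->P needs two nucleotide changes
            _key(1, "W", "R"): 2.0,
            _key(2, "A", "V"): 0.5,
            _key(2, "A", "E"): 1.5,
        }
        table = ddg_rank(raw, snv_reachable_only=True)
        assert _key(1, "W", "P") not in table.entries
        assert _key(1, "W", "R") in table.entries
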