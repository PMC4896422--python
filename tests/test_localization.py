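"""Propensity-guided segment placement and per-residue map bookkeeping."""

import itertools

import numpy as np
import pytest

from cdfragmap.deconvolution import FractionSet, SegmentCounts
from cdfragmap.localization import (CHOU_FASMAN, ResidueMap, assign_segments,
                                    _optimal_segments, _residue_scores,
                                    distorted_from_labels, fractions_from_map,
                                    load_propensity_table, max_component_shift)


def brute_force_best(n, hp, sp, n_a, h_tot, n_b, s_tot):
    """Enumerate every placement of the required segments (separated by at
    least one coil residue) and return the best propensity score."""
    def compositions(total, k, mn):
        if k == 0:
            if total == 0:
                yield []
            return
        for first in range(mn, total - mn * (k - 1) + 1):
            for rest in compositions(total - first, k - 1, mn):
                yield [first] + rest

    best = -np.inf
    type_orders = set(itertools.permutations(["H"] * n_a + ["S"] * n_b))
    for hl in compositions(h_tot, n_a, 4):
        for sl in compositions(s_tot, n_b, 2):
            for order in type_orders:
                for hperm in set(itertools.permutations(hl)):
                    for sperm in set(itertools.permutations(sl)):
                        hit, sit = iter(hperm), iter(sperm)
                        lengths = [(t, next(hit) if t == "H" else next(sit))
                                   for t in order]
                        k = len(lengths)
                        free = n - sum(l for _, l in lengths) - (k - 1)
                        if free < 0:
                            continue
                        for marks in itertools.combinations(range(free + k), k):
                            gaps, prev = [], -1
                            for m in marks:
                                gaps.append(m - prev - 1)
                                prev = m
                            gaps.append(free + k - 1 - prev)
                            pos, score = gaps[0], 0.0
                            for idx, (t, l) in enumerate(lengths):
                                arr = hp if t == "H" else sp
                                score += arr[pos:pos + l].sum()
                                pos += l + (1 if idx < k - 1 else 0) + gaps[idx + 1]
                            best = max(best, score)
    return best


class TestDPOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_dp_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 30))
        seq = "".join(rng.choice(list(CHOU_FASMAN.keys()), n))
        hp, sp = _residue_scores(seq, CHOU_FASMAN)
        n_a = int(rng.integers(0, 3))
        n_b = int(rng.integers(0, 2 if n_a else 3))
        if n_a + n_b == 0:
            n_a = 1
        h_tot = 0 if n_a == 0 else int(rng.integers(4 * n_a, 4 * n_a + 5))
        s_tot = 0 if n_b == 0 else int(rng.integers(2 * n_b, 2 * n_b + 3))
        if h_tot + s_tot + n_a + n_b > n + 1:
            pytest.skip("infeasible draw")
        segments = _optimal_segments(n, hp, sp, n_a, h_tot, n_b, s_tot)
        score = sum((hp if lab == "H" else sp)[a:b].sum()
                    for a, b, lab in segments)
        assert score == pytest.approx(
            brute_force_best(n, hp, sp, n_a, h_tot, n_b, s_tot), abs=1e-4)


class TestAssignSegments:
    def test_full_helix_coverage(self):
        f = FractionSet(0.8, 0.2, 0, 0, 0, 0)
        m = assign_segments("A" * 20, f, SegmentCounts(1, 0))
        assert "".join(m.labels) == "H" * 20
        # two distorted residues at each helix end (1-based 1,2,19,20)
        assert list(np.where(m.distorted_mask)[0] + 1) == [1, 2, 19, 20]

    def test_no_structure_gives_all_coil(self):
        f = FractionSet(0, 0, 0, 0, 0.3, 0.7)
        m = assign_segments("ACDEFGHIKLMNPQRSTVWY", f, SegmentCounts(0, 0))
        assert set(m.labels) == {"O"}
        assert not m.distorted_mask.any()

    def test_helix_blocks_chosen_over_glycine_linker(self):
        # alanine favours helix (P=1.42), glycine breaks it (P=0.57):
        # 20 helix residues in 2 segments land exactly on the A blocks
        seq = "A" * 10 + "G" * 10 + "A" * 10
        f = FractionSet(12 / 30, 8 / 30, 0, 0, 0, 10 / 30)
        m = assign_segments(seq, f, SegmentCounts(2, 0))
        assert "".join(m.labels) == "H" * 10 + "O" * 10 + "H" * 10

    def test_determinism(self, small_protein):
        f = small_protein.fractions
        counts = SegmentCounts(6, 3)
        a = assign_segments(small_protein.sequence, f, counts)
        b = assign_segments(small_protein.sequence, f, counts)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.distorted_mask, b.distorted_mask)

    def test_infeasible_totals_name_the_bound(self):
        f = FractionSet(0.05, 0.01, 0, 0, 0, 0.94)   # 6 residues of helix
        with pytest.raises(ValueError, match="helix content"):
            assign_segments("A" * 100, f, SegmentCounts(2, 0))

    def test_content_without_segments_is_an_error_when_strict(self):
        f = FractionSet(0, 0, 0.02, 0, 0, 0.98)      # 2 strand residues
        with pytest.raises(ValueError, match="n_beta == 0"):
            assign_segments("A" * 100, f, SegmentCounts(0, 0))

    def test_non_strict_reconciles_marginal_infeasibility(self):
        f = FractionSet(0, 0, 0.02, 0, 0, 0.98)
        m = assign_segments("A" * 100, f, SegmentCounts(0, 0), strict=False)
        assert set(m.labels) == {"O"}

    def test_contract_roundtrip_on_randomized_inputs(self):
        # CD-derived fractions vs fractions implied by the assigned map:
        # each component moves by less than 0.03
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(150, 300))
            f_rH = rng.uniform(0.15, 0.45)
            f_dH = rng.uniform(0.05, 0.2)
            f_rS = rng.uniform(0.0, 0.08)
            f_dS = rng.uniform(0.0, 0.08)
            rest = 1 - f_rH - f_dH - f_rS - f_dS
            f = FractionSet(f_rH, f_dH, f_rS, f_dS, 0.3 * rest, 0.7 * rest)
            from cdfragmap.deconvolution import estimate_segment_counts
            counts = estimate_segment_counts(f, n)
            seq = "".join(rng.choice(list(CHOU_FASMAN.keys()), n))
            m = assign_segments(seq, f, counts, strict=False)
            assert max_component_shift(f, fractions_from_map(m)) <= 0.03
            m.validate()


class TestResidueMap:
    def test_fractions_from_single_helix_by_hand(self):
        # a 10-residue helix in a 20-residue chain: 4 distorted + 6 regular
        labels = np.array(list("O" * 5 + "H" * 10 + "O" * 5))
        m = ResidueMap(labels, distorted_from_labels(labels))
        f = fractions_from_map(m)
        assert f.f_rH == pytest.approx(0.3)
        assert f.f_dH == pytest.approx(0.2)
        assert f.f_T == 0.0
        assert f.f_D == pytest.approx(0.5)

    def test_all_coil_map(self):
        m = ResidueMap.from_labels("O" * 50)
        f = fractions_from_map(m)
        assert f.f_D == 1.0
        assert f.helix == 0.0

    def test_strand_runs_have_one_distorted_residue_per_end(self):
        m = ResidueMap.from_labels("OOSSSSOO")
        assert list(np.where(m.distorted_mask)[0]) == [2, 5]

    def test_validate_rejects_short_runs(self):
        labels = np.array(list("OHHHOO"))
        m = ResidueMap(labels, distorted_from_labels(labels))
        with pytest.raises(ValueError, match="helix run"):
            m.validate()

    def test_run_length_string(self):
        m = ResidueMap.from_labels("OOHHHHSSOO")
        assert m.run_length_string() == "O2-H4-S2-O2"

    def test_tsv_round_trip_columns(self, tmp_path):
        m = ResidueMap.from_labels("OHHHHO")
        m.to_tsv(tmp_path / "map.tsv", sequence="MKVALE")
        lines = (tmp_path / "map.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["position", "aa", "label", "distorted"]
        assert lines[2].split("\t") == ["2", "K", "H", "1"]


def test_propensity_table_loader(tmp_path):
    path = tmp_path / "prop.tsv"
    path.write_text("aa\thelix\tstrand\nA\t1.5\t0.7\nG\t0.5\t0.8\n")
    table = load_propensity_table(path)
    assert table["A"] == (1.5, 0.7)
    seq = "AAAAGGGG"
    f = FractionSet(0.25, 0.25, 0, 0, 0, 0.5)
    m = assign_segments(seq, f, SegmentCounts(1, 0), propensity=table)
    assert "".join(m.labels) == "HHHHOOOO"
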