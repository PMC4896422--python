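"""Edge trimming, majority-vote consensus, and difference spectroscopy."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdfragmap.consensus import (FragmentDef, NonNativeFragmentWarning,
                                 consensus_map, difference_spectrum,
                                 load_fragment_table, region_fractions,
                                 trim_edges)
from cdfragmap.localization import ResidueMap
from cdfragmap.spectra import CANONICAL_GRID, Spectrum


def spec(values, sid="s"):
    return Spectrum(CANONICAL_GRID.copy(), np.asarray(values, dtype=float),
                    sample_id=sid, units="delta_epsilon")


class TestTrimEdges:
    def test_trim_arithmetic(self):
        frag = FragmentDef("f", 10, 21)          # 12 residues
        m = ResidueMap.from_labels("O" * 12)
        partial = trim_edges(m, frag, trim=5)
        assert partial.labels.size == 2
        assert list(partial.positions()) == [15, 16]

    def test_tiny_fragment_trims_to_empty_without_error(self):
        frag = FragmentDef("f", 1, 10)
        partial = trim_edges(ResidueMap.from_labels("O" * 10), frag, trim=5)
        assert partial.labels.size == 0

    def test_zero_trim_is_identity_placement(self):
        frag = FragmentDef("f", 3, 8)
        m = ResidueMap.from_labels("HHHHSS")
        partial = trim_edges(m, frag, trim=0)
        assert list(partial.positions()) == [3, 4, 5, 6, 7, 8]
        assert "".join(partial.labels) == "HHHHSS"

    def test_negative_trim_rejected(self):
        with pytest.raises(ValueError):
            trim_edges(ResidueMap.from_labels("O" * 10),
                       FragmentDef("f", 1, 10), trim=-1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="map has"):
            trim_edges(ResidueMap.from_labels("O" * 9),
                       FragmentDef("f", 1, 10), trim=0)


class TestConsensusMap:
    def test_zero_fragments_returns_parent(self):
        parent = ResidueMap.from_labels("OOHHHHOOSSOO")
        cons, cov = consensus_map(parent, [])
        assert np.array_equal(cons.labels, parent.labels)
        assert np.all(cov == 1)

    def test_agreeing_fragments_leave_parent_unchanged(self):
        parent = ResidueMap.from_labels("OOHHHHHHHHOO")
        frags = []
        for start, end in ((1, 12), (2, 11)):
            sub = ResidueMap.from_labels("".join(parent.labels[start - 1:end]))
            frags.append((FragmentDef(f"f{start}", start, end), sub))
        cons, cov = consensus_map(parent, frags, trim=1)
        assert np.array_equal(cons.labels, parent.labels)
        assert cov.max() == 3

    def test_vote_patterns_match_enumerated_oracle(self):
        # all voter patterns with <= 2 covering fragments: majority label
        # wins; ties (including 1-vs-1) go to the parent
        for parent_lab, f1, f2 in itertools.product("HSO", repeat=3):
            votes = [parent_lab, f1, f2]
            counts = {lab: votes.count(lab) for lab in "HSO"}
            top = max(counts.values())
            winners = {lab for lab, c in counts.items() if c == top}
            expected = parent_lab if parent_lab in winners else winners.pop()

            parent = ResidueMap.from_labels(parent_lab * 8)
            frags = [
                (FragmentDef("a", 1, 8), ResidueMap.from_labels(f1 * 8)),
                (FragmentDef("b", 1, 8), ResidueMap.from_labels(f2 * 8)),
            ]
            cons, cov = consensus_map(parent, frags, trim=0)
            assert cons.labels[4] == expected, (parent_lab, f1, f2)
            assert np.all(cov == 3)

    def test_consensus_label_always_in_vote_set(self):
        rng = np.random.default_rng(3)
        labs = np.array(list("HSO"))
        for _ in range(20):
            n = 15
            parent = ResidueMap.from_labels(rng.choice(labs, n))
            frags = []
            for k in range(int(rng.integers(1, 4))):
                start = int(rng.integers(1, n - 3))
                end = int(rng.integers(start + 2, n + 1))
                sub = ResidueMap.from_labels(rng.choice(labs, end - start + 1))
                frags.append((FragmentDef(f"f{k}", start, end), sub))
            cons, cov = consensus_map(parent, frags, trim=0)
            for i in range(n):
                votes = {str(parent.labels[i])}
                for frag, fmap in frags:
                    if frag.start <= i + 1 <= frag.end:
                        votes.add(str(fmap.labels[i + 1 - frag.start]))
                assert str(cons.labels[i]) in votes

    def test_removing_agreeing_fragment_never_changes_consensus(self):
        rng = np.random.default_rng(9)
        labs = np.array(list("HSO"))
        for _ in range(10):
            n = 20
            parent = ResidueMap.from_labels(rng.choice(labs, n))
            disagree = (FragmentDef("d", 1, n),
                        ResidueMap.from_labels(rng.choice(labs, n)))
            agree = (FragmentDef("a", 1, n),
                     ResidueMap.from_labels("".join(parent.labels)))
            with_dup, _ = consensus_map(parent, [disagree, agree], trim=0)
            without, _ = consensus_map(parent, [disagree], trim=0)
            assert np.array_equal(with_dup.labels, without.labels)

    def test_non_native_fragments_are_ignored(self):
        parent = ResidueMap.from_labels("H" * 8)
        bad = (FragmentDef("bad", 1, 8, native_flag=False),
               ResidueMap.from_labels("O" * 8))
        cons, cov = consensus_map(parent, [bad, bad], trim=0)
        assert "".join(cons.labels) == "H" * 8
        assert np.all(cov == 1)

    def test_fragment_beyond_parent_bounds_rejected(self):
        parent = ResidueMap.from_labels("O" * 10)
        frag = (FragmentDef("f", 5, 14), ResidueMap.from_labels("O" * 10))
        with pytest.raises(ValueError, match="beyond parent"):
            consensus_map(parent, [frag], trim=0)


class TestDifferenceSpectrum:
    def test_equal_constant_spectra_are_a_fixed_point(self):
        parent = spec(np.full(86, 3.7))
        frag = spec(np.full(86, 3.7))
        out = difference_spectrum(parent, 355, frag, 300)
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(30, 340))
    def test_inverts_length_weighted_mixing_exactly(self, seed, n_frag):
        # parent spectrum built as the length-weighted mix of region and
        # fragment spectra; the difference operator must return the region
        # spectrum to machine precision
        rng = np.random.default_rng(seed)
        n_parent = 355
        s_frag = rng.normal(0, 8, 86)
        s_region = rng.normal(0, 8, 86)
        mixed = (n_frag * s_frag + (n_parent - n_frag) * s_region) / n_parent
        out = difference_spectrum(spec(mixed), n_parent, spec(s_frag), n_frag)
        np.testing.assert_allclose(out.values, s_region, atol=1e-12 * 8 * 355)

    def test_degenerate_counts_rejected(self):
        s = spec(np.zeros(86))
        with pytest.raises(ValueError, match="divides by"):
            difference_spectrum(s, 100, s, 100)
        with pytest.raises(ValueError, match="larger than parent"):
            difference_spectrum(s, 100, s, 150)
        with pytest.raises(ValueError, match="positive"):
            difference_spectrum(s, 100, s, 0)


class TestRegionFractions:
    def test_pure_helix_region_recovered(self, basis, clean_refs):
        # construct a parent whose extra region is pure regular helix
        rng = np.random.default_rng(17)
        B = basis.matrix()
        f_frag = rng.dirichlet([3, 2, 1, 1, 1.5, 2.5])
        region = np.eye(6)[0]                      # pure rH
        n_parent, n_frag = 355, 300
        frag_vals = B @ f_frag
        parent_vals = (n_frag * frag_vals + (n_parent - n_frag) * (B @ region)) \
            / n_parent
        fit = region_fractions(spec(parent_vals), n_parent,
                               spec(frag_vals), n_frag, clean_refs)
        assert fit.valid
        assert fit.n_region == 55
        assert fit.fractions.f_rH >= 0.95

    def test_non_native_flag_produces_warning(self, basis, clean_refs):
        B = basis.matrix()
        f = np.array([0.4, 0.22, 0.02, 0.06, 0.09, 0.21])
        parent_vals = B @ f
        frag_vals = B @ f
        with pytest.warns(NonNativeFragmentWarning):
            fit = region_fractions(spec(parent_vals), 355, spec(frag_vals),
                                   300, clean_refs, frag_native=False)
        assert not fit.valid
        assert fit.warnings


def test_fragment_table_round_trip(tmp_path):
    path = tmp_path / "frags.tsv"
    path.write_text("id\tstart\tend\tnative_flag\n"
                    "fA\t1\t120\t1\n"
                    "fB\t40\t355\t0\n")
    frags = load_fragment_table(path)
    assert [f.id for f in frags] == ["fA", "fB"]
    assert frags[0].n_residues == 120
    assert frags[1].native_flag is False


def test_fragment_def_invariants():
    with pytest.raises(ValueError):
        FragmentDef("x", 0, 10)
    with pytest.raises(ValueError):
        FragmentDef("x", 10, 5)
    FragmentDef("x", 2, 9).check_within(9)
    with pytest.raises(ValueError, match="beyond parent"):
        FragmentDef("x", 2, 10).check_within(9)
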