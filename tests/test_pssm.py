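import math

import numpy as np
import pytest

import profscan as ps
from profscan.pssm import (GAP, HALF_BIT, MasterSlaveMSA, _block_bounds,
                           _distinct_types, build_msa, effective_observations,
                           position_based_weights, pssm_from_msa)
from profscan.sequences import AA_INDEX, AMINO_ACIDS

from oracles import brute_local_score


def seq(sid, residues):
    return ps.ProteinSequence(id=sid, residues=residues)


def profile_rows_for(master, matrix):
    return [[int(matrix.scores[AA_INDEX[a], b]) for b in range(21)]
            for a in master]


class TestAlignToMaster:
    def test_self_alignment_scores_diagonal_sum(self, blosum62):
        master = seq("m", "MKVLAWCD")
        aln = ps.align_to_master(master, master, blosum62)
        assert aln.score == sum(blosum62.score(c, c) for c in master.residues)
        assert (aln.master_start, aln.master_end) == (1, 8)
        assert aln.columns == {i + 1: AA_INDEX[c]
                               for i, c in enumerate(master.residues)}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_tiny_pairs(self, seed, blosum62):
        rng = np.random.Generator(np.random.Philox(seed))
        m = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, size=rng.integers(2, 9)))
        s = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, size=rng.integers(2, 9)))
        aln = ps.align_to_master(seq("m", m), seq("s", s), blosum62)
        want = brute_local_score(profile_rows_for(m, blosum62),
                                 [AA_INDEX[c] for c in s], 11, 1)
        assert aln.score == want

    def test_no_positive_pair_gives_empty_alignment(self, blosum62):
        aln = ps.align_to_master(seq("m", "WWWW"), seq("s", "PPPP"), blosum62)
        assert aln.empty and aln.columns == {}

    def test_all_x_member_flagged_empty(self, blosum62, caplog):
        aln = ps.align_to_master(seq("m", "MKVLAW"), seq("s", "XXXX"), blosum62)
        assert aln.empty


class TestBuildMsa:
    def test_single_member_family(self, blosum62):
        fam = ps.FamilySeedSet(family="f", members=[seq("m", "MKVLAW")],
                               master_id="m")
        msa = build_msa(fam, blosum62)
        assert msa.member_ids == ["m"]
        assert np.all(msa.rows["m"] >= 0)  # gap-free
        assert msa.length == 6

    def test_two_identical_members(self, blosum62):
        fam = ps.FamilySeedSet(family="f",
                               members=[seq("a", "MKVLAWCD"), seq("b", "MKVLAWCD")],
                               master_id="a")
        msa = build_msa(fam, blosum62)
        assert np.array_equal(msa.rows["a"], msa.rows["b"])

    def test_divergent_members_all_covered(self, small_family, blosum62):
        msa = build_msa(small_family, blosum62)
        assert set(msa.member_ids) == {m.id for m in small_family.members}
        # master row equals master residues
        assert np.array_equal(msa.rows[msa.master.id], msa.master.encoded())

    def test_short_fragment_excluded_by_coverage(self, blosum62):
        master = seq("m", "MKVLAWCDEFGHIKNP")
        frag = seq("frag", "MKVL")  # 25% of master
        fam = ps.FamilySeedSet(family="f", members=[master, frag], master_id="m")
        msa = build_msa(fam, blosum62, min_coverage=0.5)
        assert msa.member_ids == ["m"]

    def test_degenerate_family_raises(self, blosum62):
        master = seq("m", "XXXXXXXX")
        fam = ps.FamilySeedSet(family="f", members=[master], master_id="m")
        with pytest.raises(ValueError, match="degenerate"):
            build_msa(fam, blosum62)

    def test_member_order_permutation_equivariance(self, small_family, blosum62):
        fam2 = ps.FamilySeedSet(family="famA",
                                members=list(reversed(small_family.members)),
                                master_id=small_family.master_id)
        a = pssm_from_msa(build_msa(small_family, blosum62), blosum62)
        b = pssm_from_msa(build_msa(fam2, blosum62), blosum62)
        assert np.array_equal(a.scores, b.scores)


def toy_msa(rows, master="AA"):
    """Rows as residue strings in master coordinates ('-' gap, '.' absent)."""
    master_seq = seq("r0", master)
    codes = {}
    ids = []
    for k, r in enumerate(rows):
        rid = f"r{k}"
        ids.append(rid)
        arr = np.empty(len(master), dtype=np.int8)
        for i, c in enumerate(r):
            arr[i] = GAP if c == "-" else (-2 if c == "." else AA_INDEX[c])
        codes[rid] = arr
    return MasterSlaveMSA(master=master_seq, member_ids=ids, rows=codes)


class TestWeights:
    def test_identical_rows_uniform(self):
        msa = toy_msa(["AA", "AA", "AA", "AA"])
        w = position_based_weights(msa)
        assert all(abs(v - 0.25) < 1e-12 for v in w.values())

    def test_two_rows_always_half(self):
        msa = toy_msa(["AC", "WY"], master="AC")
        w = position_based_weights(msa)
        assert all(abs(v - 0.5) < 1e-12 for v in w.values())

    def test_hand_computed_three_row_example(self):
        # cols: {A,A,A} -> r=1,s=3: 1/3 each; {A,A,C} -> A: 1/(2*2), C: 1/(2*1)
        msa = toy_msa(["AA", "AA", "AC"])
        w = position_based_weights(msa)
        raw = {"r0": (1 / 3 + 1 / 4) / 2, "r1": (1 / 3 + 1 / 4) / 2,
               "r2": (1 / 3 + 1 / 2) / 2}
        total = sum(raw.values())
        for rid, v in raw.items():
            assert abs(w[rid] - v / total) < 1e-12
        assert abs(sum(w.values()) - 1.0) < 1e-12


class TestEffectiveObservations:
    def test_identical_column_block(self):
        msa = toy_msa(["AA", "AA"])
        assert effective_observations(msa, 0) == 1.0

    def test_mixed_block_mean(self):
        msa = toy_msa(["AA", "AC"])
        assert effective_observations(msa, 0) == 1.5
        assert effective_observations(msa, 1) == 1.5

    def test_matches_independent_recount(self, blosum62):
        rng = np.random.Generator(np.random.Philox(3))
        rows = ["".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, size=12))
                for _ in range(10)]
        msa = toy_msa(rows, master=rows[0])
        # full coverage -> single block; mean distinct types over columns
        expect = np.mean([len({r[c] for r in rows}) for c in range(12)])
        assert abs(effective_observations(msa, 5) - expect) < 1e-12

    def test_blocks_split_on_coverage_change(self):
        msa = toy_msa(["AAAA", "AC.."], master="AAAA")
        bounds = _block_bounds(msa)
        assert bounds[0] == (0, 1) and bounds[2] == (2, 3)
        assert effective_observations(msa, 0) == 1.5  # {A,A}, {A,C}: (1+2)/2
        assert effective_observations(msa, 2) == 1.0


class TestPseudoFrequencies:
    def test_beta_zero_returns_observed(self, blosum62):
        f = np.zeros(20)
        f[AA_INDEX["A"]] = 0.5
        f[AA_INDEX["W"]] = 0.5
        q = ps.pseudo_frequencies(f, blosum62, alpha=3.0, beta=0.0)
        assert np.allclose(q, f)

    def test_alpha_zero_returns_matrix_target(self, blosum62):
        f = np.zeros(20)
        f[AA_INDEX["A"]] = 1.0
        q = ps.pseudo_frequencies(f, blosum62, alpha=0.0, beta=5.0)
        lam = blosum62.ungapped_lambda
        g = blosum62.background_freqs * np.exp(
            lam * blosum62.scores[:20, AA_INDEX["A"]].astype(float))
        g = g / g.sum()
        assert np.allclose(q, g)

    def test_mixture_formula_direct_evaluation(self, blosum62):
        f = np.zeros(20)
        f[AA_INDEX["A"]] = 1.0
        q = ps.pseudo_frequencies(f, blosum62, alpha=1.0, beta=10.0)
        lam = blosum62.ungapped_lambda
        g = blosum62.background_freqs * np.exp(
            lam * blosum62.scores[:20, AA_INDEX["A"]].astype(float))
        g = g / g.sum()
        want = (1.0 * f + 10.0 * g) / 11.0
        assert np.allclose(q, want / want.sum())
        assert abs(q.sum() - 1.0) < 1e-9
        assert (q > 0).all()

    def test_degenerate_mixture_rejected(self, blosum62):
        f = np.full(20, 0.05)
        with pytest.raises(ValueError):
            ps.pseudo_frequencies(f, blosum62, alpha=0.0, beta=0.0)


class TestPssmFromMsa:
    @pytest.mark.parametrize("seed", range(5))
    def test_single_sequence_argmax_is_master_residue(self, seed, blosum62):
        rng = np.random.Generator(np.random.Philox(seed))
        residues = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, size=40))
        fam = ps.FamilySeedSet(family="f", members=[seq("m", residues)],
                               master_id="m")
        pssm = pssm_from_msa(build_msa(fam, blosum62), blosum62)
        for i, c in enumerate(residues):
            assert AMINO_ACIDS[int(pssm.scores[i].argmax())] == c

    def test_background_frequencies_score_zero(self, blosum62):
        # alpha huge, beta tiny: Q ~= observed = background -> log-odds 0
        q = ps.pseudo_frequencies(blosum62.background_freqs, blosum62,
                                  alpha=1e9, beta=1.0)
        scores = np.round(np.log(q / blosum62.background_freqs) / HALF_BIT)
        assert np.all(scores == 0)

    def test_row_normalization_invariant(self, small_pssm):
        norm = small_pssm.row_normalization()
        assert norm.min() >= 0.8 and norm.max() <= 1.25

    def test_row_frequencies_sum_to_one(self, small_pssm):
        assert np.allclose(small_pssm.weighted_freqs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_rows_equal_single_copy(self, blosum62):
        members = [seq(f"m{k}", "MKVLAWCDEFGH") for k in range(4)]
        fam_n = ps.FamilySeedSet(family="f", members=members, master_id="m0")
        fam_1 = ps.FamilySeedSet(family="f", members=members[:1], master_id="m0")
        p_n = pssm_from_msa(build_msa(fam_n, blosum62), blosum62)
        p_1 = pssm_from_msa(build_msa(fam_1, blosum62), blosum62)
        assert np.array_equal(p_n.scores, p_1.scores)

    def test_self_positive_scores_on_master_residues(self, blosum62):
        residues = "MKVWCDEF"  # all with positive BLOSUM62 self-score
        fam = ps.FamilySeedSet(family="f", members=[seq("m", residues)],
                               master_id="m")
        pssm = pssm_from_msa(build_msa(fam, blosum62), blosum62, beta=0.0)
        for i, c in enumerate(residues):
            assert pssm.scores[i, AA_INDEX[c]] > 0


class TestPssmIO:
    def test_round_trip_identity(self, small_pssm, tmp_path):
        p = tmp_path / "fam.pssm"
        ps.write_pssm(small_pssm, p)
        back = ps.read_pssm(p)
        assert back.family == small_pssm.family
        assert back.length == small_pssm.length
        assert back.consensus == small_pssm.consensus
        assert np.array_equal(back.scores, small_pssm.scores)
        assert np.allclose(back.weighted_freqs, small_pssm.weighted_freqs,
                           atol=5e-5)
        for attr in ("scale_lambda", "stats_lambda", "gapped_K", "gap_open",
                     "gap_extend", "pseudocount_beta"):
            assert getattr(back, attr) == getattr(small_pssm, attr)
        # write-read-write is byte identical
        p2 = tmp_path / "fam2.pssm"
        ps.write_pssm(back, p2)
        assert p.read_text() == p2.read_text()

    def test_length_mismatch_rejected(self, small_pssm, tmp_path):
        p = tmp_path / "fam.pssm"
        ps.write_pssm(small_pssm, p)
        text = p.read_text().replace(f"# length:{small_pssm.length}",
                                     f"# length:{small_pssm.length + 3}")
        p.write_text(text)
        with pytest.raises(ValueError, match="rows"):
            ps.read_pssm(p)

    def test_truncated_header_rejected(self, tmp_path):
        p = tmp_path / "bad.pssm"
        p.write_text("# profscan-pssm v1\n# family:f\n")
        with pytest.raises(ValueError):
            ps.read_pssm(p)

    def test_hand_written_two_column_file(self, tmp_path, blosum62):
        scores_a = " ".join(["6"] + ["-2"] * 19).split()
        scores_c = " ".join(["-2"] + ["8"] + ["-3"] * 18).split()
        freqs = [f"{v:.4f}" for v in blosum62.background_freqs]
        bg = ",".join(repr(float(v)) for v in blosum62.background_freqs)
        lines = ["# profscan-pssm v1", "# family:toy", "# length:2",
                 "# lambda:0.34657359027997264", "# stats_lambda:0.267",
                 "# K:0.041", "# gap:11,1", "# beta:10.0",
                 "# background:" + bg]
        lines.append("\t".join(["1", "A"] + scores_a + freqs))
        lines.append("\t".join(["2", "C"] + scores_c + freqs))
        p = tmp_path / "toy.pssm"
        p.write_text("\n".join(lines) + "\n")
        pssm = ps.read_pssm(p)
        assert pssm.family == "toy" and pssm.length == 2
        assert pssm.scores[0, 0] == 6 and pssm.scores[1, 1] == 8
        assert pssm.consensus == "AC"
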