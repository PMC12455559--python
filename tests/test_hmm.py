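import numpy as np
import pytest

from petscreen.alphabet import AA_INDEX, UNIFORM_BACKGROUND
from petscreen.hmm import ProfileHMM, build_profile, normalize_scores, tune_hmm
from petscreen.seqio import Alignment, SequenceRecord

LN2 = np.log(2.0)


def enumerate_forward_odds(hmm: ProfileHMM, seq: str) -> float:
    """Independent oracle: sum of path probabilities (odds vs background) over
    every legal Begin -> ... -> End state path, by explicit recursion."""
    L = hmm.L
    me, ie, tr, bg = hmm.match_emissions, hmm.insert_emissions, hmm.transitions, hmm.background
    x = [AA_INDEX[c] for c in seq]
    n = len(x)

    def emit_m(k, t):
        return me[k, x[t]] / bg[x[t]]

    def emit_i(t):
        return ie[x[t]] / bg[x[t]]

    def rec(kind, node, t):
        # total odds of completing the path from state (kind, node) with t residues emitted
        total = 0.0
        s = {"M": 0, "I": 1, "D": 2}[kind]
        # to End (only from node L)
        if node == L and t == n:
            total += tr[L, s, 0]
        # to M(node+1)
        if node < L and t < n:
            total += tr[node, s, 0] * emit_m(node + 1, t) * rec("M", node + 1, t + 1)
        # to I(node)
        if t < n:
            total += tr[node, s, 1] * emit_i(t) * rec("I", node, t + 1)
        # to D(node+1)
        if node < L:
            total += tr[node, s, 2] * rec("D", node + 1, t)
        return total

    return rec("M", 0, 0)


def random_tiny_hmm(rng, L):
    me = np.zeros((L + 1, 20))
    me[1:] = rng.dirichlet(np.ones(20), size=L)
    ie = rng.dirichlet(np.ones(20))
    tr = rng.random((L + 1, 3, 3))
    tr[0, 2, :] = 0.0  # no delete state at Begin
    tr[L, :, 2] = 0.0  # no delete past the last node
    sums = tr.sum(axis=2, keepdims=True)
    sums[sums == 0] = 1.0
    tr = tr / sums
    return ProfileHMM(L=L, match_emissions=me, insert_emissions=ie, transitions=tr, mode="global")


def single_match_hmm(residue="A", mode="global"):
    me = np.zeros((2, 20))
    me[1, AA_INDEX[residue]] = 1.0
    tr = np.zeros((2, 3, 3))
    tr[0, 0, 0] = 1.0
    tr[1, 0, 0] = 1.0
    return ProfileHMM(
        L=1,
        match_emissions=me,
        insert_emissions=UNIFORM_BACKGROUND.copy(),
        transitions=tr,
        mode=mode,
    )


class TestForward:
    def test_single_match_closed_form(self):
        hmm = single_match_hmm("A")
        assert hmm.bit_score("A") == pytest.approx(np.log2(20.0), abs=1e-12)

    def test_background_emissions_score_zero(self):
        L = 4
        me = np.zeros((L + 1, 20))
        me[1:] = UNIFORM_BACKGROUND
        tr = np.zeros((L + 1, 3, 3))
        tr[:, 0, 0] = 1.0
        hmm = ProfileHMM(
            L=L,
            match_emissions=me,
            insert_emissions=UNIFORM_BACKGROUND.copy(),
            transitions=tr,
            mode="global",
        )
        assert hmm.bit_score("MKVL") == pytest.approx(0.0, abs=1e-12)

    def test_forward_equals_path_enumeration(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 4))
            hmm = random_tiny_hmm(rng, L)
            n = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
            oracle = enumerate_forward_odds(hmm, seq)
            got = hmm.bit_score(seq) * LN2  # back to nats
            if oracle == 0.0:
                assert got == -np.inf
            else:
                assert got == pytest.approx(np.log(oracle), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            single_match_hmm().bit_score("")

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            single_match_hmm().bit_score("A1")

    def test_x_scores_as_background(self):
        hmm = single_match_hmm("A")
        # X emits at background odds: only transition structure contributes
        assert hmm.bit_score("X") == pytest.approx(0.0, abs=1e-12)

    def test_background_sequences_mean_nonpositive(self, rng):
        aln = Alignment(
            [
                SequenceRecord("a", "MKVLAWGT"),
                SequenceRecord("b", "MKVLAWGS"),
                SequenceRecord("c", "MRVLAWGT"),
            ]
        )
        hmm = build_profile(aln, mode="global")
        scores = []
        for _ in range(60):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8))
            scores.append(hmm.bit_score(seq))
        assert np.mean(scores) <= 0.0


class TestBuildProfile:
    def test_laplace_closed_form(self):
        n, alpha = 4, 1.0
        aln = Alignment([SequenceRecord(f"s{i}", "AAA") for i in range(n)])
        hmm = build_profile(aln, pseudocount=alpha)
        expected = (n + alpha) / (n + 20 * alpha)
        for k in range(1, 4):
            assert hmm.match_emissions[k, AA_INDEX["A"]] == pytest.approx(expected)

    def test_gappy_column_becomes_insert(self):
        rows = [
            SequenceRecord("a", "M-K"),
            SequenceRecord("b", "MAK"),
            SequenceRecord("c", "M-K"),
            SequenceRecord("d", "M-K"),
            SequenceRecord("e", "M-K"),
        ]
        hmm = build_profile(Alignment(rows), match_gap_threshold=0.5)
        assert hmm.L == 2
        assert hmm.match_columns == [0, 2]

    def test_three_row_toy_hand_computed(self):
        # rows: MK, M-, MR ; column 2 has gap fraction 1/3 <= 0.5 -> match
        aln = Alignment(
            [SequenceRecord("a", "MK"), SequenceRecord("b", "M-"), SequenceRecord("c", "MR")]
        )
        hmm = build_profile(aln, pseudocount=1.0, transition_pseudocount=1.0)
        assert hmm.L == 2
        # match 1 emissions: 3 M observed -> (3+1)/(3+20)
        assert hmm.match_emissions[1, AA_INDEX["M"]] == pytest.approx(4 / 23)
        assert hmm.match_emissions[1, AA_INDEX["K"]] == pytest.approx(1 / 23)
        # match 2: K and R observed once each -> (1+1)/(2+20)
        assert hmm.match_emissions[2, AA_INDEX["K"]] == pytest.approx(2 / 22)
        assert hmm.match_emissions[2, AA_INDEX["R"]] == pytest.approx(2 / 22)
        # node1 transitions: M->M twice (a, c), M->D once (b); +1 pseudocount each
        assert hmm.transitions[1, 0, 0] == pytest.approx((2 + 1) / (3 + 3))
        assert hmm.transitions[1, 0, 2] == pytest.approx((1 + 1) / (3 + 3))
        assert hmm.transitions[1, 0, 1] == pytest.approx(1 / 6)

    def test_zero_match_columns_error(self):
        rows = [SequenceRecord("a", "M-"), SequenceRecord("b", "-K"), SequenceRecord("c", "--")]
        rows = [SequenceRecord("a", "M--"), SequenceRecord("b", "-K-"), SequenceRecord("c", "--V")]
        with pytest.raises(ValueError):
            build_profile(Alignment(rows), match_gap_threshold=0.2)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            build_profile(Alignment([SequenceRecord("a", "MK")]))

    def test_row_order_invariance(self):
        rows = [
            SequenceRecord("a", "MKVLA"),
            SequenceRecord("b", "MRVLA"),
            SequenceRecord("c", "MKV-A"),
        ]
        h1 = build_profile(Alignment(rows))
        h2 = build_profile(Alignment(rows[::-1]))
        assert np.allclose(h1.match_emissions, h2.match_emissions)
        assert np.allclose(h1.transitions, h2.transitions)
        assert h1.bit_score("MKVLA") == pytest.approx(h2.bit_score("MKVLA"))

    def test_json_round_trip(self, tmp_path):
        aln = Alignment([SequenceRecord("a", "MKVLA"), SequenceRecord("b", "MRVLA")])
        hmm = build_profile(aln)
        path = tmp_path / "hmm.json"
        hmm.to_json(path)
        back = ProfileHMM.from_json(path)
        assert back.bit_score("MKVLA") == pytest.approx(hmm.bit_score("MKVLA"))


class TestViterbi:
    def test_consensus_all_match(self):
        aln = Alignment(
            [SequenceRecord("a", "MKVLA"), SequenceRecord("b", "MKVLA"), SequenceRecord("c", "MKVLA")]
        )
        hmm = build_profile(aln, mode="global")
        _, cols = hmm.viterbi("MKVLA")
        assert list(cols) == [1, 2, 3, 4, 5]

    def test_extra_residue_single_insert(self):
        aln = Alignment([SequenceRecord(f"s{i}", "MKVLA") for i in range(5)])
        hmm = build_profile(aln, mode="global")
        _, cols = hmm.viterbi("MKVWLA")
        assert sum(1 for c in cols if c < 0) == 1
        assert sorted(c for c in cols if c > 0) == [1, 2, 3, 4, 5]

    def test_viterbi_never_exceeds_forward(self, rng):
        for _ in range(30):
            L = int(rng.integers(1, 4))
            hmm = random_tiny_hmm(rng, L)
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(1, 5))))
            v, _ = hmm.viterbi(seq)
            f = hmm.bit_score(seq)
            assert v <= f + 1e-9

    def test_matched_span_ignores_flanks(self):
        aln = Alignment([SequenceRecord(f"s{i}", "WWMKVLAWW"[2:7]) for i in range(5)])
        hmm = build_profile(aln)  # unilocal
        span = hmm.matched_span("GGGGMKVLAGGGG")
        assert span == (4, 9)


class TestTuneHMM:
    def test_empty_new_actives_identity(self):
        base = [SequenceRecord("a", "MKVLAWGT"), SequenceRecord("b", "MRVLAWGS")]
        h0 = tune_hmm(base, [])
        h1 = tune_hmm(base)
        assert np.allclose(h0.match_emissions, h1.match_emissions)
        assert np.allclose(h0.transitions, h1.transitions)

    def test_duplicate_copies_pseudocount_ratio(self):
        # doubling identical rows changes emissions by the closed-form count ratio
        base = [SequenceRecord(f"s{i}", "MKVLA") for i in range(3)]
        extra = [SequenceRecord(f"t{i}", "MKVLA") for i in range(3)]
        h_base = tune_hmm(base, [])
        h_tuned = tune_hmm(base, extra)
        i_m = AA_INDEX["M"]
        assert h_base.match_emissions[1, i_m] == pytest.approx(4 / 23)
        assert h_tuned.match_emissions[1, i_m] == pytest.approx(7 / 26)

    def test_align_to_profile_route(self):
        base = [SequenceRecord("a", "MKVLAWGT"), SequenceRecord("b", "MRVLAWGS")]
        from petscreen.msa import progressive_align

        base_aln = progressive_align(base)
        new = [SequenceRecord("c", "MKVLAWGT")]
        h = tune_hmm(base, new, realign=False, base_alignment=base_aln)
        assert h.L == base_aln.n_columns


class TestNormalizeScores:
    def test_reference_is_one(self):
        ss = normalize_scores({"ref": 100.0, "a": 50.0}, "ref")
        assert ss.normalized["ref"] == 1.0
        assert ss.normalized["a"] == 0.5

    def test_missing_reference(self):
        with pytest.raises(KeyError):
            normalize_scores({"a": 1.0}, "ref")

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            normalize_scores({"ref": 0.0}, "ref")
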