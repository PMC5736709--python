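"""Forward/Viterbi scoring against an exhaustive path-enumeration oracle."""

import numpy as np
import pytest

from sbs.alphabet import AA, BACKGROUND
from sbs.msa import Alignment
from sbs.hmm import build_profile, forward_bits, viterbi_align
from sbs.hmm.score import path_bits


def enum_forward_bits(hmm, sequence):
    """Oracle: sum path probabilities over every possible local alignment
    by explicit recursion (usable for tiny models/sequences only)."""
    xs = [AA.index(c) if c in AA else -1 for c in sequence.upper()]
    L, k = len(xs), hmm.n_match_states
    bg = hmm.background

    def em_m(j, x):
        return 1.0 if x < 0 else hmm.match_em[j, x] / bg[x]

    def em_i(j, x):
        return 1.0 if x < 0 else hmm.insert_em[j, x] / bg[x]

    total = 0.0

    def go(state, j, i, prob):
        nonlocal total
        if state == "M":
            total += prob * hmm.t_me[j]
            if j < k - 1:
                if i + 1 < L:
                    go("M", j + 1, i + 1,
                       prob * hmm.t_mm[j] * em_m(j + 1, xs[i + 1]))
                    go("I", j, i + 1, prob * hmm.t_mi[j] * em_i(j, xs[i + 1]))
                if hmm.t_md[j] > 0:
                    go("D", j + 1, i, prob * hmm.t_md[j])
        elif state == "I":
            if i + 1 < L:
                go("M", j + 1, i + 1,
                   prob * hmm.t_im[j] * em_m(j + 1, xs[i + 1]))
                go("I", j, i + 1, prob * hmm.t_ii[j] * em_i(j, xs[i + 1]))
        else:  # D
            if i + 1 < L:
                go("M", j + 1, i + 1,
                   prob * hmm.t_dm[j] * em_m(j + 1, xs[i + 1]))
            if hmm.t_dd[j] > 0:
                go("D", j + 1, i, prob * hmm.t_dd[j])

    for i0 in range(L):
        for j0 in range(k):
            go("M", j0, i0, (1.0 / k) * em_m(j0, xs[i0]))
    return np.log2(total)


def _tiny_models():
    yield build_profile(Alignment([("a", "A"), ("b", "A")]), pseudocount_weight=0.0)
    yield build_profile(Alignment([("a", "ACD"), ("b", "ACD")]),
                        pseudocount_weight=0.5)
    yield build_profile(
        Alignment([("a", "AC-D"), ("b", "ACWD"), ("c", "A-WD")]),
        pseudocount_weight=1.0,
    )


@pytest.mark.parametrize("seq", ["A", "AC", "WAC", "ACDW", "DCA", "AXCD"])
def test_forward_matches_exhaustive_enumeration(seq):
    for hmm in _tiny_models():
        assert forward_bits(hmm, seq) == pytest.approx(
            enum_forward_bits(hmm, seq), abs=1e-9
        )


def test_one_match_state_closed_form():
    hmm = build_profile(Alignment([("a", "A"), ("b", "A")]), pseudocount_weight=0.0)
    # single possible path: enter M1, emit A, exit
    expected = np.log2(1.0 / BACKGROUND[AA.index("A")])
    assert forward_bits(hmm, "A") == pytest.approx(expected, abs=1e-12)


def test_forward_at_least_viterbi_everywhere(rng):
    for hmm in _tiny_models():
        for _ in range(20):
            seq = "".join(rng.choice(list(AA), size=rng.integers(1, 8)))
            f = forward_bits(hmm, seq)
            try:
                _, v, _ = viterbi_align(hmm, seq)
            except ValueError:
                continue
            assert f >= v - 1e-9


def test_forward_at_least_viterbi_on_real_model(models, rng):
    hmm = models["canonical"]
    for _ in range(5):
        seq = "".join(rng.choice(list(AA), size=60, p=BACKGROUND))
        f = forward_bits(hmm, seq)
        _, v, _ = viterbi_align(hmm, seq)
        assert f >= v - 1e-9


def test_viterbi_exact_match_path_and_envelope():
    hmm = build_profile(Alignment([("a", "ACD"), ("b", "ACD")]),
                        pseudocount_weight=0.0)
    path, bits, env = viterbi_align(hmm, "ACD")
    assert path == [("M", 0), ("M", 1), ("M", 2)]
    assert env == (0, 3)
    assert path_bits(hmm, "ACD", path, env[0]) == pytest.approx(bits, abs=1e-9)


def test_viterbi_insertion_handled():
    hmm = build_profile(Alignment([("a", "ACDEFG"), ("b", "ACDEFG")]),
                        pseudocount_weight=1.0)
    path, bits, env = viterbi_align(hmm, "ACDWEFG")
    inserts = [p for p in path if p[0] == "I"]
    assert len(inserts) == 1
    assert env == (0, 7)
    assert path_bits(hmm, "ACDWEFG", path, env[0]) == pytest.approx(bits, abs=1e-9)


def test_viterbi_short_insert_detour_loses_to_core_match():
    # with a 3-state model the extra matched residue does not pay for the
    # insert transitions, so the best local alignment is the C-D core
    hmm = build_profile(Alignment([("a", "ACD"), ("b", "ACD")]),
                        pseudocount_weight=1.0)
    path, bits, env = viterbi_align(hmm, "AWCD")
    assert env == (2, 4)
    assert path == [("M", 1), ("M", 2)]
    assert path_bits(hmm, "AWCD", path, env[0]) == pytest.approx(bits, abs=1e-9)


def test_viterbi_path_probability_self_consistent(models, rng):
    hmm = models["vibrio"]
    seq = "".join(rng.choice(list(AA), size=80, p=BACKGROUND))
    path, bits, env = viterbi_align(hmm, seq)
    assert path_bits(hmm, seq, path, env[0]) == pytest.approx(bits, abs=1e-9)


def test_model_emissions_score_higher_than_background_on_average(rng):
    hmm = build_profile(
        Alignment([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL"), ("c", "ACDWFGHIKL")]),
        pseudocount_weight=1.0,
    )
    k = hmm.n_match_states
    bg_scores, model_scores = [], []
    for _ in range(200):
        bg_seq = "".join(rng.choice(list(AA), size=k, p=BACKGROUND))
        m_seq = "".join(
            AA[rng.choice(20, p=hmm.match_em[j])] for j in range(k)
        )
        bg_scores.append(forward_bits(hmm, bg_seq))
        model_scores.append(forward_bits(hmm, m_seq))
    assert np.mean(bg_scores) <= np.mean(model_scores)


def test_unknown_residue_error_names_character_and_position():
    hmm = build_profile(Alignment([("a", "ACD"), ("b", "ACD")]))
    with pytest.raises(ValueError, match=r"'\*' at position 2"):
        forward_bits(hmm, "AC*D")


def test_ambiguity_codes_score_as_background():
    hmm = build_profile(Alignment([("a", "ACD"), ("b", "ACD")]),
                        pseudocount_weight=0.5)
    # X contributes zero log-odds wherever it lands
    assert np.isfinite(forward_bits(hmm, "AXD"))
    assert np.isfinite(forward_bits(hmm, "XXX"))
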