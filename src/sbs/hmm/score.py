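"""Forward and Viterbi scoring of sequences against a profile HMM.

Scores are log2-odds ("bits") of the model versus an i.i.d. background
null over the same sequence.  Residues outside the local alignment are
emitted by the background in both numerator and denominator, so only the
aligned core contributes.  Computation is carried out in natural-log odds
space and converted to bits at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..alphabet import encode
from .model import ProfileHmm

_LN2 = np.log(2.0)
_NEG = -np.inf


def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


@dataclass
class _Tables:
    """Pre-computed log-odds tables for one model."""

    lm: np.ndarray       # (k, 20) match log-odds emissions
    li: np.ndarray       # (k-1, 20) insert log-odds emissions
    entry: float
    ltmm: np.ndarray
    ltmi: np.ndarray
    ltmd: np.ndarray
    ltim: np.ndarray
    ltii: np.ndarray
    ltdm: np.ndarray
    ltdd: np.ndarray
    ltme: np.ndarray
    k: int


def _tables(hmm: ProfileHmm) -> _Tables:
    t = getattr(hmm, "_score_tables", None)
    if t is not None and t.k == hmm.n_match_states:
        return t
    lbg = _safe_log(hmm.background)
    k = hmm.n_match_states
    t = _Tables(
        lm=_safe_log(hmm.match_em) - lbg,
        li=(_safe_log(hmm.insert_em) - lbg) if hmm.insert_em.size else np.zeros((0, 20)),
        entry=float(-np.log(k)),
        ltmm=_safe_log(hmm.t_mm),
        ltmi=_safe_log(hmm.t_mi),
        ltmd=_safe_log(hmm.t_md),
        ltim=_safe_log(hmm.t_im),
        ltii=_safe_log(hmm.t_ii),
        ltdm=_safe_log(hmm.t_dm),
        ltdd=_safe_log(hmm.t_dd),
        ltme=_safe_log(hmm.t_me),
        k=k,
    )
    object.__setattr__(hmm, "_score_tables", t)
    return t


def _shift(v: np.ndarray) -> np.ndarray:
    out = np.empty_like(v)
    if out.size:
        out[0] = _NEG
        out[1:] = v[:-1]
    return out


def _dscan(vm: np.ndarray, t: _Tables, reduce_max: bool) -> np.ndarray:
    """In-row delete chain: vD[j] for j = 1..k-2 from the current vM row."""
    k = t.k
    vd = np.full(k, _NEG)
    if k < 3:
        return vd
    x = vm[: k - 2] + t.ltmd[: k - 2]          # source M_{j-1} -> D_j
    chain = t.ltdd[1: k - 2]                   # D_j -> D_{j+1}, j = 1..k-3
    if chain.size and np.all(np.isfinite(chain)):
        c = np.concatenate([[0.0], np.cumsum(chain)])
        op = np.maximum if reduce_max else np.logaddexp
        r = op.accumulate(x - c) + c
    else:  # sparse chains (zero-pseudocount models): plain scan
        r = np.empty_like(x)
        acc = _NEG
        for q in range(x.size):
            step = t.ltdd[q] if q >= 1 else _NEG
            prev = acc + step if np.isfinite(step) and np.isfinite(acc) else _NEG
            acc = max(x[q], prev) if reduce_max else np.logaddexp(x[q], prev)
            r[q] = acc
    vd[1: k - 1] = r
    return vd


def _emissions(t: _Tables, x: int) -> tuple[np.ndarray, np.ndarray]:
    if x < 0:  # ambiguity code: scored as background (zero log-odds)
        return np.zeros(t.k), np.zeros(max(t.k - 1, 0))
    return t.lm[:, x], (t.li[:, x] if t.li.size else np.zeros(0))


def forward_bits(hmm: ProfileHmm, sequence: str) -> float:
    """Local forward bit score: log2 of the summed odds of all local
    alignments of ``sequence`` to the model."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    xs = encode(sequence)
    t = _tables(hmm)
    k = t.k
    vm = np.full(k, _NEG)
    vi = np.full(max(k - 1, 0), _NEG)
    vd = np.full(k, _NEG)
    total = _NEG
    for x in xs:
        em_m, em_i = _emissions(t, int(x))
        cand = np.full(k, t.entry)
        if k > 1:
            prev_m = _shift(vm)
            cand = np.logaddexp(cand, prev_m + np.concatenate([[_NEG], t.ltmm]))
            prev_i = np.concatenate([[_NEG], vi]) + np.concatenate([[_NEG], t.ltim])
            cand = np.logaddexp(cand, prev_i)
            prev_d = _shift(vd) + np.concatenate([[_NEG], t.ltdm[: k - 1]])
            cand = np.logaddexp(cand, prev_d)
        new_m = em_m + cand
        if k > 1:
            new_i = em_i + np.logaddexp(vm[:-1] + t.ltmi, vi + t.ltii)
        else:
            new_i = vi
        new_d = _dscan(new_m, t, reduce_max=False)
        vm, vi, vd = new_m, new_i, new_d
        total = np.logaddexp(total, _lse(vm + t.ltme))
    return float(total / _LN2)


def _lse(v: np.ndarray) -> float:
    m = np.max(v) if v.size else _NEG
    if not np.isfinite(m):
        return _NEG
    return float(m + np.log(np.sum(np.exp(v - m))))


def viterbi_align(
    hmm: ProfileHmm, sequence: str
) -> tuple[list[tuple[str, int]], float, tuple[int, int]]:
    """Best local alignment.

    Returns ``(path, bit_score, envelope)`` where ``path`` is a list of
    ``(state, index)`` pairs over ``{"M", "I", "D"}`` (0-based state
    indices) and ``envelope`` is the half-open residue interval consumed
    by the alignment's match/insert states.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    xs = encode(sequence)
    t = _tables(hmm)
    k, L = t.k, len(xs)
    VM = np.full((L, k), _NEG)
    VI = np.full((L, max(k - 1, 0)), _NEG)
    VD = np.full((L, k), _NEG)
    vm = np.full(k, _NEG)
    vi = np.full(max(k - 1, 0), _NEG)
    vd = np.full(k, _NEG)
    for i, x in enumerate(xs):
        em_m, em_i = _emissions(t, int(x))
        cand = np.full(k, t.entry)
        if k > 1:
            cand = np.maximum(cand, _shift(vm) + np.concatenate([[_NEG], t.ltmm]))
            cand = np.maximum(
                cand, np.concatenate([[_NEG], vi]) + np.concatenate([[_NEG], t.ltim])
            )
            cand = np.maximum(
                cand, _shift(vd) + np.concatenate([[_NEG], t.ltdm[: k - 1]])
            )
        new_m = em_m + cand
        if k > 1:
            new_i = em_i + np.maximum(vm[:-1] + t.ltmi, vi + t.ltii)
        else:
            new_i = vi
        new_d = _dscan(new_m, t, reduce_max=True)
        vm, vi, vd = new_m, new_i, new_d
        VM[i], VD[i] = vm, vd
        if VI.size:
            VI[i] = vi

    end = VM + t.ltme[None, :]
    i_end, j_end = np.unravel_index(np.argmax(end), end.shape)
    score = end[i_end, j_end]
    if not np.isfinite(score):
        raise ValueError("no finite local alignment exists for this sequence")

    def close(a: float, b: float) -> bool:
        return np.isfinite(a) and abs(a - b) <= 1e-9 * max(1.0, abs(b))

    path: list[tuple[str, int]] = []
    state, i, j = "M", int(i_end), int(j_end)
    start = i
    while True:
        path.append((state, j))
        if state == "M":
            em, _ = _emissions(t, int(xs[i]))
            base = VM[i, j] - em[j]
            start = i
            if close(t.entry, base):
                break
            if i == 0 or j == 0:
                raise AssertionError("traceback failed at match state")
            if close(VM[i - 1, j - 1] + t.ltmm[j - 1], base):
                state, i, j = "M", i - 1, j - 1
            elif VI.size and close(VI[i - 1, j - 1] + t.ltim[j - 1], base):
                state, i, j = "I", i - 1, j - 1
            elif close(VD[i - 1, j - 1] + t.ltdm[j - 1], base):
                state, i, j = "D", i - 1, j - 1
            else:
                raise AssertionError("traceback failed at match state")
        elif state == "I":
            _, em_i = _emissions(t, int(xs[i]))
            base = VI[i, j] - em_i[j]
            if close(VM[i - 1, j] + t.ltmi[j], base):
                state, i = "M", i - 1
            elif close(VI[i - 1, j] + t.ltii[j], base):
                state, i = "I", i - 1
            else:
                raise AssertionError("traceback failed at insert state")
        else:  # D
            base = VD[i, j]
            if close(VM[i, j - 1] + t.ltmd[j - 1], base):
                state, j = "M", j - 1
            elif close(VD[i, j - 1] + t.ltdd[j - 1], base):
                state, j = "D", j - 1
            else:
                raise AssertionError("traceback failed at delete state")
    path.reverse()
    envelope = (start, int(i_end) + 1)
    return path, float(score / _LN2), envelope


def path_bits(
    hmm: ProfileHmm, sequence: str, path: list[tuple[str, int]], start: int
) -> float:
    """Recompute the bit score of an explicit local state path.

    Independent of the DP: walks the path, multiplying entry, emission
    odds, transition and exit probabilities.
    """
    xs = encode(sequence)
    t = _tables(hmm)
    total = t.entry
    i = start
    for n, (state, j) in enumerate(path):
        if state == "M":
            em, _ = _emissions(t, int(xs[i]))
            total += em[j]
            i += 1
        elif state == "I":
            _, em_i = _emissions(t, int(xs[i]))
            total += em_i[j]
            i += 1
        if n + 1 < len(path):
            s2, j2 = path[n + 1]
            total += {
                ("M", "M"): lambda: t.ltmm[j],
                ("M", "I"): lambda: t.ltmi[j],
                ("M", "D"): lambda: t.ltmd[j],
                ("I", "M"): lambda: t.ltim[j],
                ("I", "I"): lambda: t.ltii[j],
                ("D", "M"): lambda: t.ltdm[j],
                ("D", "D"): lambda: t.ltdd[j],
            }[(state, s2)]()
    total += t.ltme[path[-1][1]]
    return float(total / _LN2)
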