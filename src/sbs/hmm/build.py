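"""Build a profile HMM from a seed alignment."""

from __future__ import annotations

import numpy as np

from ..alphabet import AA_INDEX, BACKGROUND, GAP_CHARS
from ..msa import Alignment
from .model import ProfileHmm


def build_profile(
    alignment: Alignment,
    match_fraction: float = 0.5,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
    exit_prob: float | None = None,
) -> ProfileHmm:
    """Estimate a local profile HMM from an aligned seed family.

    Columns whose gap fraction is below ``match_fraction`` become match
    states; the rest are insert columns.  Match/insert emissions are
    normalized residue counts with additive background-proportional
    pseudocounts of total weight ``pseudocount_weight``; transitions are
    estimated from the observed per-sequence state paths with
    Laplace-style pseudocounts of the same weight.  ``exit_prob`` is the
    per-match-state local exit probability (default ``1/k``).
    """
    if not 0 < match_fraction <= 1:
        raise ValueError("match_fraction must be in (0, 1]")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be non-negative")
    if not alignment.records:
        raise ValueError("no sequences")

    n_cols = alignment.n_columns
    match_mask = np.array(
        [alignment.gap_fraction(j) < match_fraction for j in range(n_cols)]
    )
    alignment.match_mask = match_mask
    k = int(match_mask.sum())
    if k == 0:
        raise ValueError("no match columns")
    col_to_match = np.full(n_cols, -1)
    col_to_match[match_mask] = np.arange(k)

    bg = BACKGROUND
    w = pseudocount_weight
    match_counts = np.zeros((k, 20))
    insert_counts = np.zeros(20)

    # Per-sequence state paths (local: clipped to the first/last match
    # emission, so flanking inserts/deletes are not counted).
    tc_m = np.zeros((max(k - 1, 0), 3))   # from M_j: [->M, ->I, ->D]
    tc_i = np.zeros((max(k - 1, 0), 2))   # from I_j: [->I, ->M]
    tc_d = np.zeros((k, 2))               # from D_j: [->D, ->M]

    for _, seq in alignment.records:
        path: list[tuple[str, int]] = []
        for j, ch in enumerate(seq):
            m = col_to_match[j]
            if m >= 0:
                if ch in GAP_CHARS:
                    path.append(("D", m))
                else:
                    path.append(("M", m))
                    if ch in AA_INDEX:
                        match_counts[m, AA_INDEX[ch]] += 1
            else:
                if ch not in GAP_CHARS:
                    # insert state index = preceding match state
                    prev_matches = int(match_mask[:j].sum())
                    path.append(("I", max(prev_matches - 1, 0)))
                    if ch in AA_INDEX:
                        insert_counts[AA_INDEX[ch]] += 1
        emitted = [i for i, (s, _) in enumerate(path) if s == "M"]
        if not emitted:
            continue
        core = path[emitted[0]: emitted[-1] + 1]
        for (s1, j1), (s2, _j2) in zip(core, core[1:]):
            if s1 == "M":
                if j1 >= k - 1:
                    continue
                tc_m[j1, {"M": 0, "I": 1, "D": 2}[s2]] += 1
            elif s1 == "I":
                tc_i[j1, 0 if s2 == "I" else 1] += 1
            elif s1 == "D":
                tc_d[j1, 0 if s2 == "D" else 1] += 1

    match_em = match_counts + w * bg
    row_tot = match_em.sum(axis=1, keepdims=True)
    if np.any(row_tot == 0):
        # counts can be all-zero only with w == 0 and fully ambiguous
        # columns; fall back to background
        match_em = np.where(row_tot > 0, match_em, bg)
        row_tot = match_em.sum(axis=1, keepdims=True)
    match_em = match_em / row_tot

    ins = insert_counts + w * bg
    ins = ins / ins.sum() if ins.sum() > 0 else bg.copy()
    insert_em = np.tile(ins, (max(k - 1, 0), 1))

    tau = 1.0 / k if exit_prob is None else float(exit_prob)
    if not 0 < tau <= 1:
        raise ValueError("exit_prob must be in (0, 1]")

    t_mm = np.zeros(max(k - 1, 0))
    t_mi = np.zeros_like(t_mm)
    t_md = np.zeros_like(t_mm)
    t_im = np.zeros_like(t_mm)
    t_ii = np.zeros_like(t_mm)
    t_dm = np.zeros(k)
    t_dd = np.zeros(k)
    t_me = np.full(k, tau)
    t_me[-1] = 1.0

    for j in range(k - 1):
        # delete target D_{j+1} exists only for 1 <= j+1 <= k-2
        has_d = 1 <= j + 1 <= k - 2
        c = tc_m[j] + w
        if not has_d:
            c[2] = 0.0
        tot = c.sum()
        if tot == 0:
            c = np.array([1.0, 0.0, 0.0])
            tot = 1.0
        core = (1.0 - tau) * c / tot
        t_mm[j], t_mi[j], t_md[j] = core

        ci = tc_i[j] + w
        if ci.sum() == 0:
            ci = np.array([0.0, 1.0])
        t_ii[j], t_im[j] = ci / ci.sum()

    for j in range(1, max(k - 1, 1)):
        has_next = j + 1 <= k - 2
        cd = tc_d[j] + w
        if not has_next:
            cd[0] = 0.0
        if cd.sum() == 0:
            cd = np.array([0.0, 1.0])
        t_dd[j], t_dm[j] = cd / cd.sum()

    hmm = ProfileHmm(
        name=name,
        match_em=match_em,
        insert_em=insert_em,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd, t_me=t_me,
        background=bg.copy(),
    )
    hmm.validate()
    return hmm
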