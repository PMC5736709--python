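"""Profile HMM container and plain-text serialization.

Architecture
------------
A local-alignment profile with match states ``M_0 .. M_{k-1}``, insert
states ``I_0 .. I_{k-2}`` (``I_j`` sits between ``M_j`` and ``M_{j+1}``)
and interior delete states ``D_1 .. D_{k-2}``.  Alignments enter uniformly
(probability ``1/k``) at any match state and leave from any match state
with a constant per-state exit probability (the last match state always
exits).  Leading/trailing deletions and flanking inserts are subsumed by
local entry/exit; flanking sequence is emitted by the background null, so
it contributes zero log-odds.

Transition probability vectors are stored *from* the source state:

* ``t_mm, t_mi, t_md`` — from ``M_j`` (length ``k-1``); together with
  ``t_me[j]`` they sum to 1.
* ``t_im, t_ii`` — from ``I_j`` (length ``k-1``), sum to 1.
* ``t_dm, t_dd`` — from ``D_j`` (length ``k``, only indices ``1..k-2``
  meaningful), sum to 1.
* ``t_me`` — match-to-exit (length ``k``, last entry 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..alphabet import AA, BACKGROUND

_TOL = 1e-9


@dataclass
class ProfileHmm:
    name: str
    match_em: np.ndarray          # (k, 20)
    insert_em: np.ndarray         # (k-1, 20)
    t_mm: np.ndarray              # (k-1,)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray              # (k,), indices 1..k-2 used
    t_dd: np.ndarray
    t_me: np.ndarray              # (k,)
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())

    @property
    def n_match_states(self) -> int:
        return self.match_em.shape[0]

    def validate(self) -> None:
        k = self.n_match_states
        if k < 1:
            raise ValueError("model must have at least one match state")
        for name, dist in [("match", self.match_em), ("insert", self.insert_em)]:
            if dist.size and not np.allclose(dist.sum(axis=1), 1.0, atol=_TOL):
                raise ValueError(f"{name} emissions do not sum to 1")
        if abs(self.background.sum() - 1.0) > _TOL:
            raise ValueError("background does not sum to 1")
        if k > 1:
            out_m = self.t_mm + self.t_mi + self.t_md + self.t_me[:-1]
            if not np.allclose(out_m, 1.0, atol=_TOL):
                raise ValueError("match transitions do not sum to 1")
            out_i = self.t_im + self.t_ii
            if not np.allclose(out_i, 1.0, atol=_TOL):
                raise ValueError("insert transitions do not sum to 1")
            used = slice(1, max(k - 1, 1))
            out_d = (self.t_dm + self.t_dd)[used]
            if out_d.size and not np.allclose(out_d, 1.0, atol=_TOL):
                raise ValueError("delete transitions do not sum to 1")
        if abs(self.t_me[-1] - 1.0) > _TOL:
            raise ValueError("last match state must exit with probability 1")


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_model(hmm: ProfileHmm, path: str | Path) -> None:
    """Serialize to a documented plain-text key-value format (``.shm``).

    Floats are written with 17 significant digits so that a read/write
    round trip is bit-exact.
    """
    lines = [
        "SBSHMM 1",
        f"NAME {hmm.name}",
        f"ALPH {AA}",
        f"K {hmm.n_match_states}",
        "BG " + " ".join(_fmt(x) for x in hmm.background),
    ]
    for j in range(hmm.n_match_states):
        lines.append(f"MATCH {j} " + " ".join(_fmt(x) for x in hmm.match_em[j]))
    for j in range(hmm.insert_em.shape[0]):
        lines.append(f"INSERT {j} " + " ".join(_fmt(x) for x in hmm.insert_em[j]))
    for key, arr in [
        ("TMM", hmm.t_mm), ("TMI", hmm.t_mi), ("TMD", hmm.t_md),
        ("TIM", hmm.t_im), ("TII", hmm.t_ii),
        ("TDM", hmm.t_dm), ("TDD", hmm.t_dd), ("TME", hmm.t_me),
    ]:
        lines.append(f"{key} " + " ".join(_fmt(x) for x in arr))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> ProfileHmm:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("SBSHMM"):
        raise ValueError(f"{path} is not an sbs profile HMM file")
    fields: dict[str, list[str]] = {}
    match_rows: dict[int, np.ndarray] = {}
    insert_rows: dict[int, np.ndarray] = {}
    name = "model"
    for line in text[1:]:
        if not line.strip() or line.strip() == "END":
            continue
        key, *rest = line.split()
        if key == "NAME":
            name = rest[0] if rest else "model"
        elif key == "MATCH":
            match_rows[int(rest[0])] = np.array([float(x) for x in rest[1:]])
        elif key == "INSERT":
            insert_rows[int(rest[0])] = np.array([float(x) for x in rest[1:]])
        else:
            fields[key] = rest
    k = int(fields["K"][0])
    match_em = np.vstack([match_rows[j] for j in range(k)]) if k else np.zeros((0, 20))
    if insert_rows:
        insert_em = np.vstack([insert_rows[j] for j in range(len(insert_rows))])
    else:
        insert_em = np.zeros((0, 20))

    def vec(key: str) -> np.ndarray:
        return np.array([float(x) for x in fields[key]])

    hmm = ProfileHmm(
        name=name,
        match_em=match_em,
        insert_em=insert_em,
        t_mm=vec("TMM"), t_mi=vec("TMI"), t_md=vec("TMD"),
        t_im=vec("TIM"), t_ii=vec("TII"),
        t_dm=vec("TDM"), t_dd=vec("TDD"), t_me=vec("TME"),
        background=vec("BG"),
    )
    hmm.validate()
    return hmm
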