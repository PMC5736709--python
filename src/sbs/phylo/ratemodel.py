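"""Empirical amino-acid replacement models (general time-reversible).

A model is defined by a symmetric 20x20 exchangeability matrix ``S`` and
stationary frequencies ``pi``.  The generator is ``Q_ab = S_ab * pi_b``
(a != b) with diagonal set so rows sum to zero, scaled so the expected
number of substitutions per site per unit time is one
(``-sum_a pi_a Q_aa = 1``).  Transition probabilities ``P(t) = expm(Q t)``
are evaluated through the symmetrised eigendecomposition, so thousands of
evaluations (bootstrap replicates) are cheap.

Any empirical matrix in PAML ``.dat`` format (lower-triangle
exchangeabilities then frequencies) can be loaded; the bundled default is
the published WAG matrix.  The analysis this package mirrors used the PMB
model, whose published ``pmb.dat`` drops straight into :func:`load_paml`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from ..alphabet import AA, AA_INDEX


class RateModel:
    def __init__(self, exchangeability: np.ndarray, frequencies: np.ndarray,
                 name: str = "custom"):
        S = np.asarray(exchangeability, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeability must be a symmetric 20x20 matrix")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.sum(pi * np.diag(Q))
        Q /= rate
        self.name = name
        self.S = S
        self.pi = pi
        self.Q = Q
        # symmetrised eigendecomposition: D^(1/2) Q D^(-1/2) is symmetric
        sq = np.sqrt(pi)
        sym = Q * (sq[:, None] / sq[None, :])
        lam, U = np.linalg.eigh((sym + sym.T) / 2.0)
        self._lam = lam
        self._left = U / sq[:, None] * 1.0          # D^(-1/2) U
        self._right = (U * sq[:, None]).T           # U^T D^(1/2)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to 1."""
        if t < 0:
            raise ValueError("time must be non-negative")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(P, 0.0, None)

    def log_joint(self, t: float) -> np.ndarray:
        """log(pi_a P_ab(t)), the per-site pair log-likelihood table."""
        with np.errstate(divide="ignore"):
            return np.log(self.pi[:, None] * self.transition_matrix(t))

    def __repr__(self) -> str:
        return f"RateModel({self.name})"


def load_paml(path: str | Path, name: str | None = None) -> RateModel:
    """Parse a PAML-format amino-acid model file (lower triangle of the
    exchangeability matrix, 19 rows, followed by 20 frequencies), residue
    order ``ARNDCQEGHILKMFPSTWYV``."""
    values: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            values.extend(float(x) for x in line.split())
    if len(values) < 190 + 20:
        raise ValueError(f"{path}: expected 190 exchangeabilities + 20 frequencies")
    tri, freqs = values[:190], values[190:210]
    S = np.zeros((20, 20))
    it = iter(tri)
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return RateModel(S, np.array(freqs), name=name or Path(path).stem.upper())


def default_model() -> RateModel:
    """The bundled WAG model."""
    ref = resources.files("sbs.phylo").joinpath("data/wag.paml")
    with resources.as_file(ref) as p:
        return load_paml(p, name="WAG")


def pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    """20x20 site-pattern counts over columns where both sequences have a
    standard residue (pairwise deletion of gaps/ambiguity)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal lengths)")
    N = np.zeros((20, 20))
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        ia, ib = AA_INDEX.get(a), AA_INDEX.get(b)
        if ia is not None and ib is not None:
            N[ia, ib] += 1
    return N


__all__ = ["RateModel", "load_paml", "default_model", "pair_counts", "AA"]
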