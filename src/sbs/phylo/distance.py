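"""Maximum-likelihood pairwise distances under an empirical rate model.

For an aligned pair the distance is the t >= 0 maximising
``sum_sites log(pi_a P_ab(t))`` with pairwise deletion of gapped columns
and a uniform rate across sites (no gamma heterogeneity).  Distances are
capped at ``SATURATION_CAP`` substitutions/site when the likelihood keeps
increasing in t (saturated pairs), keeping matrices finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .ratemodel import RateModel, pair_counts

SATURATION_CAP = 10.0
_REL_TOL = 1e-6


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite and non-negative")
        self.d = d


def _neg_loglik(counts: np.ndarray, model: RateModel):
    def f(t: float) -> float:
        ll = counts * model.log_joint(t)
        # counts>0 where log term is -inf cannot occur for t>0 (P>0);
        # at t=0 off-diagonal observed pairs give -inf
        val = ll[counts > 0].sum()
        return -val if np.isfinite(val) else np.inf
    return f


def ml_distance(
    seq_a: str, seq_b: str, model: RateModel, cap: float = SATURATION_CAP
) -> float:
    """ML substitutions/site between two aligned sequences."""
    counts = pair_counts(seq_a, seq_b)
    return ml_distance_from_counts(counts, model, cap=cap)


def ml_distance_from_counts(
    counts: np.ndarray, model: RateModel, cap: float = SATURATION_CAP
) -> float:
    n = counts.sum()
    if n == 0:
        raise ValueError("no comparable sites")
    off = n - np.trace(counts)
    if off == 0:
        return 0.0
    nll = _neg_loglik(counts, model)
    # bracket the optimum: expand until the likelihood stops improving
    p_dist = off / n
    t0 = max(min(-np.log(max(1.0 - p_dist * 20.0 / 19.0, 1e-6)), cap), 1e-4)
    hi = min(max(4.0 * t0, 0.5), cap)
    while hi < cap and nll(hi) > nll(min(2 * hi, cap)):
        hi = min(2 * hi, cap)
    res = minimize_scalar(
        nll, bounds=(0.0, hi), method="bounded",
        options={"xatol": _REL_TOL * max(t0, 1.0)},
    )
    t_hat = float(res.x)
    # saturated: monotone decreasing nll up to the cap
    if hi >= cap and nll(cap) <= res.fun:
        return cap
    return min(t_hat, cap)


def distance_matrix(
    records: list[tuple[str, str]], model: RateModel, cap: float = SATURATION_CAP
) -> DistanceMatrix:
    """All-pairs ML distances for an alignment given as (id, row) pairs."""
    if len(records) < 3:
        raise ValueError("need at least three sequences")
    labels = [rid for rid, _ in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = ml_distance(
                    records[i][1], records[j][1], model, cap=cap
                )
            except ValueError as exc:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
    return DistanceMatrix(labels=labels, d=d)
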