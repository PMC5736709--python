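"""STD-NMR build-up curves and binding-epitope maps.

Each ligand proton's STD intensity versus saturation time follows a
mono-exponential build-up ``y = a * (1 - exp(-b * t))`` (plateau ``a``,
rate ``b`` in 1/s; ``b`` is reported positive with the decaying
exponential written explicitly).  The initial slope ``a*b`` — the STD
build-up rate at zero saturation time — is insensitive to relaxation bias
and is the quantity mapped onto the ligand: slopes are normalised to a
reference proton (H7 of the sialic acid ring by convention, assigned
100%) and binned for display: blue 0-24%, yellow 25-50%, red 51-100%,
with values over 100% flagged separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

DEFAULT_SATURATION_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class StdBuildupCurve:
    proton_id: str
    saturation_times: np.ndarray
    std_intensities: np.ndarray
    a: float | None = None
    b: float | None = None
    converged: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.saturation_times, dtype=float)
        y = np.asarray(self.std_intensities, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("saturation times must be positive and increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        self.saturation_times = t
        self.std_intensities = y

    @property
    def initial_slope(self) -> float:
        if self.a is None or self.b is None:
            raise ValueError(f"curve {self.proton_id} has not been fitted")
        return self.a * self.b


def _model(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * (1.0 - np.exp(-b * t))


def fit_buildup(curve: StdBuildupCurve, max_restarts: int = 8) -> StdBuildupCurve:
    """Unweighted least-squares fit of the mono-exponential build-up.

    Initialisation: ``a0 = max(y)``; ``b0`` from inverting the model at
    the first time point, with geometric restarts if the optimiser fails.
    On noiseless model data the generating ``(a, b)`` are recovered to
    machine-level precision.  Degenerate (all-zero) data and non-positive
    fitted parameters raise/flag instead of returning a slope.
    """
    t, y = curve.saturation_times, curve.std_intensities
    if t.size < 3:
        raise ValueError("need at least three time points")
    if np.allclose(y, 0.0):
        raise ValueError(f"degenerate curve for proton {curve.proton_id}")
    a0 = float(max(y.max(), 1e-12))
    frac = np.clip(y[0] / a0, 1e-6, 1.0 - 1e-9)
    b0 = float(-np.log(1.0 - frac) / t[0])
    last_err: Exception | None = None
    for scale in [1.0, 0.3, 3.0, 0.1, 10.0, 0.03, 30.0, 0.01][: max_restarts]:
        try:
            popt, _ = curve_fit(
                _model, t, y, p0=[a0, b0 * scale], maxfev=20000,
            )
            a_hat, b_hat = float(popt[0]), float(popt[1])
            if a_hat <= 0 or b_hat <= 0:
                curve.a, curve.b = a_hat, b_hat
                curve.converged = False
                return curve
            curve.a, curve.b = a_hat, b_hat
            curve.converged = True
            return curve
        except RuntimeError as exc:  # no convergence; retry
            last_err = exc
    raise RuntimeError(
        f"build-up fit failed for proton {curve.proton_id} after "
        f"{max_restarts} restarts: {last_err}"
    )


_BINS = (("blue", 0.0, 24.0), ("yellow", 25.0, 50.0), ("red", 51.0, 100.0))


def _bin_for(pct: float) -> str:
    if pct > 100.0:
        return "over100"
    for name, lo, hi in _BINS:
        if lo <= round(pct) <= hi:
            return name
    return "blue"


@dataclass
class EpitopeMap:
    ligand_id: str
    reference_proton: str
    entries: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    # proton_id -> (initial_slope, normalized_pct, bin)


def epitope_map(
    curves: list[StdBuildupCurve],
    reference: str = "H7",
    ligand_id: str = "ligand",
) -> EpitopeMap:
    """Normalise fitted initial slopes to the reference proton (= 100%)."""
    by_id = {c.proton_id: c for c in curves}
    ref = by_id.get(reference)
    if ref is None or not ref.converged:
        raise ValueError(f"reference proton unavailable: {reference!r}")
    ref_slope = ref.initial_slope
    if ref_slope <= 0:
        raise ValueError(f"reference proton unavailable: {reference!r}")
    emap = EpitopeMap(ligand_id=ligand_id, reference_proton=reference)
    for c in curves:
        if not c.converged:
            continue
        slope = c.initial_slope
        pct = 100.0 if c.proton_id == reference else 100.0 * slope / ref_slope
        emap.entries[c.proton_id] = (slope, pct, _bin_for(pct))
    return emap
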