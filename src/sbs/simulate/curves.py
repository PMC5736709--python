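"""Synthetic STD build-up curves, ITC titrations and RFU tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..biophys.itc import ItcTitration, itc_forward
from ..biophys.std import DEFAULT_SATURATION_TIMES, StdBuildupCurve


def gen_std(
    protons: dict[str, tuple[float, float]],
    times: tuple[float, ...] = DEFAULT_SATURATION_TIMES,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[StdBuildupCurve], dict]:
    """Mono-exponential build-ups y = a (1 - exp(-b t)) + noise.

    ``protons`` maps proton id to true (a, b); the truth record keeps
    (a, b, a*b) per proton.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    curves = []
    truth = {"seed": seed, "protons": {}}
    for pid, (a, b) in protons.items():
        if a <= 0 or b <= 0:
            raise ValueError(f"proton {pid}: a and b must be positive")
        y = a * (1.0 - np.exp(-b * t)) + rng.normal(0.0, noise_sd, size=t.size)
        curves.append(StdBuildupCurve(pid, t, y))
        truth["protons"][pid] = {"a": a, "b": b, "slope": a * b}
    return curves, truth


def gen_itc(
    Kd_mM: float,
    dH_kJ_mol: float,
    cell_conc_uM: float = 115.0,
    syringe_conc_mM: float = 10.0,
    cell_volume_ul: float = 200.0,
    n_injections: int = 19,
    injection_volume_ul: float = 2.0,
    N: float = 1.0,
    dilution_heat_uJ: float = 0.0,
    noise_sd_uJ: float = 0.0,
    seed: int = 0,
) -> tuple[ItcTitration, dict]:
    """Single-site titration heats with optional dilution-control series.

    The default schedule (19 x 2 µl into a 200 µl cell at 115 µM protein,
    10 mM ligand) matches the instrument setup the package's assay
    defaults mirror.  When ``dilution_heat_uJ`` is non-zero a matching
    buffer-control series is attached for subtraction.
    """
    rng = np.random.default_rng(seed)
    vols = np.full(n_injections, float(injection_volume_ul))
    q = itc_forward(
        Kd_mM, dH_kJ_mol, cell_volume_ul, cell_conc_uM, syringe_conc_mM,
        vols, N=N,
    )
    control = None
    if dilution_heat_uJ != 0.0:
        control = np.full(n_injections, float(dilution_heat_uJ))
        q = q + control
    q = q + rng.normal(0.0, noise_sd_uJ, size=n_injections)
    tit = ItcTitration(
        cell_volume_ul=cell_volume_ul,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_mM=syringe_conc_mM,
        injection_volumes_ul=vols,
        heats_uJ=q,
        control_heats_uJ=control,
    )
    truth = {
        "seed": seed,
        "Kd_mM": Kd_mM,
        "dH_kJ_mol": dH_kJ_mol,
        "N": N,
        "dilution_heat_uJ": dilution_heat_uJ,
    }
    return tit, truth


def gen_rfu(
    means: dict[str, float],
    n_reps: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Replicate RFU table: truth mean + Gaussian noise, floored at 0."""
    if any(m < 0 for m in means.values()):
        raise ValueError("true means must be non-negative")
    rng = np.random.default_rng(seed)
    rows = {
        g: np.clip(m + rng.normal(0.0, noise_sd, size=n_reps), 0.0, None)
        for g, m in means.items()
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rep{i+1}" for i in range(n_reps)]
    )
    df.index.name = "glycan"
    truth = {"seed": seed, "means": dict(means)}
    return df, truth
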