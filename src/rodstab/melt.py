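"""Two-state thermal denaturation fitting for single-wavelength CD melts.

The melt signal is modelled as a van 't Hoff two-state transition with linear
folded and unfolded baselines:

    signal(T) = (b_f(T) + b_u(T) K(T)) / (1 + K(T)),
    K(T) = exp[-dH/R (1/T - 1/Tm)]   (T in Kelvin),

where K is the unfolding equilibrium constant, Tm the midpoint (the reported
melting temperature) and dH the van 't Hoff enthalpy.  Fitting recovers Tm
from curves such as 220 nm ellipticity scanned in 2 degC steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

R_KJ = 8.314462618e-3  # gas constant, kJ/(mol K)
KELVIN = 273.15


@dataclass
class MeltCurve:
    """Temperature (degC, strictly increasing) vs. ellipticity-like signal."""

    temperatures_C: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures_C.size != self.signal.size:
            raise ValueError("temperature and signal lengths differ")
        if self.temperatures_C.size < 8:
            raise ValueError("need >= 8 points")
        if np.any(np.diff(self.temperatures_C) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class MeltFit:
    tm_C: float
    dH_kJ_mol: float  # van 't Hoff enthalpy
    baseline_folded: tuple[float, float]  # intercept, slope (per degC)
    baseline_unfolded: tuple[float, float]
    rms: float
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags

    def fraction_unfolded(self, temperatures_C) -> np.ndarray:
        T = np.asarray(temperatures_C, dtype=float) + KELVIN
        K = np.exp(-self.dH_kJ_mol / R_KJ * (1.0 / T - 1.0 / (self.tm_C + KELVIN)))
        return K / (1.0 + K)


def two_state_signal(
    temperatures_C, tm_C: float, dH: float, bf0: float, bf1: float, bu0: float, bu1: float
):
    """Model signal at the given temperatures (degC)."""
    tC = np.asarray(temperatures_C, dtype=float)
    T = tC + KELVIN
    K = np.exp(np.clip(-dH / R_KJ * (1.0 / T - 1.0 / (tm_C + KELVIN)), -500, 500))
    frac_u = K / (1.0 + K)
    return (bf0 + bf1 * tC) * (1.0 - frac_u) + (bu0 + bu1 * tC) * frac_u


def fit_melt(curve: MeltCurve) -> MeltFit:
    """Fit the two-state model; Tm is the fitted transition midpoint.

    Initialization: Tm at the steepest finite-difference slope of the signal,
    baselines from straight-line fits to the first and last temperature
    quartiles, dH from a generic 200 kJ/mol start.  A transition weaker than
    5x the local noise level or a midpoint outside the scanned range is
    flagged, never silent.
    """
    from lmfit import Model

    tC, y = curve.temperatures_C, curve.signal
    flags: list[str] = []

    # local noise from second differences; transition visibility check
    noise = float(np.std(np.diff(y, 2)) / np.sqrt(6)) if y.size > 2 else 0.0
    span = float(np.ptp(y))
    if noise > 0 and span < 5 * noise:
        flags.append("weak_transition")

    grad = np.gradient(y, tC)
    tm0 = float(tC[np.argmax(np.abs(grad))])
    q = max(2, tC.size // 4)
    bf1_0, bf0_0 = np.polyfit(tC[:q], y[:q], 1)
    bu1_0, bu0_0 = np.polyfit(tC[-q:], y[-q:], 1)

    model = Model(two_state_signal, independent_vars=["temperatures_C"])
    params = model.make_params(
        tm_C=tm0, dH=200.0, bf0=bf0_0, bf1=bf1_0, bu0=bu0_0, bu1=bu1_0
    )
    params["tm_C"].set(min=tC[0] - 20.0, max=tC[-1] + 20.0)
    params["dH"].set(min=1.0, max=5000.0)
    result = model.fit(y, params, temperatures_C=tC)

    if not result.success:
        flags.append(f"no_convergence: {result.message}")
    tm = float(result.params["tm_C"].value)
    if not tC[0] <= tm <= tC[-1]:
        flags.append("unresolved_tm: midpoint outside scanned range")
    return MeltFit(
        tm_C=tm,
        dH_kJ_mol=float(result.params["dH"].value),
        baseline_folded=(float(result.params["bf0"].value), float(result.params["bf1"].value)),
        baseline_unfolded=(float(result.params["bu0"].value), float(result.params["bu1"].value)),
        rms=float(np.sqrt(np.mean(result.residual**2))),
        flags=tuple(flags),
    )


# --- CSV I/O -----------------------------------------------------------------


def read_melt_csv(path: str | Path) -> MeltCurve:
    import pandas as pd

    df = pd.read_csv(path)
    return MeltCurve(df["temp_C"].to_numpy(), df["signal"].to_numpy())


def write_fits_csv(fits: dict[str, MeltFit], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"sample": s, "tm_C": f.tm_C, "dH_kJ_mol": f.dH_kJ_mol, "rms": f.rms,
             "flags": ";".join(f.flags)}
            for s, f in fits.items()
        ]
    ).to_csv(path, index=False)
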