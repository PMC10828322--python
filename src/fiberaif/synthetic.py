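"""Synthetic inputs: decaying-source count series and AIF-like curves.

``generate_decaying_series`` emulates a bench acquisition of a decaying
source seen through a non-paralyzable detector: true rate
``n(t) = n0 exp(-lambda t)``, observed rate ``m = n / (1 + n tau)``, with
optional Poisson counting noise per bin.  It feeds the dead-time fitter.

``generate_aif_curve`` is an explicit stand-in for an arterial input
function: a gamma-variate bolus with a stated peak concentration, peak time
and washout rate.  No particular AIF model is implied by the detector
study; the form and parameters ride along in the returned metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .counting import CountRateSeries
from .transport import EnergySpectrum


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Decaying-source series parameters (non-paralyzable detector)."""

    n0_cps: float
    lambda_: float  # 1/s
    tau_s: float
    bin_duration_s: float
    total_duration_s: float
    noise: str = "poisson"  # "none" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n0_cps, self.lambda_, self.bin_duration_s,
               self.total_duration_s) <= 0.0:
            raise ValueError("n0, lambda and durations must be positive")
        if self.tau_s < 0.0:
            raise ValueError("tau must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


def generate_decaying_series(spec: SyntheticSeriesSpec) -> CountRateSeries:
    """Observed count-rate series of a decaying source.

    Rates are evaluated at bin centers; Poisson noise draws the counts in
    each bin at mean ``m * bin_duration``.  Pure function of the spec.
    """
    n_bins = int(np.floor(spec.total_duration_s / spec.bin_duration_s))
    starts = np.arange(n_bins) * spec.bin_duration_s
    centers = starts + spec.bin_duration_s / 2.0
    true = spec.n0_cps * np.exp(-spec.lambda_ * centers)
    observed = true / (1.0 + true * spec.tau_s)
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(observed * spec.bin_duration_s)
        observed = counts / spec.bin_duration_s
    return CountRateSeries(starts, spec.bin_duration_s, observed)


@dataclass(frozen=True)
class SyntheticAIFSpec:
    """Gamma-variate bolus: concentration peaks at ``peak_time`` and decays
    at ``washout_rate`` asymptotically."""

    peak_concentration_kbq_ml: float
    peak_time_s: float
    washout_rate: float  # 1/s
    frame_duration_s: float
    total_duration_s: float = 600.0
    form: str = "gamma_variate"
    include_decay: bool = False
    decay_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_concentration_kbq_ml < 0.0:
            raise ValueError("peak concentration must be >= 0")
        if min(self.peak_time_s, self.washout_rate, self.frame_duration_s) <= 0.0:
            raise ValueError("peak time, washout and frame duration must be > 0")
        if self.include_decay and self.decay_constant <= 0.0:
            raise ValueError("include_decay requires a positive decay constant")


def _gamma_variate(t: np.ndarray, spec: SyntheticAIFSpec) -> np.ndarray:
    tp = spec.peak_time_s
    alpha = tp * spec.washout_rate
    x = np.clip(t / tp, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = spec.peak_concentration_kbq_ml * x**alpha * np.exp(alpha * (1.0 - x))
    c = np.where(t <= 0.0, 0.0, c)
    if spec.include_decay:
        c = c * np.exp(-spec.decay_constant * np.clip(t, 0.0, None))
    return c


def generate_aif_curve(spec: SyntheticAIFSpec):
    """Frame-integrated AIF samples as a DataFrame (time_s, concentration).

    Each sample is the average concentration over one frame, computed on a
    fine sub-grid.  Metadata with the functional form is attached in
    ``DataFrame.attrs``.
    """
    import pandas as pd

    n_frames = int(np.floor(spec.total_duration_s / spec.frame_duration_s))
    starts = np.arange(n_frames) * spec.frame_duration_s
    sub = np.linspace(0.0, spec.frame_duration_s, 17)
    grid = starts[:, None] + sub[None, :]
    conc = np.trapezoid(_gamma_variate(grid, spec), sub, axis=1) / spec.frame_duration_s
    df = pd.DataFrame({
        "time_s": starts + spec.frame_duration_s / 2.0,
        "concentration_kBq_mL": conc,
    })
    df.attrs["form"] = spec.form
    df.attrs["peak_time_s"] = spec.peak_time_s
    df.attrs["washout_rate"] = spec.washout_rate
    df.attrs["include_decay"] = spec.include_decay
    return df


def detectable_window(aif_frame, mda_kbq_ml: float):
    """Frames of an AIF curve whose concentration clears a given MDA."""
    mask = aif_frame["concentration_kBq_mL"].to_numpy() > mda_kbq_ml
    return aif_frame[mask]


_FIXTURES: Dict[str, Tuple[float, float, int]] = {
    # name -> (E_lo, E_hi, counts per 10 keV bin)
    "uniform_0_600": (0.0, 600.0, 10),
}


def spectrum_fixture(name: str) -> EnergySpectrum:
    """Deterministic canned spectra with known threshold efficiencies.

    ``uniform_0_600``: flat deposit spectrum over 0-600 keV with every
    emitted positron detected, so the efficiency at threshold ``t`` keV is
    exactly ``1 - t/600``.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; registered: {sorted(_FIXTURES)}")
    lo, hi, per_bin = _FIXTURES[name]
    edges = np.arange(0.0, 2000.0 + 10.0, 10.0)
    counts = np.zeros(len(edges) - 1)
    sel = (edges[:-1] >= lo) & (edges[1:] <= hi)
    counts[sel] = per_bin
    return EnergySpectrum(
        scene_name=f"fixture:{name}",
        bin_edges=edges,
        counts={("source_artery", "positron"): counts},
        n_histories={"source_artery": float(counts.sum())},
    )
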