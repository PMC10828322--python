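"""Dead-time estimation and AIF feasibility on synthetic data.

(1) Generates decaying-source acquisitions (Ga68 decay, non-paralyzable
dead time, Poisson counting noise) and recovers (n0, tau) with the
decaying-source regression, noiseless and over 100 noisy replicates.
(2) Builds a gamma-variate bolus peaking at twice the mouse-tail MDA and
reports the window of frames in which the detector can quantify it.
Writes results/deadtime_aif/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fiberaif import (
    SyntheticAIFSpec,
    SyntheticSeriesSpec,
    fit_dead_time,
    generate_aif_curve,
    generate_decaying_series,
    get_isotope,
)
from fiberaif.synthetic import detectable_window

out = Path("results/deadtime_aif")
out.mkdir(parents=True, exist_ok=True)

lam = get_isotope("Ga68").decay_constant
TAU = 2.3664e-6  # bench-scale dead time used as a realistic setting

clean = generate_decaying_series(SyntheticSeriesSpec(
    n0_cps=5e4, lambda_=lam, tau_s=TAU, bin_duration_s=10.0,
    total_duration_s=15 * 3600.0, noise="none"))
fit = fit_dead_time(clean, lam)
print(f"noiseless recovery: tau = {fit.tau_us:.4f} us (true {TAU * 1e6:.4f}), "
      f"n0 = {fit.n0_cps:.1f} cps")

rows = []
for seed in range(100):
    noisy = generate_decaying_series(SyntheticSeriesSpec(
        n0_cps=5e4, lambda_=lam, tau_s=TAU, bin_duration_s=1.0,
        total_duration_s=3 * 4062.6, noise="poisson", seed=seed))
    f = fit_dead_time(noisy, lam)
    rows.append({"seed": seed, "tau_us": f.tau_us, "n0_cps": f.n0_cps})
df = pd.DataFrame(rows)
df.to_csv(out / "deadtime_recovery.csv", index=False)
err = df["tau_us"] / (TAU * 1e6) - 1.0
print(f"poisson replicates (n=100): tau bias {err.mean() * 100:+.2f}%, "
      f"spread {err.std() * 100:.2f}%, worst {err.abs().max() * 100:.2f}%")

# AIF feasibility against the mouse MDA scale
MDA_MOUSE = 860.0  # kBq/mL, from the mouse-tail analysis at a 50 keV cut
aif = generate_aif_curve(SyntheticAIFSpec(
    peak_concentration_kbq_ml=2.0 * MDA_MOUSE, peak_time_s=30.0,
    washout_rate=0.01, frame_duration_s=1.0, total_duration_s=600.0))
aif.to_csv(out / "synthetic_aif.csv", index=False)
window = detectable_window(aif, MDA_MOUSE)
print(f"AIF bolus peaking at 2x MDA: {len(window)} of {len(aif)} one-second "
      f"frames are above the detection limit "
      f"(t = {window['time_s'].min():.0f}..{window['time_s'].max():.0f} s)")
print(f"wrote {out}/")
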