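"""Estimate dim-light melatonin onset by composite 24/12-h cosinor.

Simulates a noisy hourly melatonin profile with a known DLMO, fits the
composite cosine model to the z-scored series, back-transforms to pg/ml
and locates the upward crossing of the 10 pg/ml threshold.
"""

import numpy as np

from circatiming import (
    MelatoninSeries,
    compute_dlmo,
    fit_composite_cosinor,
    simulate_melatonin,
)

rng = np.random.default_rng(11)
true_dlmo = 14.4  # hours since the start of the constant routine
mel = simulate_melatonin(true_dlmo, noise_log_sd=0.15, rng=rng)

series = MelatoninSeries(mel["time_h"].to_numpy(), mel["conc_pgml"].to_numpy())
fit = fit_composite_cosinor(series)
est = compute_dlmo(fit)

amp24_pgml = fit.amp24 * fit.series_sd
print(f"fitted 24-h amplitude: {amp24_pgml:.2f} pg/ml, acrophase {fit.phase24:.2f} h")
print(f"fitted 12-h amplitude: {fit.amp12 * fit.series_sd:.2f} pg/ml")
print(f"true DLMO  {true_dlmo:.2f} h")
print(f"est. DLMO  {est:.2f} h   (error {est - true_dlmo:+.2f} h)")
print("\nThe DLMO is the time the back-transformed fitted curve rises from a "
      "low\nbackground through 10 pg/ml with positive slope; it anchors the "
      "circadian\ntime axis of the trajectory model.")
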