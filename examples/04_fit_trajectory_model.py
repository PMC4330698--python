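"""Fit the full 15-term heteroscedastic random-coefficient model.

Simulates one full-design cohort from the reference coefficients and
refits it from scratch, printing the Wald table and the amplitude/
acrophase implied by the circadian sine and cosine coefficients.
"""

from circatiming import (
    REFERENCE_BETA,
    ModelSpec,
    amplitude_phase,
    fit_occasions,
    simulate_from_lmm,
    wald_table,
)

occ, truth = simulate_from_lmm(seed=1)
fit = fit_occasions(occ, ModelSpec(), method="ML")

table = wald_table(fit)
table["truth"] = [REFERENCE_BETA[t] for t in table["term"]]
print(table.round(3).to_string(index=False))

print(f"\nlog-likelihood {fit.loglik:.1f}, n = {fit.n_obs}, "
      f"denominator df = {fit.df}, converged = {fit.converged}")
mult = {k: round(v, 2) for k, v in fit.var_multipliers.items()}
print(f"base residual SD {fit.sigma:.2f} (ratio units); cell multipliers {mult}")
coefs = dict(zip(fit.term_names, fit.beta))
amp, acro = amplitude_phase(coefs["sin"], coefs["cos"])
print(f"\ncircadian component (production reference): amplitude {amp:.2f} "
      f"ratio units, acrophase {acro:.1f} h after DLMO")
print("Negative TASK:exp means the estimation trajectory rises toward "
      "veridical\nwhile production falls — opposite behavioural imprints of "
      "one rising pacemaker rate.")
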