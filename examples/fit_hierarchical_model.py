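"""Fit the hierarchical Bayesian ANCOVA to a synthetic 95-lake survey.

Simulates a positive community response with a known latitude effect
(β_latitude = −2 on the log scale: the response declines northwards), then
refits it with the nested site-in-lake intercept model and adaptive
Metropolis sampling, and prints the posterior for the latitude slope with
convergence diagnostics and DIC.
"""

import math

import numpy as np

from pufalakes import (
    GeneratorConfig,
    ModelSpec,
    fit,
    generate_responses,
    generate_survey,
    simulate_parameter_state,
)

samples = generate_survey(GeneratorConfig(seed=1))
spec = ModelSpec(response="y", family="normal-on-log", continuous_terms=("latitude",))

mean_loglat = float(np.mean([math.log(s.latitude) for s in samples]))
truth = simulate_parameter_state(
    samples,
    mu0=3.0 + 2.0 * mean_loglat,  # responses around e^3 ~ 20 at the mean latitude
    tau0=0.05, sigma0=0.05,        # lake- and site-level intercept spread
    beta_cont={"latitude": -2.0},
    sigma2=0.01,                   # ~10% observation noise on the log scale
    seed=2,
)
responses = generate_responses(samples, spec, truth, seed=3)
print(f"{len(samples)} sites in {len({s.lake_id for s in samples})} lakes; "
      f"response range {responses['y'].min():.1f}-{responses['y'].max():.1f}")

result = fit(spec, samples, responses, n_iter=5000, n_chains=2,
             n_adapt=1000, burn_in=1000, thin=5, seed=4)
summary = result.summary().loc[["beta_latitude", "mu0", "sigma2"]]
print("\nPosterior summary (true beta_latitude = -2):")
print(summary.round(3).to_string())
print(f"\nDIC = {result.dic:.1f}  (Dbar = {result.dbar:.1f}, pD = {result.pd:.1f})")
print("rhat near 1 indicates converged chains; mc_error_ratio should stay below 0.05.")
print("The observation variance sigma2 mixes slowly: with one observation per site")
print("it is only weakly separated from the site-level variance (see docs/methods.md);")
print("the regression slopes are unaffected.")
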