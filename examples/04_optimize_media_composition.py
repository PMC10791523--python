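"""Response-surface optimization of the culture-medium composition.

Each trial is a media composition (α: fraction of neuronal N2B27
medium, β: serum % by volume) with the behaviour parameters inferred
under it.  Second-degree polynomial surfaces over (α, β) locate the
compositions that maximise or minimise each behaviour, and a blended
desirability vote suggests the next trial to run at the bench.
"""

import numpy as np
import pandas as pd

from myosim import (fit_quadratic_surface, standardized_regression,
                    suggest_next_composition, surface_extrema)

# seven synthetic trials on a media grid (the shapes mimic behaviours
# that peak at moderate serum and fall off with neuronal medium)
rng = np.random.default_rng(3)
alpha = np.array([0.0, 0.0, 0.0, 0.5, 0.5, 1.0, 1.0])
beta = np.array([0.0, 2.0, 10.0, 2.0, 5.0, 2.0, 10.0])
trials = pd.DataFrame({
    "alpha": alpha, "beta": beta,
    "t_rmax": 30 + 40 * np.exp(-((beta - 5) / 3.0) ** 2) - 10 * alpha,
    "t_mtfuse": 2.0 + 1.5 * (beta / 10.0) ** 2 + 0.8 * alpha
                - 1.2 * np.exp(-((beta - 5) / 3.0) ** 2),
    "k_nuc": 0.3 + 0.05 * beta - 0.004 * beta**2 + 0.2 * alpha,
    "dm": 200 + 500 * np.exp(-((beta - 5) / 4.0) ** 2) * (1 - 0.6 * alpha),
})

# which behaviours move the quality indicator? (effect sizes)
effects = standardized_regression(trials, "dm",
                                  ["t_rmax", "t_mtfuse", "k_nuc"])
print("standardized effects on dM:")
print(effects[["coef", "t", "p"]].round(3), "\n")

domain = ((0.0, 1.0), (0.0, 10.0))
fits = []
for var, direction in (("t_rmax", "maximize"), ("t_mtfuse", "minimize"),
                       ("k_nuc", "maximize")):
    fit = fit_quadratic_surface(trials[["alpha", "beta", var]].to_numpy(),
                                name=var)
    top = surface_extrema(fit, domain)[0]
    print(f"{var}: R2={fit.r2:.2f}, best {top.kind} at "
          f"alpha={top.location[0]:.2f}, beta={top.location[1]:.2f}")
    fits.append((fit, direction))

(a_next, b_next), audit = suggest_next_composition(fits, domain)
print(f"\nsuggested next trial: alpha={a_next:.2f}, beta={b_next:.2f}%")
print(audit.to_string(index=False))
# The suggestion is the composition where the most surfaces sit within
# 10% of their own optimum — the next dish to pour.
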