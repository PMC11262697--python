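"""Fit the dose-response regression forms used to summarize parameter
sweeps: the saturating exponential f(P) = a - b exp(-c P) for the VEGF
parameters, the linear and logistic forms for the gel parameters, and
the two-factor junction-versus-time surface.

Here the data are generated noiselessly from known coefficients, so the
fits recover them exactly (r^2 = 1); on real sweep output the same call
reports the fitted coefficients with their r^2.
"""

from capnet.fixtures import regression_dataset
from capnet.morphometrics import fit_regressions

x, y, truth = regression_dataset("exp_saturation")
fit = fit_regressions(x, y, form="exp_saturation")
print("saturating exponential f(P) = a - b exp(-c P)")
for name, true_val in truth.items():
    print(f"  {name}: fitted {fit.params[name]:.4g}   (generating "
          f"{true_val:.4g})")
print(f"  r^2 = {fit.r2:.6f}, adjusted r^2 = {fit.adj_r2:.6f}")

fit_lin = fit_regressions([1e9, 2e9, 4e9], [48.5, 64.5, 96.5], form="linear")
print("\nlinear f(kappa) = a1 + b1 kappa (traction sweep form)")
print(f"  a1 = {fit_lin.params['a']:.4g}, b1 = {fit_lin.params['b']:.4g}, "
      f"r^2 = {fit_lin.r2:.4f}")
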