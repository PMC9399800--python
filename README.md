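# sesakin

Kinetic modelling of the reversible isomerization of **sesamin** into its
epimer **asarinin** over a solid acid catalyst (citric-acid-loaded Hβ
zeolite) in sesame oil — for food/process chemists who want to simulate,
generate and fit concentration–time data for this system with honest
uncertainty reporting.

Asarinin is the more bioactive epimer, and it forms from sesamin during
acid-catalysed oil processing at 70–90 °C. The package implements the
site-balance (Langmuir–Hinshelwood) rate law for the batch reaction
A ⇌ B:

    R = k(T)·w_cat·([A] − [B]/K(T)) / (1 + K₁[A] + K₂[B])
    d[A]/dt = −R,   d[B]/dt = +R

with both temperature laws anchored at a reference temperature
T_ref = 353.15 K to decorrelate the pre-exponential factor from the
activation energy:

    k(T) = exp[ln k_ref + (Ea/RT_ref)(1 − T_ref/T)]
    K(T) = exp[ln K_ref + (ΔH_r/RT_ref)(1 − T_ref/T)]

Parameters are estimated by minimizing the multiresponse **determinant
criterion** S(θ) = (n+m+1)·ln|υ(θ)| over both observed species jointly,
with 95% marginal HPD half-widths, a parameter correlation matrix,
structural-indeterminacy flags (the adsorption constant K₁ is famously
non-identifiable when K₂ = K₁), per-response parity R², and a separate
Van't Hoff regression route for the reaction enthalpy. A closed-form
solution of the ODE system (exact when K₁ = K₂) serves as the analytic
oracle for the numerical integrator. Because no machine-readable
experimental data exist for this system, a synthetic-data module generates
datasets with the structure of the original nine-run campaign
(21.47–23.83 mmol/L sesamin, 70–90 °C, 1.0–3.0 wt.% catalyst, zero initial
asarinin, 3–240 min sampling, configurable measurement noise).

## Worked example

```python
import sesakin as sk

truth = sk.reference_parameters()          # ln k_ref=9.74, Ea/RTref=21.4,
                                           # K_ref=0.536, dH_r=34578, K1=4029.99
# generate a noisy nine-run campaign and refit it
data = sk.generate_dataset(truth, noise=sk.NoiseModel("multiplicative-gaussian", 0.02, 0))
from sesakin.workflows import perturbed_guess
result = sk.fit(data, perturbed_guess(truth), fixed=("K1",))
for name in result.free:
    print(f"{name:>14s} = {result.estimates[name]:10.4g}  "
          f"+/- {result.hpd[name]:.3g} ({result.hpd_percent[name]:.2f} %)")
print("parity R²:", {k: round(v, 4) for k, v in result.r2.items()})
```

prints (seed 0):

```
      ln_k_ref =      9.748  +/- 0.0143 (0.15 %)
 ea_over_RTref =      21.88  +/- 1.03 (4.73 %)
         K_ref =     0.5314  +/- 0.00933 (1.76 %)
          dH_r =  2.837e+04  +/- 3.5e+03 (12.32 %)
parity R²: {'sesamin': 0.9821, 'asarinin': 0.999}
```

i.e. with 2% measurement noise the four free parameters return to within
about two HPD half-widths of their generating values (9.74, 21.4, 0.536,
34578), and the parity plots of predicted versus observed concentrations
are tight for both species. The
reaction is endothermic (ΔH_r ≈ 34.6 kJ/mol), so the equilibrium asarinin
share — and with it the attainable conversion, K/(1+K)·100 ≈ 34.9 % at
80 °C — grows with temperature.

The numbered scripts under `analysis/` run the full study: dataset
generation, scenario simulations (temperature/loading/stirring effects),
the joint determinant-criterion fit, and the two-stage Van't Hoff
regression. A `sesakin` CLI (`generate`, `simulate`, `fit`, `report`;
`--config`, `--seed`, `--out-dir`, `--log-level`) wraps the same library
functions for shell use.

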