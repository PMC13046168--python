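# hawkesmix

Space-time self-exciting (Hawkes) point processes with mixed
Gaussian-type exponent kernels: fast closed-form likelihood estimation,
BIC order selection, branching simulation, and super-thinning residual
diagnostics.

## The problem

Event catalogs in epidemiology, seismology and crime analysis — each event
a location (x, y) in km and an occurrence time t — often show
*self-excitation*: an event raises the chance of further events nearby and
soon after. The canonical model is the conditional-intensity process

```
λ(x, y, t | H_t) = μ(x, y) + Σ_{i : t_i < t} g(x − x_i, y − y_i, t − t_i)
```

where μ is a temporally constant background (immigrants) and g a
triggering kernel (offspring). This package models both as sums of
Gaussian-type exponent components,

```
μ(x, y)     = Σ_{j=0..p} a_j exp(−α_{μ,j}(x − c_j)² − β_{μ,j}(y − d_j)²)
g(dx,dy,dt) = Σ_{j=0..q} b_j exp(−α_{g,j}dx² − β_{g,j}dy² − γ_{g,j}dt) ,
```

which buys two things:

* **a closed-form likelihood.** The compensator
  ∫∫∫ λ dx dy dt over a rectangle S and window D reduces to products of
  one-dimensional Gaussian interval masses (error functions) and
  exponential temporal masses — no numerical integration anywhere in the
  likelihood;
* **mixture flexibility.** The component counts (p+1, q+1) are chosen by
  BIC, `−2 log L + (5(p+1) + 4(q+1)) ln n`, so the kernels can adapt to
  multi-scale triggering without a nonparametric estimator's cost.

The remaining O(n²) triggering sum in the log term is truncated: each
event's sum runs over only its `n*` immediately preceding events (the
*modified truncated intensity*), cutting the cost to O(n·n*). `n*` can be
given directly (default 200) or derived from a time bound z as the largest
event count in any trailing window of length z.

Model adequacy is checked by *super-thinning*: thin events where the
fitted intensity exceeds a rate k, superpose simulated points where it
falls below, and test the residual pattern for homogeneity with the
edge-corrected Ripley K / centered L function against Monte-Carlo
envelopes.

## Worked example

Simulate a 5000-event catalog from the built-in burglary-like reference
kernel (background mass 5.71 events/day centred at (10, 10) km with scale
4.5 km; triggering mass θ = 0.2, decay ω = 0.1/day, offsets
σx = 0.01 km, σy = 0.1 km on a 20 × 20 km domain), then fit it:

```
$ hawkesmix --seed 1 simulate --n 5000 --out demo.csv
$ hawkesmix --seed 1 fit --catalog demo.csv --p 0 --q 0 --out demo_fit.json
order (p, q) = (0, 0)   n = 5000
loglik = -21679.5999   BIC = 43435.8546
converged = True   restarts = 3
background[0]: a=0.0453066 c=10.0368 d=10.0411 alpha=0.023781 beta=0.024305
trigger[0]: b=3.25854 alpha=4879.38 beta=49.9221 gamma=0.121486
trigger total mass = 0.170733
natural scale: mu_bar=5.92037 sigma_mu=(4.58532, 4.53563) c=10.0368 d=10.0411
  component 0: omega=0.121486 theta=0.170733 sigma_x=0.0101228 sigma_y=0.100078
```

The natural-scale block maps the raw exponent parameters back to the
generator's units: the background mass is recovered near 5.71, the
spatial scales near (0.01, 0.1), and the cluster location near (10, 10).
The decay estimate ω̂ ≈ 0.121 sits above the generating 0.1 and the mass
θ̂ ≈ 0.17 below 0.2 — the characteristic signature of the 200-event
truncation window, which attributes triggering mass beyond ≈ 30 days of
history to the background (fit with `--n-star -1` to derive the window
from the time bound z instead, which removes the bias at this event
rate; see `docs/methods.md`).

Order selection and residual diagnostics:

```
$ hawkesmix --seed 1 select --catalog demo.csv --grid 0,0 0,1 1,0
$ hawkesmix --seed 1 diagnose --catalog demo.csv --fit demo_fit.json \
      --out demo_diag.csv --plot demo_diag.png
```

`diagnose` writes per-distance columns `d, centered_L, env_lo, env_hi,
mean_L` (plus the super-thinned replicate band `st_lo, st_hi, st_mean`):
the residual curve staying inside `[env_lo, env_hi]` indicates the fitted
intensity homogenises the data, i.e. the model is adequate.

The same operations are available as a library (`hawkesmix.simulate_catalog`,
`fit_mle`, `select_order`, `superthin_diagnostic`, ...); geographic
catalogs (t, lon, lat) can be projected to km with
`project_equirectangular`.

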