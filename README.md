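# eatr

Unbiased transition rate constants — and a measure of how good your biasing
coordinate is — from enhanced-sampling simulations with time-dependent bias.

Molecular processes such as protein unfolding or ligand unbinding are rare
events: their waiting times grow exponentially with the free-energy barrier,
so plain molecular dynamics almost never observes them.  Methods like
metadynamics (MetaD) and OPES flooding deposit a history-dependent repulsive
bias V(ξ, t) along a collective variable (CV) ξ to force transitions within
reach, at the price of distorting the clock.  This package infers the
*unbiased* rate constant k₀ from an ensemble of such biased first-passage
simulations, for users of infrequent-metadynamics-style rate protocols who
want estimates that survive an imperfect CV.

## The model

A single-barrier escape has survival probability S(t) = e^{−k₀t}.  Under a
time-dependent bias the rate is scaled, k(t) = k₀ f(t), and

S(t) = exp(−k₀ Γ(t)),  Γ(t) = ∫₀ᵗ f(t′) dt′.

Three scaling functions are implemented, all fitted either by censored
maximum likelihood (LM) or by least squares against the empirical CDF of
first-passage times:

* **iMetaD** (hyperdynamics rescaling): f_i(t) = e^{βV_i(t)} per trajectory,
  so each trajectory's clock is dilated by its acceleration factor
  α_i = (1/t_i)∫₀^{t_i} e^{βV_i} dt.  Assumes a perfect CV.
* **KTR** (Kramers time-dependent rate):
  f(t) = exp(γβ⟨max_{t′≤t} V_i(t′)⟩), where γ ∈ [0, 1] is the *CV biasing
  efficiency* — the fraction of the applied bias that actually promotes the
  transition (γ → 1: good CV; γ → 0: bias wasted on orthogonal directions).
* **EATR** (exponential-average time-dependent rate):
  f(t) = ⟨e^{γβV_i(t)}⟩.  At γ = 1 (and all trajectories transitioned) it
  reduces *exactly* to the iMetaD estimator, so it bridges the two theories
  while still reporting γ.

The likelihood concentrates analytically in k₀
(k₀*(γ) = M / Σᵢ Γ(τᵢ) for M events among N trajectories, censoring
included), leaving a 1D profile optimization over γ.  Bootstrap errors,
Kolmogorov–Smirnov goodness-of-fit tests, and a slope-based (k₀, γ) fit for
OPES flooding ensembles at several barrier parameters (where the likelihood
is degenerate in γ) round out the toolkit.

A built-in overdamped-Langevin simulator on a 1D matched-harmonic barrier,
with WT-MetaD and OPES-flooding bias engines compiled via numba, generates
all benchmark data from scratch — no external trajectories needed — and the
Kramers reference rate is available in closed form and by numerical
quadrature.

## Worked example

Reproduce the unbiased 1D benchmark (barrier 8 k_BT, D = 0.02, dt = 0.01 τ,
100 walkers — about 10¹⁰ integrator steps, ~15 min on one core):

```
$ eatr simulate --out runs/unbiased8 --barrier 8 --bias none --n 100 \
      --max-time 2e7 --seed 1
$ eatr estimate --input runs/unbiased8 --method unbiased --fit cdf
k0 = 8.95283e-07 /tau  (log10 = -6.0480)  gamma = 1.0000  KS p = 0.999
$ eatr bootstrap --input runs/unbiased8 --method unbiased --fit cdf \
      --replicates 100 --seed 2
log10 k0 = -6.0480 +/- 0.0469  gamma = 1.0000 +/- 0.0000
```

The CDF-fitted rate, log₁₀k₀ = −6.05 ± 0.05, agrees with the closed-form
Smoluchowski-limit Kramers rate for this potential, 9.49 × 10⁻⁷ τ⁻¹
(log₁₀ = −6.02), and the KS p-value ≫ 0.05 confirms the transition times
are Poisson-distributed.  Biased ensembles work the same way, e.g.
`--bias wtmetad --pace 1000` followed by
`eatr estimate --method eatr --fit cdf --gamma free`, which prints k₀ and
the fitted CV biasing efficiency γ.

The same workflow is available as a library:

```python
import numpy as np, eatr
from eatr import simulator as sim

spec = sim.PotentialSpec(dU=8.0)                      # matched-harmonic barrier
bias = sim.MetaDParams(height=1.0, sigma=0.5, pace=100_000, biasfactor=2.0)
ens  = sim.run_ensemble(spec, sim.LangevinParams(seed=42), bias=bias, n=100)
est  = eatr.fit_cdf(ens, "eatr")                      # k0 and gamma, CDF fit
print(est.k0, est.gamma)
```

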