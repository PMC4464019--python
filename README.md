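# trajstat

Ensemble statistics and reporting for stochastic simulation time-series.

## The problem

Stochastic models of biochemical and ecological systems — Gillespie-type
chemical kinetics, birth-death processes, predator-prey dynamics — are
analysed through *simulation ensembles*: many independent realisations of
the same model, typically stored as one delimited text file per run (first
column time, remaining columns the model variables). The quantities a
modeller needs are statistical properties of that ensemble:

- the **average trace** X̄(t) = (1/n) Σᵢ Xᵢ(t) and its standard deviation
  σ_X(t) across the n runs;
- the **probability density** P(X_t = x) of a variable at a fixed time,
  estimated by histogramming the cross-run sample {Xᵢ(t)}, optionally with
  the closed-form Gaussian maximum-likelihood fit
  μ̂ = (1/n) Σ xᵢ, σ̂² = (1/n) Σ (xᵢ − μ̂)²;
- the same density swept over a time interval on shared state bins — an
  empirical estimate of the solution P(x, t) of the **master equation**
  ∂ₜP(x, t), which is generally accessible only through simulation;
- **phase-space** projections, per-variable extrema, and the plots that turn
  all of the above into a model-assessment report.

Jump-process trajectories are piecewise constant between reaction events and
different runs never share event times, so every statistic here is built on
a **zero-order-hold** sampling convention: the value of a run at time t is
its value at the latest recorded event ≤ t.

trajstat is simulator-agnostic — any tool that writes time-series text files
(or SBRML time-course documents) can feed it — and ships a built-in
Gillespie direct-method simulator with predator-prey and analytically
solvable birth-death models, used both for fixtures and for validating the
whole estimation pipeline against exact transient laws.

## Worked example

Estimate the law of an immigration-death process (influx k = 10, per-capita
death μ = 1) at t = 2 from 2000 simulated runs and compare it with the exact
transient law Poisson((k/μ)(1 − e^(−μt))):

```python
import math
from scipy import stats as ss
from trajstat import (generate_ensemble, immigration_death, pdf_at,
                      total_variation_from_pmf)

ens = generate_ensemble(immigration_death(10.0, 1.0), n_runs=2000,
                        t_max=3.0, seed=3)
est = pdf_at(ens, 2.0, "X", normed=True, fit=True)
lam = 10.0 * (1.0 - math.exp(-2.0))
tv = total_variation_from_pmf(est, lambda x: ss.poisson.pmf(x, lam))
print(f"mu={est.fit.mu:.3f} sigma2={est.fit.sigma2:.3f} tv={tv:.4f}")
```

prints

```
mu=8.557 sigma2=8.470 tv=0.0170
```

The fitted mean and variance both approximate λ = 8.647 (a Poisson law has
equal mean and variance), and the estimated histogram is within total
variation 0.017 of the exact distribution — Monte-Carlo error at n = 2000.

The `examples/` directory walks through every capability: dataset
generation, mean/SD traces, densities and fits, master-equation heatmaps,
config-driven batch reports, and SBRML interchange. The same operations are
available from the shell:

```bash
trajstat simulate --model lotka-volterra --n-runs 100 --seed 1 --out runs/
trajstat summary runs/
trajstat pdf runs/ --t 100 --var Preys --normed --fit
trajstat meq runs/ --var Preys --stop 100 --out meq.png
trajstat report --config report.yaml
```

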