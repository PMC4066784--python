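# duonet

Modelling and inference toolkit for two-gene regulatory networks, built
around the ERα–GATA3 circuit that maintains the luminal cell state in
ER-positive breast cancer cells.

ERα (estrogen receptor α) and GATA3 regulate each other and possibly
themselves; each of the four links — ERα autoregulation, GATA3→ERα,
ERα→GATA3, GATA3 autoregulation — can be activating (+), repressing (−) or
absent (∅), giving 3⁴ = 81 candidate sign topologies. `duonet` implements
the full computational workflow for resolving these signs from perturbation
experiments and for analysing the noise properties of the resulting
network:

* a dimensionless ODE model of normalised protein levels *e*, *g* with
  multiplicative fold-change Hill regulation,

  de/dt = s_e·b_e·F₁(e)·F₂(g) − k_e·e,  dg/dt = s_g·b_g·F₃(e)·F₄(g) − k_g·g,

  F_j(x) = (1 + f_j (x/K_j)^{n_j}) / (1 + (x/K_j)^{n_j}),

  where f_j > 1, < 1, = 1 encode positive, negative and null regulation,
  concentrations are normalised so the unperturbed steady state is (1, 1),
  and siRNA knockdown (synthesis scaling), cycloheximide windows
  (synthesis off) and the ER degrader ICI 182,780 (loss of active ERα) are
  first-class experimental conditions;
* exhaustive sign-topology enumeration and seeded multi-start
  least-squares fitting to siRNA depletion (0–48 h) and
  cycloheximide-chase recovery time courses, with statsmodels-style
  model/results objects;
* identifiability analyses: logarithmic link gains
  LG_j = d log F_j / d log x, link-elimination error changes, and
  steady-state ICI dose–response curves that discriminate the sign of ERα
  autoregulation;
* intrinsic noise by the Linear Noise Approximation (validated against an
  exact Gillespie simulation), controlled link removal that preserves
  means while exposing the noise-buffering role of the negative feedback,
  and extrinsic (parameter) noise by lognormal ensemble propagation;
* a synthetic-data generator that emulates the study's western-blot and
  qPCR readouts (multiplicative lognormal noise, replicate summaries) from
  a calibrated ground-truth network, so the entire pipeline is testable
  without external data.

## Worked example

```python
import numpy as np
import duonet as dn

# synthetic study: depletion + recovery time courses, 3 replicates, 10% noise
config = dn.GeneratorConfig(noise_cv=0.1, n_replicates=3, seed=11)
datasets = dn.generate_study(config)

# fit the nine autoregulation topologies (cross-links fixed to the
# experimentally determined signs) and rank them
leaderboard, fits = dn.rank_topologies(datasets, n_starts=200, seed=7)
print(leaderboard.to_string(index=False))
```

```
topology     error  error_ratio  passes
    ++-+ 12.700182     1.000000    True
    0+-+ 12.877897     1.013993    True
    -+-+ 12.877897     1.013993    True
    ++-0 55.272594     4.352110   False
    ++-- 55.272594     4.352110   False
    -+-0 55.436921     4.365049   False
    -+-- 55.436921     4.365049   False
    0+-0 55.498551     4.369902   False
    0+-- 55.498551     4.369902   False
```

Only the three topologies with positive GATA3 autoregulation (trailing
`+`) fit the data within twice the best error — the recovery kinetics of
GATA3 after a translation block are sigmoidal in a way no null or negative
autoregulation can reproduce. The ERα autoregulation sign is then probed
with the elimination analysis and the ICI dose–response prediction:

```python
changes = fits["-+-+"].eliminate_link(1, k=50)   # set f1 := 1, re-normalise
print(np.median(changes))                        # -> -2.6e-10 (percent)

curves = fits["0+-+"].dose_response([0.0, 0.1, 1.0, 10.0, 100.0], k=50)
print(curves[0].levels.round(3))                 # -> [1. 1.024 1.173 1.357 1.37]
print(curves[0].label)                           # -> 'increasing'
```

The negative-autoregulation topology only fits with its autoregulation
collapsed to nothing (eliminating it changes the error by ~10⁻¹⁰ %), and
the null-autoregulation fits predict a monotonically increasing
steady-state ERα mRNA proxy under the ER degrader ICI — the signature that
identifies the final network: GATA3→ERα activation, ERα→GATA3 repression
(an overall negative feedback) and positive GATA3 autoregulation, with no
ERα autoregulation.

The noise consequences of that architecture:

```python
topology, params = dn.default_ground_truth()
system = dn.StochasticSystem(params, topology, omega=500)
wt = dn.lna_noise(system)                        # CV_e 0.072, CV_g 0.052
cut = dn.lna_noise(dn.remove_link_controlled(system, 2))
print(cut.cv_g / wt.cv_g)                        # -> 1.22  (+22% GATA3 noise)
print(cut.cv_e / wt.cv_e)                        # -> 0.62
```

Cutting the GATA3→ERα arm of the feedback (means held fixed) raises GATA3
noise by >20% while ERα noise falls: the loop buffers the fluctuations
that GATA3's positive autoregulation would otherwise amplify.

A command-line surface wraps the same functionality:

```bash
duonet generate --seed 11 --out data.csv
duonet rank-topologies --data data.csv --starts 200 --seed 7
duonet run-all --out results/
```

## Layout

| module | contents |
|---|---|
| `duonet.model` | Hill folds, ODE integration, steady states, log gains |
| `duonet.topology` | sign topologies and enumeration |
| `duonet.fitting` | `TopologyFit` / `TopologyFitResults`, ranking, elimination |
| `duonet.doseresponse` | ICI dose–response curves and monotonicity labels |
| `duonet.noise` | LNA, Gillespie oracle, controlled removal, extrinsic noise |
| `duonet.synthetic` | calibrated ground truth and data generators |
| `duonet.pipeline` / `duonet.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the modelling assumptions, parameter
conventions, calibration choices and known limitations.
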