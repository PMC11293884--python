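# dispersalkit

Tools for studying **habitat selection during juvenile dispersal** from GPS
telemetry: net-squared-displacement segmentation of trajectories into
dispersal states, integrated step-selection analysis (iSSA) fitted per
individual per state, and inverse-variance pooling of coefficients to
population level — together with a seedable landscape and trajectory
simulator whose known selection coefficients let every stage be validated
against ground truth.

It is written for movement ecologists analyzing collar data from
wide-ranging animals (the motivating system is dispersing juvenile mountain
lions tracked at a 4-hour fix rate across two study sites), and for
methodologists who want a transparent, fully testable Python implementation
of the iSSA workflow.

## The model

A *step* is the straight segment between consecutive fixes; each observed
("used") step is matched with 20 random ("available") steps drawn from
tentative movement kernels — a gamma distribution for step length
`sl ~ Gamma(k, θ)` and a zero-centered von Mises for turning angle
`ta ~ vM(0, κ)` — fitted to the animal's own used steps.  With habitat
covariates `x` at step endpoints (log distance-to land-cover classes,
elevation, terrain ruggedness; z-scored), the conditional logistic
likelihood over strata `s` with steps `j`

```
L(β) = Π_s  exp(β·x_used) / Σ_j exp(β·x_j)
```

is maximized per individual by Newton iterations on the analytic gradient.
The fitted movement coefficients refine the tentative kernels
(`k' = k + β_log_sl`, `1/θ' = 1/θ − β_sl`, `κ' = κ + β_cos_ta`), and
coefficient contrasts give the log relative selection strength
`log-RSS = β·(x₁ − x₂)` with delta-method confidence intervals.
Individual coefficients pool to site level with inverse-variance weights:
`β̄ = Σ(βᵢ/seᵢ²)/Σ(1/seᵢ²)`, `se(β̄) = (Σ 1/seᵢ²)^(−1/2)`.

Dispersal states come from the net-squared displacement (NSD) of one
daily fix from the natal-range center: residency is a low plateau, an
*exploratory* sally rises and returns, a *departure* rises without
returning, and a post-departure plateau is a *transient home range*
(under six months) or an *established* range (over six months).

## Worked example

`examples/03_fit_step_selection.py` simulates one animal moving under known
standardized selection coefficients (forest −0.5, ruggedness +0.25,
developed +0.3) and fits the step-selection model to its 301 strata:

```
term               truth     beta      se
dist_developed      0.30    0.114   0.083
dist_forest        -0.50   -0.510   0.053
tri                 0.25    0.334   0.081
sl                     -   -0.000   0.000
log_sl                 -    0.178   0.142
cos_ta                 -    0.072   0.089

log-RSS for +1 SD log distance-to-forest: -0.510 (95% CI -0.613 .. -0.407)
```

Two of the three habitat coefficients land within about one standard
error of their truth; `dist_developed` misses by two — single-animal fits
are noisy, which is why coefficients are pooled across individuals (the
two-site example `04` recovers 0.4 and 0.0 to within one pooled SE).  The
negative log-RSS says endpoints one standard deviation farther from
forest are exp(−0.510) ≈ 0.60 times as likely to be chosen, all else
equal; `sl`, `log_sl`, `cos_ta` are the movement terms that feed the
kernel update.

The other examples cover landscape generation and the collinearity screen
(`01`), dispersal simulation and NSD state recovery (`02`), and the
two-site pooled comparison (`04`).

## Layout

```
src/dispersalkit/
  grid.py         planar raster grid + plain-text (ESRI ASCII) raster I/O
  landscape.py    synthetic land-cover / elevation generator
  covariates.py   distance-to, log transform, TRI, collinearity screen, extraction
  simulate.py     discrete-choice trajectory simulator with scheduled states
  preprocess.py   ingest, resampling to a fix rate, kill-site cluster removal
  nsd.py          daily NSD, natal-range estimation, state classification
  issa.py         movement kernels, random steps, conditional logit, log-RSS
  pooling.py      inverse-variance pooling and the two-site comparison
  pipeline.py     end-to-end conveniences used by the examples and studies
  experiments.py  the validation experiments behind tests and acceptance
```
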