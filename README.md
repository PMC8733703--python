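# hybridoe

Hybrid (grey-box) modeling of fed-batch CHO cell culture processes, built
around a simulated two-scale design-of-experiments study: a full-factorial
shake-flask characterization (cultivation temperature × feed glucose level),
15 L bioreactor runs with static and *intensified* designs (intra-experimental
shifts of the critical process parameters), and the question of how well a
model trained at one scale or design style transfers to the other.

## Who this is for

Process-development scientists and modelers who want a tested, end-to-end
reference implementation of serial hybrid modeling for mammalian fed-batch
processes: data structures for cultivation runs, a ground-truth simulator to
develop against, spline-based rate estimation, ensemble training with
run-level cross-validation, and the input-selection workflow.

## The model

A serial hybrid: a single-hidden-layer network (4 tanh neurons, linear
output) maps six z-scored process inputs — cultivation temperature, feed
glucose level, glutamine, asparagine, alanine, and the aspartate/glutamate
ratio — to the specific growth rate μ and the specific production rate
v<sub>P/X</sub>, which drive the fed-batch mass balances

    dX/dt = μ·X − D·X
    dP/dt = v_P/X·X − D·P

with X the viable cell concentration, P the product titer, and D the
dilution rate (feed flow / volume; daily 3.3 % v/v bolus events at the
shake-flask scale). The network is trained by damped Levenberg–Marquardt
with an L2 weight penalty *through* the integrated balances, against
mean-normalized VCC and titer residuals at the sampling times. Run-level
cross-validation (0.6 random splits, or leave-one-run-out for intensified
designs) yields one model per partition at its minimal validation NRMSE;
the ensemble average carries per-time SD and CI bands

    SD(t) = sqrt( Σᵢ (ŷ_avg(t) − ŷᵢ(t))² / (n−1) ),   CI(t) = ŷ_avg ± SD(t)

and performance is reported as NRMSE[%] = 100·RMSE/mean(y).

Because the study's original cultivation data are not public, the package
ships a calibrated ground-truth simulator (`hybridoe.synthetic`) whose
noiseless center-point trajectories reproduce the study's landmark values,
and whose true rate functions are known — so recovery, transfer and
input-selection claims are all testable.

## Worked example

```
$ python examples/transfer_experiment.py
training on 21 runs, testing on 8 bioreactor runs
train: NRMSE VCC 8.9 %, titer 14.0 %
test: NRMSE VCC 14.2 %, titer 19.6 %
```

The ensemble is trained on the 18 shake-flask runs plus the three
bioreactor center points, then applied — with no refitting — to the eight
remaining 15 L runs (two static, six with intra-experimental CPP shifts).
Test errors a few points above the training errors mean the six inputs
carried the scale-dependent kinetics; see `examples/` for the other
capabilities (simulation, rate estimation, input selection), and the
`hybridoe` command line (`hybridoe simulate|train|evaluate|select-inputs`)
for file-based workflows.

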