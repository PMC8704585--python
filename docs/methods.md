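# Methods

## Model

Two feature detectors, tuned to opposite vernier polarities, act as
leaky integrators of piecewise-constant stimulus drive, and a third
leaky stage pools their difference:

    dx_V/dt  = m(t) [ −τ x_V  + I_V(t) ]
    dx_AV/dt = m(t) [ −τ x_AV + I_AV(t) ]
    dy/dt    = m(t) [ −τ y + x_V − x_AV ]

All states start at rest (0). The pooled activity at the readout time
r is mapped to percent accordance by d(y) = 100/(1 + exp(−2y/σ)), and
dominance = accordance − 50. The system is linear in the drives, so
responses to drive decompositions superpose exactly — the mechanistic
counterpart of the observed near-linearity of feature integration
(single-offset dominances approximately add to the combined-condition
dominance when |y| ≪ σ).

The binary gate m(t) encodes the difference between the two memory
stores. With m ≡ 1 (`variant="leaky"`) contents decay with time
constant 1/τ throughout — the retinotopic store. With
`variant="gated"`, m = 0 during inter-frame blanks: both input and
leak are switched off and the state is frozen exactly, which is how the
non-retinotopic store preserves frame-1 contents across 100–220 ms
blanks. The default gating policy (`isi_only`) closes the gate exactly
on the gaps between display-frame windows and leaves it open after the
last frame; the alternative `every_offset` closes it whenever no
element is on screen, including permanently after the last offset
(reflecting the reading that the offset transient itself triggers the
freeze). The bracket in the pooled-stage equation is taken to gate the
full right-hand side, consistent with the two feature stages.

Assumptions worth stating: masking is not modelled mechanically —
metacontrast enters only through which store's contents survive;
element vs. group motion in Ternus displays is supplied by the caller
(the ISI-dependence of the percept is not predicted); attention/cueing
is not a model input, so predictions depend only on the event train —
integration is mandatory (covered by a test: positions, stream labels
and eccentricity metadata never reach the integrators).

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| τ (`tau`) | ms⁻¹ | 0.0291 | decay rate; 1/τ ≈ 34.36 ms time constant of the retinotopic store |
| σ (`sigma`) | activity units | 80 | sigmoid slope; sets how much pooled activity saturates the percept |
| r (`readout`) | ms | 300 | readout time, measured from first-frame onset (option: from last offset) |
| amplitude | — | 1 | drive per element; fixed, since a joint rescaling of amplitude and σ leaves every prediction unchanged (tested) |
| `tau_y` | ms⁻¹ | = τ | optional distinct pooled-stage rate; default shares the single fitted rate |

τ = 0.0291 ms⁻¹ is the fitted decay rate of the retinotopic store and
is used as the generating value everywhere. σ = 80 and r = 300 ms are
this package's choices for synthetic-data generation: with unit drive
and 30 ms elements the pooled activity reaches magnitudes of roughly
80–300, so σ = 80 places the anchor conditions on the informative part
of the sigmoid (V-AV-S at about −38% dominance, matching the observed
strong anti-vernier dominance) without saturating everything, and
r = 300 ms lies just after frame 2 for the standard 30 ms / 160 ms
two-frame timing. Stimulus-construction defaults: 30 ms element
duration and SOA for metacontrast streams; 400 ms integration window
(configurable to 450 ms) after which events no longer drive the
integrators; retinotopic positions are integer indices and physical
eccentricity is metadata only.

## Numerics

Drives are piecewise constant, so the cascade is solved exactly on the
merged segmentation of drive breakpoints and gate switches. On an
open-gate segment with constant drive c, x(t) = c/τ + (x(a) −
c/τ)e^(−τ(t−a)); the pooled stage sees forcing F0 + F1 e^(−τ(t−a)) and,
because both stages share τ, carries the repeated-eigenvalue term
(t−a)e^(−τ(t−a)) (the distinct-rate two-exponential form is used when
`tau_y` differs by more than 1e−10 relative). Closed gates copy the
state forward unchanged. A fixed-step 4th-order Runge–Kutta integrator
(0.01 ms steps, segment-aligned so discontinuities never fall inside a
step) lives in the test suite as an independent oracle; the closed form
matches it to better than 1e−6 relative on random gated drives, and the
spot checks x(30 ms) ≈ 20.0 for unit drive at τ = 0.0291 and a ≈0.95%
residual after 160 ms of free decay come from that oracle. For fitting
loops a precompiled per-condition segment program
(`CompiledCondition`) evaluates y(r) by scalar recursion; it agrees
with the reference path to machine precision (tested) and is ~200×
faster.

Degenerate inputs: an empty or all-straight train gives y ≡ 0 and
exactly chance accordance; a readout before late events simply ignores
them; overlapping same-polarity events sum their drives; occluded or
out-of-window events keep their place in the stream but contribute no
drive.

## Fitting

Loss is the sum of squared residuals on the dominance scale (a binomial
log-likelihood objective is available for count data). Bounds default
to τ ∈ [1e−4, 1] ms⁻¹, σ ∈ [1e−3, 100], r ∈ [0, 1000] ms. The loss
surface has large plateaus — wherever |y(r)| ≫ σ for most conditions the
predictions pin at ±50% and the loss is locally flat — so plain
multi-start local search from uniform draws stalls often, and scipy's
*bounded* Powell was observed to return points worse than its start on
this surface. The fit therefore screens a seeded pool of uniform draws
(default 512) by loss, runs bounded Nelder–Mead from the best
`n_starts` (default 8) in log(τ), log(σ), r coordinates, and reports
the best start, with ties broken by lower τ and then start index. Fits
are bit-reproducible given the seed. Note that bounds excluding the
generating τ do not necessarily pin the fit at the bound: σ and r can
compensate, producing a genuinely interior (if worse) optimum.

## Synthetic data

Observers are simulated as binomial: k ~ B(n, accordance/100) per
condition, n = 100 trials by default (a typical psychophysics session
scale). Batteries always begin with the three named anchor conditions
(V-AV-S, S-S-V, V-AV-V-AV at 30 ms sub-frames, 160 ms blank, group
motion) followed by randomized V/AV/S combinations with frame durations
in [10, 100] ms and blanks in [0, 300] ms, bracketing the published
timings; the default battery size is 33 conditions. The
generator emulates stationary, lapse-free, bias-free observers with
model-true percepts; it does not emulate attentional lapses, response
bias, learning, reaction times or inter-observer variability, so
passing recovery tests shows the *procedure* is consistent, not that
real data are this clean. Parameter recovery refits each synthetic
replicate; on noise-free predictions from a 33-condition battery the
generating τ = 0.0291 ms⁻¹ is recovered to well within 5% (machine
precision in practice), and with binomial noise at realistic trial
counts τ remains identifiable while σ and r — which trade off against
each other on saturated conditions, and r is additionally frozen
through blanks in the gated variant — recover with visibly larger
spread, especially on batteries without ISI variation.

## Design choices

The element-vs-group percept is an input, not a prediction. Dominance
is canonically accordance − 50 (clipping of the additivity prediction
happens only at reporting). Gating derives from frame windows rather
than from a free parameter. Occlusion is a flag that silences an
element's drive while preserving stream continuity; removal deletes the
element and splits the stream at the gap — exactly the two outcomes the
saccade/occlusion manipulations distinguish. Problem sizes used by the
test suite and acceptance script (33-condition batteries, 100 random
oracle drives, recovery with a handful of replicates) were chosen as
the smallest sizes that exercise every code path meaningfully.

## Known limitations

No masking mechanism, no spiking or population dynamics, no prediction
of motion correspondence or of Korte's-law tradeoffs, no
hierarchical/multi-observer fitting, and no lapse/guess-rate
psychometric extensions. The smear model reduces motion blur to the
trailing-threshold length (speed/τ)·ln(1/threshold) of an exponentially
persisting point trace; the density-dependent *suppression* of smear in
continuous motion is out of scope.
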