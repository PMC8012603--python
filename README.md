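# pcfret

Separation of spectrally identical FRET pairs by donor photochromism.

Many FRET biosensors share the same cyan/yellow fluorophore pair, so two
sensors expressed in the same cell are indistinguishable by emission
spectrum alone. `pcfret` implements an analysis that separates such
overlapping pairs when their donors differ in *photochromism* — reversible,
light-driven on/off switching of donor fluorescence. Alternating on- and
off-switching irradiation turns every FRET timepoint into a pair of
acquisitions whose ratio (the photoswitching ratio ρ) differs between
pairs, and a linear unmixing of the paired signals recovers each pair's
contribution and FRET efficiency. The package is aimed at quantitative
fluorescence microscopists running multiplexed biosensor experiments, and
at anyone evaluating the approach on simulated photon budgets.

## The model

A sensitized-emission acquisition measures donor-excited donor emission
S_DD, donor-excited acceptor emission S_DA, and directly excited acceptor
emission S_AA. After cross-talk correction with bleed-through α and
cross-excitation δ,

    F_c = S_DA − α·S_DD − δ·S_AA,        Θ = 1 / (γ·S_DD / F_c + 1),

where γ is the acceptor/donor brightness-and-collection factor and Θ the
FRET efficiency. Off-switching light reduces the signals of a photochromic
donor by the photoswitching ratios ρ_D = S_DD,off / S_DD,on and
ρ_A = F_c,off / F_c,on. Because FRET competes with photochromism, ρ depends
on Θ; for a single well-behaved species

    ρ(Θ) = ρ₀^(1−Θ),

with ρ₀ the ratio measured absent FRET. Real biosensors use an empirical
calibration instead (double-exponential or straight line, fitted by
orthogonal distance regression).

With two co-expressed pairs the measured signals are sums over the pairs,

    S_DD,on  = S_DD,on,1 + S_DD,on,2          S_DA,on  = S_DA,on,1 + S_DA,on,2
    S_DD,off = ρ_D,1·S_DD,on,1 + ρ_D,2·S_DD,on,2
    S_DA,off = ρ_A,1·S_DA,on,1 + ρ_A,2·S_DA,on,2

— four equations in four unknowns, solved exactly per channel. Since the ρ
values depend on the unknown efficiencies, the solver iterates: evaluate
each pair's calibration at the current Θ estimate, solve the linear system,
recompute Θ from the recovered signals, repeat to a fixed point. The scheme
extends to n pairs with n acquisitions per switching cycle.

The package also provides the Poisson photon-budget Monte-Carlo study used
to validate the approach (accuracy scored by the mean absolute deviation,
MAD, of the recovered efficiencies against a random-guess control) and the
downstream time-lapse pipeline: ROI extraction with background
subtraction, photobleaching baseline fits, percent-increase responses,
onset times, and k-means classification of cellular response profiles.

## Worked example

Simulate one paired on/off acquisition of a mixture of a photochromic
sensor (ρ₀ = 0.3, true Θ = 0.35) and a photostatic one (ρ₀ = 1.0, true
Θ = 0.10), each with a 4000-photon budget, and unmix it:

```python
import numpy as np
from pcfret import (PairSimSpec, StudyCondition, iterative_unmix,
                    power_law_pair_model, random_guess_control, run_study,
                    simulate_acquisition)

specs = (PairSimSpec(brightness_n=4000, rho0=0.3),   # photochromic donor
         PairSimSpec(brightness_n=4000, rho0=1.0))   # photostatic donor
models = (power_law_pair_model("rs", specs[0], (0.0, 0.6)),
          power_law_pair_model("ek", specs[1], (0.0, 0.6)))

on, off = simulate_acquisition(specs, thetas=[0.35, 0.10], rng=1)
res = iterative_unmix(on, off, models)
print(f"recovered theta: pair 1 = {res.theta[0]:.3f}, "
      f"pair 2 = {res.theta[1]:.3f} ({res.iterations} iterations)")

study = run_study([StudyCondition("1000 photons",
                                  (PairSimSpec(1000, 0.3), PairSimSpec(1000, 1.0)),
                                  n_sims=500, seed=1)])
control = random_guess_control((0.0, 0.6), 500, seed=1)
print(f"median MAD at 1000 photons: {study[0].summary['median']:.4f}")
print(f"random-guess control median: {control.summary['median']:.4f}")
```

Output:

```
recovered theta: pair 1 = 0.353, pair 2 = 0.102 (3 iterations)
median MAD at 1000 photons: 0.0275
random-guess control median: 0.2020
```

Despite Poisson noise on every channel, the two efficiencies come back
within a few thousandths of the ground truth, and across 500 random
draws the analysis at a 1000-photon budget is an order of magnitude more
accurate than guessing (MAD 0.028 vs 0.202).

The same machinery is exposed as a CLI: `pcfret simulate`,
`pcfret calibrate`, `pcfret unmix`, `pcfret analyze-traces`, and
`pcfret fixtures` (see `pcfret --help`).

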