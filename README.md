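# pausekit

Kinetic and statistical analysis of transcriptional pausing by RNA
polymerase (RNAP): how pausing, overall speed, termination, restart under
force, and fidelity change between two conditions — typically with and
without a trailing, translating ribosome coupled to the polymerase.

It is written for single-molecule biophysicists and molecular biologists
who have (a) quantified gel time courses of transcription reactions,
(b) optical-tweezers records of single transcribing polymerases,
(c) restart-time tables from force-clamp experiments, and/or
(d) consensus sequencing reads for misincorporation calling — and want
the pause kinetics, restart energetics and per-position error statistics
those data support, with a synthetic-data generator for validating every
estimator.

## The model

At a pause-prone site, on-pathway elongation (rate *k*ₙ) competes with
off-pathway pause entry (rate *k*ₚ). The pause efficiency is the
branching ratio

> *E* = *k*ₚ / (*k*ₚ + *k*ₙ)

and, because an escaped polymerase can re-enter the pause, the apparent
pause duration is

> *T*app = (1/*k*₋ₚ) / (1 − *E*)

so the pause-band fraction on a gel decays as *P*(*t*) = *P*₀·e^(−*k*₋ₚ,app·*t*),
fit on a semilog scale (two segments, with exponential peeling, when a
second "sluggish" paused population is present). Tweezers traces are
converted to bp via the extensible worm-like chain, step-fit with a
monotone 1-bp staircase HMM, and crossing times through a 5-bp window
around a pause are fit by maximum likelihood to
*a*₁*k*₁e^(−*k*₁*t*) + *a*₂*k*₂e^(−*k*₂*t*) (*k*₁ > *k*₂), giving
*E* = *a*₂ and τ = 1/*k*₂. Restart of a backtracked, mismatch-bearing
polymerase follows a piecewise Arrhenius law
*t*(*F*) = *t*₀·exp(−*F*·Δx/*k*B*T*), constant above *F*max, fit
bilinearly in ln *t*; Δx/0.34 nm is the backtrack depth in nucleotides.
Per-position misincorporation is contrasted by relative percent error
and two-sided Fisher exact tests. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

Fit a biphasic pause decay (12 gel timepoints, 5% quantification noise,
generated from slow amplitude 0.359 / 2.1 min and sluggish 0.068 /
9.1 min) and compare two pause efficiencies:

```python
import numpy as np
from pausekit.gel import fit_two_segment
from pausekit.kinetics import rescue_fraction, predicted_duration_fold_change
from pausekit.io import named_rng

t = np.geomspace(0.5, 30, 12)          # minutes
decay = 0.359*np.exp(-t/2.1) + 0.068*np.exp(-t/9.1)
noisy = decay * named_rng(7, "demo").lognormal(0.0, 0.05, t.size)
fit = fit_two_segment(t, noisy)
print(f"slow:     E = {fit.e_slow:.3f}   T_app = {fit.t_slow_app:.2f} min")
print(f"sluggish: E = {fit.e_sluggish:.3f}   T_app = {fit.t_sluggish_app:.2f} min")
print(f"rescue fraction (0.427 -> 0.232): {rescue_fraction(0.427, 0.232):.2f}")
print(f"predicted duration fold change:   {predicted_duration_fold_change(0.427, 0.232):.2f}")
```

prints

```
slow:     E = 0.350   T_app = 2.05 min
sluggish: E = 0.070   T_app = 9.05 min
rescue fraction (0.427 -> 0.232): 0.46
predicted duration fold change:   1.34
```

i.e. the fit recovers the generating amplitudes and durations of both
paused populations; a drop in efficiency from 42.7% to 23.2% means 46%
of pausing events are rescued, and the re-entry relation alone predicts
a ~1.3-fold shorter apparent pause duration.

The same analyses are available from the command line:

```sh
pausekit simulate --out-gel gel.csv --n 2000 --seed 7
pausekit gel-fit --input gel.csv --site 34 --model single --seed 7
pausekit restart-fit --input restarts.tsv --bootstrap 500 --seed 7
pausekit errors --plus plus.fa --minus minus.fa --ref ref.fa
```

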