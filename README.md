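# turnofit

Kinetic analysis of multi-turnover DNA cleavage by Cas9-type nucleases:
mass-action simulation of the enzyme turnover cycle, simulation-based
global fitting of product timecourses with locked and floating rate
constants, profile-likelihood (confidence-contour) limits, burst-phase
analysis, and gel-quantification arithmetic.

## The problem

Cas9 cleaves its DNA target quickly but then stays bound to the cut
product, so under substrate excess the product timecourse shows a rapid
burst that plateaus at the enzyme concentration — single-turnover
behaviour. Truncating or mismatching the guide RNA accelerates product
release and turns the enzyme into a multi-turnover catalyst. Resolving
*why* requires separating the intrinsic rate constants of the cycle,
which observed rates alone cannot do; the standard approach is global
fitting of complete timecourses against the mass-action scheme

```
            k_on          k_cat         k_rel
    E + S  <====>  ES  --------->  EP  <====>  E + P
            k_off                        k_rebind
```

with E the guide-loaded enzyme (RNP), S the uncut target, ES the
pre-cleavage complex, EP the product-bound complex and P released
product. Substrate binding is locked at Kd = k_off/k_on = 1 nM; product
rebinding (E + P -> EP) is what makes accumulating product inhibit
turnover. Units are nM and minutes throughout.

The package ships three parameter presets for the turnover assay
conditions (20 nM active enzyme, 100 nM plasmid substrate):

| preset | guide                  | k_cat (min⁻¹) | k_rel (min⁻¹) |
|--------|------------------------|---------------|---------------|
| `20nt` | full-length            | 60 (locked)   | 0.00085       |
| `15nt` | truncated 15-nt        | 0.109         | 0.005         |
| `2mm`  | 2 terminal mismatches  | 0.723         | 0.053         |

Because no raw densitometry data are deposited for these assays, a
seeded synthetic-data generator reproduces the assay design and noise
structure so that every stage — fitting, profiling, burst analysis — is
testable end to end.

## Worked example

Generate a noisy turnover dataset under the mismatch-guide preset, fit
it, and profile the release constant:

```bash
$ turnofit --seed 1 generate --preset 2mm --out demo_2mm.csv
$ turnofit fit demo_2mm.csv --preset 2mm
converged: True
chi2_min: 26.0836  (n_points=32, n_free=2)
k_on      1  [locked]
k_off     1  [locked]
k_cat     0.73254  [fitted]  +/- 0.0412
k_rel     0.0521595  [fitted]  +/- 0.00156
k_rebind  1  [locked]
```

The fitted cleavage and release constants recover the generating values
(0.723 and 0.053 min⁻¹) to a few percent; the binding step stays locked
at Kd = 1 nM. Profile-likelihood limits at the 0.99 F-threshold:

```bash
$ turnofit profile demo_2mm.csv --preset 2mm --param k_rel --out prof.csv
estimate k_rel = 0.0521595
chi2_min = 26.0836, threshold(0.99) = 35.4569
limits: [0.0479236, 0.05875]
```

The interval brackets the generating k_rel = 0.053 min⁻¹. Quantification
arithmetic and fold changes:

```bash
$ turnofit report --lane 50,25,25 --release 3,1 --fold 0.053,0.00085
lane (50,25,25): 50.00% cleaved
release (3,1): fraction released 0.7500
fold (0.053,0.00085): 62.35
```

A lane with bands (linear 50, nicked 25, supercoiled 25) is 50% cleaved;
released/(released+bound) = 3/4; and the mismatch-guide release constant
exceeds the full-length one 62.35-fold — the product-release difference
that converts single-turnover into multi-turnover behaviour.

The same operations are available as a library:

```python
import turnofit as tf

rates, design = tf.preset("2mm")
ds = tf.generate_timecourse(rates, design, tf.NoiseModel(seed=1))
fit = tf.fit_global([ds], float_params=("k_cat", "k_rel"), init=rates)
print(fit.estimates.k_cat, fit.estimates.k_rel)
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the numerical
choices (integrator, optimiser, profile interpolation) and the known
limitations of the synthetic-data generator.
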