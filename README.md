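# rmmtree

Response-mixture IRTree modeling of Likert-scale data whose middle
category may hide non-responses.

## The problem

Likert items often include a neutral middle option.  Respondents use it
in two very different ways: to communicate a genuinely neutral position
(informative), or as a covert "I won't / can't answer" (non-informative).
Both uses produce the same observed score, so ordinal models that treat
every middle response as informative — such as the graded response model
(GRM) — confound measurement: trait estimates shrink, discrimination
parameters are underestimated, and the middle thresholds are pushed
apart.

`rmmtree` implements a response-mixture IRTree model (RMM) that treats
each response as the outcome of a two-node decision tree.  Node 1 is a
probit non-response process, `P(Z_pi = 1) = Φ(−α₁θ_p1 − β_i)`, where
`Z_pi` indicates an informative response, θ₁ is a per-person non-response
tendency and −β_i an item intercept.  Node 2, reached when `Z = 1`, is a
probit GRM over all `h + 1` categories,
`P(X_pi ≥ k | Z = 1) = Φ(α₂ᵢθ_p2 − δ_ik)`, measuring the substantive
trait θ₂.  A middle response can come from either path; the model infers,
per response, the posterior probability that it was informative.  Two
baselines are included: the GRM (all middle responses informative) and a
hard IRTree (none informative).

Estimation is Bayesian: a Gibbs sampler with probit data augmentation,
per-draw identification rescaling (traits standardized, Σ a correlation
matrix), and DIC model comparison with the non-response trait integrated
out by Gauss–Hermite quadrature.  A synthetic-data module generates data
by literal tree traversal and drives a parameter-recovery study
comparing RMM and GRM under 0–20% non-response rates.

Intended users: psychometricians and applied researchers analyzing
questionnaire scales with a neutral midpoint, and methodologists studying
response styles.

## Worked example

```python
import rmmtree as rt

space = rt.CategorySpace(4)                      # 5 categories, middle = 2
items = rt.generate_item_bank(25, nr_rate=0.2, seed=11)
persons = rt.generate_person_bank(1000, seed=12)
data, z_true = rt.generate_responses(persons, items, space, seed=13)

samples = rt.fit(data, config=rt.ChainConfig(1500, 300, 2, seed=7, model="rmm"))
nr = rt.nr_summary(samples, data)
print(f"first-node slope alpha1 = {samples.alpha1.mean():.2f}")
print(f"overall P(non-informative) = {nr.overall:.3f}  (truth {1 - z_true.mean():.3f})")
print(f"among middle responses    = {nr.middle_only:.3f}")
print(f"theta1-theta2 correlation = {samples.Sigma[:, 0, 1].mean():+.2f}")
```

Output:

```
first-node slope alpha1 = 0.55
overall P(non-informative) = 0.194  (truth 0.188)
among middle responses    = 0.476
theta1-theta2 correlation = +0.07
```

The fitted mixture recovers the generated ~19% non-informative share,
and finds that just under half of the *observed* middle responses were
non-informative (the rest are genuine neutral answers).  The traits were
generated independently, and the estimated correlation is near zero.

A command-line interface wraps the same functionality:

```bash
rmmtree simulate --N 1000 --K 25 --nr-rate 0.2 --seed 1 --out-dir sim/
rmmtree fit sim/responses.csv --model rmm --seed 2 --out-dir fit/
rmmtree dic sim/responses.csv --models rmm,grm,irtree --seed 3 --out-dir dic/
rmmtree summarize sim/responses.csv --seed 4 --out-dir sum/
```

Every run writes a `manifest.json` (seed, config, input checksum,
version) sufficient to reproduce it exactly.

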