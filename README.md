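# bayesequiv

Bayesian equivalence testing for two-sample designs.

In biomedical two-group comparisons it is rarely credible that two
treatments have *exactly* the same effect; what matters is whether the
standardized effect size `δ = (μ1 − μ2)/σ` is *negligibly small*.
Equivalence tests therefore replace the point null `H0: δ = 0` with an
interval null `H0: δ ∈ (−c, c)` — a region of practical equivalence
(ROPE).  Several Bayesian tests of such interval hypotheses coexist, and
they differ sharply in type I error, power, and how the width of the
Cauchy prior `C(0, γ)` on `δ` pushes those rates around.  This package
implements the main contenders side by side, measures their operating
characteristics by Monte Carlo, and turns those measurements into an
*objective* choice of the equivalence region: given a tolerable type I
error rate, a required power, an attainable sample size and an elicited
prior, it recommends the narrowest admissible (test, region) pair.

Everything is driven by the pooled two-sample t-statistic: given `t`,
its degrees of freedom `ν = n1 + n2 − 2` and the effective sample size
`n_δ = n1·n2/(n1 + n2)`, the marginal likelihood of the data under an
effect-size prior `π(δ)` is

    m(π) = ∫ T_ν(t | √n_δ · δ) · π(δ) dδ,

with `T_ν(· | a)` the noncentral-t density.  The implemented tests are

- **JZS Bayes factor** — point null `δ = 0` vs `δ ~ C(0, γ)`
  (`BF01 = T_ν(t) / m(π)`), the default Bayesian t-test, included for
  comparison;
- **OH (overlapping hypotheses)** — null `δ ~ C(0, r0)` vs alternative
  `δ ~ C(0, r1)`, `r0 = r1/10` by default; obtained by transitivity from
  two JZS Bayes factors;
- **NOH (non-overlapping hypotheses)** — the interval Bayes factor: the
  Cauchy prior is split at the equivalence region, and `BF01` is the
  ratio of the truncated-prior marginals inside vs outside the region
  (identical to the informed interval Bayes factor);
- **hybrid** — a mixture null putting weight `π0` on the exact point
  `δ = 0` and `1 − π0` on the interval null;
- **ROPE tests** — the posterior `p(δ | t) ∝ T_ν(t | √n_δ δ) π(δ)` is
  built on a dense grid, and equivalence is accepted/rejected from the
  location of the 95% HPD interval, the (essentially) full posterior
  interval, or the `BF = k` support interval relative to the region.

Decisions are three-way: `accept_H0` (equivalence), `reject_H0`
(non-equivalence), `inconclusive` (BF between 1/3 and 3, or an interval
straddling the region boundary).

## Worked example

Two patient groups (n = 177 and 257) with exhaled-volume means 3.28 and
3.41 (SDs 0.87, 0.96).  The interval Bayes factor for the default region
`(−0.1, 0.1)` under a wide `C(0, 1)` prior:

```sh
$ bayesequiv bf --model noh --prior-scale 1.0 --region -0.1 0.1 \
    --n1 177 --mean1 3.28 --sd1 0.87 --n2 257 --mean2 3.41 --sd2 0.96
{"model": "noh", "bf01": 7.599850695135726, "log_bf01": 2.0281286017224343,
 "numerical_error": 3.116185858661544e-09, "t": -1.439778383462857,
 "df": 432.0, "effective_n": 104.81336405529954,
 "prior": {"location": 0.0, "scale": 1.0}}
```

`BF01 ≈ 7.6`: the data favour the interval null by a factor of about
seven — moderate evidence for equivalence (`BF01 ≥ 3` accepts).  The 95%
HPD ROPE test on the same data is more cautious:

```sh
$ bayesequiv decide --method rope_hpd95 --region -0.1 0.1 --prior-scale 1.0 \
    --n1 177 --mean1 3.28 --sd1 0.87 --n2 257 --mean2 3.41 --sd2 0.96
{"outcome": "inconclusive", "method": "rope_hpd95", "region": [-0.1, 0.1],
 "evidence": {"interval": [-0.32821837330246273, 0.05180406258784063],
 "kind": "hpd95", "mass": 0.95}}
```

The 95% HPD interval `[−0.33, 0.05]` sticks out of the region, so the
ROPE test stays inconclusive — an instance of the two test families
disagreeing on the same data, which is exactly why their error rates
need to be measured before one is chosen.

The same machinery is available as a library:

```python
from bayesequiv import (CauchyPrior, EquivalenceRegion, TwoSampleSummary,
                        noh_bf01, pooled_t)

tt = pooled_t(TwoSampleSummary(177, 257, 3.28, 3.41, 0.87, 0.96))
res = noh_bf01(tt.t, tt.df, tt.effective_n, CauchyPrior(0, 1.0),
               EquivalenceRegion(-0.1, 0.1))
print(res.bf01)   # 7.599850695135726
```

## Choosing the equivalence region from error rates

`bayesequiv simulate` runs a factorial Monte-Carlo design (settings with
no/small/medium/large true effect × sample sizes × prior widths ×
regions × methods) and writes one CSV row of type I / type II / power /
inconclusive rates per cell; `bayesequiv select` then ranks (method,
region) pairs against your criteria:

```sh
bayesequiv simulate --design design.yaml --out results.csv
bayesequiv select --results results.csv \
    --alpha-max 0.05 --power-min 0.8 --n 170 --prior-scale 1.0
```

The recommendation is the *narrowest* region whose method meets both
criteria (ties broken by lower type I error, then higher power); the
prior is an input, never a tuning knob — a selection call refuses to
rank across prior scales.  A total-error variant (`--total-max`) bounds
type I plus non-detection instead.

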