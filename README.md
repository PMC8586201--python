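# empacea

A Markov cohort cost-effectiveness model of adding empagliflozin (an SGLT2
inhibitor, 10 mg once daily) to standard guideline-directed therapy in
patients with heart failure and reduced ejection fraction (HFrEF), from a
healthcare-system perspective with Taiwan inputs. It is written for health
economists and methodologists who want a scriptable, fully tested
re-implementation of this class of decision-analytic model: base-case ICERs,
one-way (tornado) and scenario sensitivity analyses, probabilistic
sensitivity analysis (PSA) with cost-effectiveness acceptability curves
(CEAC), a threshold drug-price solver, and a synthetic trial generator for
end-to-end testing.

## The model

A cohort starts at age 67 in stable HFrEF and is simulated in 1-month cycles
over 15 years (180 cycles). Each cycle, the alive fraction may be
hospitalized for heart failure (HHF, a transient one-month event after which
survivors return to stable HF), die of a cardiovascular (CV) cause, or die
of a non-CV cause, with constant monthly probabilities `p` derived from
16-month trial event proportions via the constant-hazard conversion

    p_month = 1 − (1 − p_followup)^(1/16).

Per cycle, discounted at an annual rate r = 3% (factor `(1+r)^(−(t−1)/12)`):

- cost = occupancy × (drug + chronic-care cost) + HHF events × 2,887
  + CV deaths × 3,430 + non-CV deaths × 3,390   (2020 US$)
- QALYs = [occupancy × u(age) + HHF events × (−0.321)] / 12, with
  u(age) = 0.770 − 0.0016 × (elapsed years)
- life-years = occupancy / 12

where *occupancy* is the credited alive person-months per cycle. By default
the package uses boundary counting (state membership credited at both cycle
boundaries, i.e. two month-equivalents per cycle, with the age decrement
running on that credited time), which is the accounting the published
Taiwan analysis used; textbook single counting is available via
`ModelSettings(occupancy_counting="single")`. See `docs/methods.md`.

The incremental cost-effectiveness ratio is ICER = ΔCost/ΔQALY
(or ΔCost/ΔLY), classified against willingness-to-pay (WTP) thresholds of
1× and 3× GDP per capita (US$25,000 / US$75,000 for Taiwan). Net monetary
benefit is NMB = ΔQALY × WTP − ΔCost.

## Worked example

```python
from empacea import MarkovCEA, taiwan_base, taiwan_distributions, taiwan_settings

model = MarkovCEA(taiwan_base(), settings=taiwan_settings(),
                  distributions=taiwan_distributions())
results = model.fit()
print(results.summary())
```

prints

```
Markov cohort CEA: empagliflozin vs standard (Taiwan)
  horizon: 180 monthly cycles, discount 3.0%/yr

                           empagliflozin        standard     increment
              cost (US$)          79,771          72,594         7,177
                   QALYs            9.76            9.40          0.36
              life-years           12.97           12.50          0.47

  ICER: 20,088 US$/QALY, 15,241 US$/LY
  classification at WTP 25,000/75,000: very cost-effective
  end-of-horizon mortality: empagliflozin 79.3%, standard 81.4%
```

Add-on empagliflozin costs US$7,177 more per patient over 15 years and
yields 0.36 extra QALYs, i.e. US$20,088 per QALY gained — below the 1× GDP
threshold, so the add-on is classified as very cost-effective in the Taiwan
setting. Continuing,

```python
psa = model.psa(n=1000, seed=0)
psa.prob_cost_effective(25000)   # 0.626
psa.prob_cost_effective(75000)   # 0.911
model.threshold_price(20000)     # 34.80 US$/month
```

the PSA puts the probability of positive net benefit at 62.6% (WTP 25,000)
and 91.1% (WTP 75,000), and the drug price at which the ICER exactly equals
US$20,000/QALY is US$34.80/month.

The same analyses are available from a shell:

```sh
empacea base                       # base case + per-cycle traces
empacea tornado --range 0.10       # one-way sensitivity, sorted bars
empacea scenario                   # bundled scenario suite (equal risks, …)
empacea psa --psa-n 1000 --seed 0  # PSA draws + CEAC
empacea threshold --wtp 20000
empacea simulate --n-per-arm 50000 --seed 1
```

Each run writes CSVs plus a `manifest.json` with the config hash, seed and
package version. Other country settings are YAML configs with the same
schema as the bundled `taiwan_base.yaml` (see `empacea.save_setting`), run
in bulk with `empacea batch --configs a.yaml --configs b.yaml`.

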