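# ovutherm

Detecting ovulatory menstrual cycles from temperature measured during
sleep. The package is aimed at researchers evaluating wearable
temperature sensing for reproductive-health monitoring: it estimates core
body temperature (CBT) from a chest skin sensor, reduces each night to
one representative temperature, detects the post-ovulatory biphasic
temperature shift with the classical *three-over-six* rule, and scores
the resulting calls against a urine-LH reference with standard
diagnostic-accuracy statistics. A synthetic-data module simulates both
minute-level nights and full study-shaped cohorts, so the entire pipeline
is runnable and testable without any recorded data.

## The model and the rule

**Heat-flux CBT estimation.** With skin temperature `Ts`, ambient
temperature `Ta`, and a dimensionless conductivity ratio `K = λ2/λ1`
(sensor over body), steady-state conduction gives

```
CBT = Ts + K (Ts − Ta)
```

`K` is calibrated from data: the model implies `Ts = (K·Ta + CBT)/(1+K)`,
so the OLS slope `α` of skin on ambient temperature yields
`K = α/(1−α)`. Per night, the first hour after sensor application is
discarded, the next 4 hours form the analysis window, minutes with
`Ta > Ts` or step-change artifacts are excluded, and the mean estimated
CBT over the remaining minutes is the night's representative temperature.

**Three-over-six rule.** A temperature shift occurs when 3 consecutive
daily measurements are each ≥ 0.2 °C above the maximum of the previous 6
days (≥ 4 of the 6 recorded suffice). Two mutually exclusive exceptions
apply: if the third value clears the maximum by less than 0.2 °C, a
fourth measurement exceeding the maximum confirms; if exactly one of the
three drops to or below the *mean* of the reference days, it is
disregarded and replaced by the next measurement, which must be ≥ 0.2 °C
above that mean. Only shifts with onset in the cycle's last 14 days make
the cycle biphasic; a cycle without one is monophasic (anovulatory by the
temperature method).

**Scoring.** Cycles with a positive LH test are ovulatory; with only
negative tests, anovulatory. Against that reference the package computes
sensitivity, specificity, predictive values and F1, compares two methods
with McNemar's paired test, compares biphasic proportions with a χ² test,
and estimates the repeated-measures correlation `r_rm` (ANCOVA with
subject intercepts and a common slope) for paired continuous
measurements.

## Worked example

`python examples/03_synthetic_study.py` simulates 26 subjects / 74 cycles
(60 ovulatory) with an estimated-CBT channel and a noisier oral-BBT
channel, runs the full pipeline, and prints:

```
74 simulated cycles, 73 pass the inclusion filters

estimated_cbt  tp=21 fp=0 tn=14 fn=38  sens=35.59% spec=100.0% F1=0.53
oral_bbt       tp=16 fp=0 tn=14 fn=43  sens=27.12% spec=100.0% F1=0.43

McNemar (estimated CBT vs oral BBT): b=9, c=4, p=0.267 [exact_binomial]
```

Each row is a 2×2 table of biphasic calls against LH labels; the less
noisy estimated-CBT channel detects more of the true ovulatory cycles,
and `b`/`c` count the cycles that only one of the two channels got right.
(Simulated sensitivities are deliberately conservative — see
`docs/methods.md`.) The other examples walk through a single night
(`01`), the shift rule on hand-sized series (`02`), and `r_rm` recovery
(`04`).

The same pipeline is available as a CLI:

```
ovutherm simulate --n-subjects 26 --n-cycles 74 --seed 1 \
    --daily-out daily.csv --nights-out nights.csv --truth truth.csv
ovutherm detect daily.csv --nights nights.csv --out classes.csv
ovutherm evaluate classes.csv
```

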