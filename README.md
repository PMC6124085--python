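# groomnet

Modelling social-grooming strategies from contact-event data: the
number-versus-strength trade-off of social relationships, the daily
grooming budget it implies, and the social-network forms that emerge when
agents spend that budget through preferential (rich-get-richer)
reinforcement.

## The problem

Every social bond needs maintenance — fur cleaning in baboons,
conversation, calls, messages or likes in humans — and time is finite.  An
ego investing total cost `C` over `N` relationships of mean tie strength
`m` (tie strength = number of distinct days the ego groomed that partner)
obeys the trade-off

    C = N · m^a ,

and the exponent `a` characterises the *grooming method*: `a < 1` marks
elaborate methods (face-to-face, phone among kin, primate grooming —
few, deep ties), `a > 1` marks lightweight methods (SNS, e-mail among
unrelated people — many, shallow ties).  With cost proxied by
participation days (`C = u^b`), `a` and `b` are estimated by the
no-intercept regression `log N ~ Normal(−a·log m + b·log u, σ)`.

Two further ingredients connect behaviour to network form: grooming per
act grows linearly with tie density, `v(w) = αw + 1`, and the daily budget
left for reinforcing existing ties is

    G(a, α; C, m) = α·C·(m^(1−a) − m^(−a)) / T ,

which increases without bound in `m` for `a ≤ 1` but peaks at
`m* = a/(a−1)` for `a > 1`.  A resource-constrained Yule–Simon
individual-based simulator spends this budget day by day, and the package
measures the resulting tie-strength distributions (power-law exponent
`φ`, hierarchy sizes `H_k` and their ratios) and their dependence on `a`,
including AIC selection between a plain line and a threshold model for
`φ(a)`.

The package is aimed at behavioural ecologists and computational social
scientists working with directed contact logs (actor, partner, day).  No
proprietary dataset ships with it; a seeded synthetic-data module
generates populations with the same statistical signature plus exact
ground truth, so every estimator is tested as an inverse problem.

## Worked example

Generate a lightweight-method population (true `a = 1.3`, `b = 1.25`,
log-noise 0.15), aggregate its event log, and fit the trade-off:

```
$ groomnet synth --seed 7 --m-egos 150 --days 200 --a 1.3 --b 1.25 --sigma 0.15 --out demo/synth
wrote 23031 events for 150 egos to demo/synth
$ groomnet summarize --events demo/synth/events.tsv --days 200 --out demo/summ
aggregated 23031 events into 150 ego summaries
$ groomnet fit-tradeoff --egos demo/summ/egos.csv --name demo --out demo/fit
a = 1.27452 (se 0.02352) -> lightweight; b = 1.24250; adj R2 = 0.998
```

The fitted exponent 1.27 sits within two standard errors of the
generating value 1.3 and above 1, so the method is labelled lightweight;
`b` ≈ 1.24 recovers the cost-participation exponent.  Simulate an
elaborate-method population (`a = 0.7`) and summarise its network form:

```
$ groomnet simulate --seed 3 --days 100 --m-egos 30 --a 0.7 --alpha 2.0 --out demo/sim
simulated 30 groomers over 100 days; mean N' = 23.63, mean m' = 32.603
$ groomnet analyze --edges demo/sim/edges.tsv --out demo/an
phi = 1.9299 over 709 ties; H_1 = 445
```

With a weak trade-off the 30 groomers end up with deep ties (mean
strength ≈ 33 days): the strength distribution has a heavy tail
(`φ` ≈ 1.93) and 445 of 709 ties exceed strength 1.

The full sweep over `(a, α)` with calibration, production runs and the
φ-threshold analysis is `groomnet experiment2` (see `--help` for the
grids); `groomnet fit-alpha` calibrates `α` for a single configuration,
and `groomnet budget` tabulates `G` over `m`.

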