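# ednasens

Sensitivity modelling and survey design for environmental-DNA (eDNA)
monitoring programs.

Managers screening water bodies for invasive fish (the motivating case is
bighead and silver carp surveillance in urban waterways) collect water
samples, filter and extract the DNA, and run PCR with sequencing
confirmation.  A negative survey can mean the species is absent — or that
the marker was present at a concentration the protocol simply cannot
detect.  `ednasens` quantifies that distinction: it models the
**sensitivity** of a monitoring event, `p[E | C_M]`, the probability of at
least one confirmed detection given the ambient marker concentration
`C_M` (copies/L), and turns it into design quantities such as the minimum
detectable concentration (MDC).

## The model

Five stages link ambient concentration to a confirmed detection:

1. **Capture** — a sample of volume `V_S` litres holds
   `N_S ~ Poisson(C_M · V_S)` marker copies (well-mixed water body).
2. **Extraction** — a fraction `φ ~ Triangular(0, 0.15, 0.3)` of captured
   copies reaches the purified elution (`V_E = 100 µl` by default):
   `N_E = φ · N_S`, elution concentration `C_E = N_E / V_E`.
3. **Subsampling** — each of `k` PCR replicates receives a `V_A = 1 µl`
   aliquot with expected copy number `µ = C_E · V_A` (realized count
   Poisson around it).
4. **PCR fluorescence** — detection curve `P_F(µ) = P(α_F, µ/β_F)`, a
   regularized lower incomplete gamma function calibrated from dilution
   experiments.
5. **Sequencing confirmation** — second gamma curve `P_S(µ)`.

A sample is positive if any replicate passes both assay stages,
`p[A|C_M] = 1 − E[(1 − P_F P_S)^k]`, and the event sensitivity is
`p[E|C_M] = 1 − (1 − p[A|C_M])^N` for `N` samples.  Both a semi-analytic
evaluation (Poisson summation + Gauss–Legendre quadrature over `φ`) and a
full hierarchical Monte Carlo simulator are provided, along with three
compositions of the assay stages (curves at expected vs realized aliquot
counts; see `docs/methods.md`).

Calibration is included: gamma detection curves are fitted to
dilution-trial tables by the method of moments (`α = x̄²/s²`,
`β = s²/x̄` over positive trials), statsmodels-style
(`GammaDetectionModel(...).fit().summary()`).

## Worked example

```python
>>> from ednasens import SurveyModel, BIGHEAD_CARP
>>> model = SurveyModel(assay=BIGHEAD_CARP)  # baseline: 10 x 2 L samples, k=8
>>> model.sensitivity(500.0)
0.7801032067178691
>>> model.simulate(500.0, n_draws=50_000, seed=1)
(0.78, 0.0018525657883055055)
>>> model.min_detectable_concentration(goal=0.95)
726.1467600571646
>>> model.with_protocol(sample_volume_l=3.0).min_detectable_concentration()
483.6360649739097
```

At 500 copies/L the baseline protocol detects the bighead marker in 78%
of monitoring events (the Monte Carlo estimate agrees with the
semi-analytic value within its standard error).  To reach 95% sensitivity
the concentration must be ≈726 copies/L; raising the sample volume from
2 L to 3 L lowers that threshold to ≈484 copies/L — volume is the most
effective single protocol change, with diminishing and subadditive
returns when strategies are combined.

The same analyses are available from the command line:

```sh
ednasens mdc --marker silver --goal 0.95
ednasens curve --marker bighead --grid 10,10000,25 --seed 1 --out curve.csv
ednasens compare --marker bighead --goal 0.95
ednasens generate-fixtures --out trials.csv && ednasens calibrate trials.csv
```

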