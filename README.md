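# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports, built around a worked case study: drug-induced
neuralgia (MedDRA preferred term "neuralgia", code 10029223).

Spontaneous-reporting databases such as the FDA Adverse Event Reporting
System (FAERS) have no exposure denominators, so drug safety signals are
screened by *disproportionality*: for each drug, the reports are arranged in
a 2×2 table

|                    | drug of interest | all other drugs |
|--------------------|------------------|-----------------|
| event of interest  | a                | b               |
| all other events   | c                | d               |

and the observed co-reporting frequency is compared with the frequency
expected under independence. `faersig` implements the four standard
algorithms on this table:

- **ROR** = ad/bc, with SE(lnROR) = √(1/a + 1/b + 1/c + 1/d) and a 95% Wald
  CI; positive when a ≥ 3, ROR ≥ 3 and the CI lower bound > 1.
- **PRR** = (a/(a+b)) / (c/(c+d)), SE(lnPRR) = √(1/a − 1/(a+b) + 1/c −
  1/(c+d)); positive when a ≥ 3, PRR ≥ 2 and the CI lower bound > 1.
- **BCPNN information component** IC = log₂(aN/((a+b)(a+c))) with
  Dirichlet-smoothed E(IC) and V(IC) (priors α=β=2, α₁=β₁=1, γ₁₁=1) and
  lower bound IC025 = E(IC) − 2√V(IC); positive when IC025 > 0.
- **EBGM**, here the observed/expected ratio aN/((a+b)(a+c)) (≡ 2^IC) with a
  Wald interval; positive when its lower bound EBGM05 > 2. (This is the
  ratio form, not the shrunken gamma-Poisson MGPS estimator — see
  `docs/methods.md`.)

A drug is called a **signal only when all four algorithms are positive at
once**. For signal drugs the package also summarises time-to-onset
(EVENT_DT − START_DT) by median, interquartile range and a two-parameter
Weibull fit whose shape parameter classifies the onset hazard as early
(<1), random (≈1) or late (>1).

Around the statistics sits a full pipeline for the FAERS quarterly ASCII
dialect ($-delimited DEMO/DRUG/REAC/OUTC/THER/INDI files): tolerant
parsing, deduplication by CASEID keeping the latest FDA_DT, validity
exclusions (missing drugs/reactions/demographics, event onset before every
therapy start), brand→generic drug-name mapping through a local dictionary,
descriptive strata and trend reports — plus a synthetic FAERS-like data
generator with exact ground truth, so every stage is testable without any
database download.

## Worked example

Simulate a reporting system with 50 null-rate background drugs and three
planted signal drugs (reporting-rate ratios 3, 5 and 10), then run the whole
pipeline:

```python
from faersig.synthetic import signal_study_config, generate_dataset
from faersig.pipeline import run_pipeline

config = signal_study_config(seed=1)          # 50,000 reports
generate_dataset(config, "studydata")
result = run_pipeline("studydata", "studydata/drug_dictionary.tsv")

print(result.cleaning_log.as_dict())
print(result.stats[result.stats.joint_positive][
    ["drug", "n", "ror", "prr", "ebgm05", "ic025"]])
for drug, tto in result.tto.items():
    print(drug, tto.n_used, tto.median_days, round(tto.weibull_shape, 2),
          tto.onset_pattern)
```

Output (seed 1):

```
{'total_input': 52467, 'retained': 47701, 'duplicates_superseded': 2467,
 'missing_drug': 495, 'missing_reaction': 527, 'missing_demo': 251,
 'implausible_dates': 1026, 'unparseable': 0, 'unparseable_lines': 0}
             drug    n        ror        prr    ebgm05     ic025
0      signalmild  470   3.648339   3.358195  2.473419  1.304973
1  signalmoderate  151   6.751615   6.549169  3.523202  1.802433
3    signalstrong  150  43.879917  42.380619  6.102546  2.743449
signalmild 348 8.0 0.8 early
signalmoderate 113 19.0 0.56 early
signalstrong 100 33.0 1.94 late
```

Reading this: the cleaning log reconciles exactly (52,467 loaded report
versions = 47,701 retained + the logged removals). All three planted drugs
— and no null-rate background drug — pass the joint four-algorithm rule,
with ROR point estimates ordered by their planted rate ratios (the ROR
estimates the odds ratio, slightly above the planted risk ratio). In the
time-to-onset block the rate-ratio-10 drug, planted with Weibull shape 2
(late-onset hazard), is classified `late`, and the shape-0.5 drug `early`;
the shape-1.0 drug (planted scale 10 days) fits at 0.8 because rounding
onsets up to whole days compresses a short-scale exponential — a
discretisation effect discussed in `docs/methods.md`.

The same pipeline is available from a shell:

```sh
faersig simulate --config config.yaml --out-dir data
faersig report --in-dir data --dictionary data/drug_dictionary.tsv --out-dir out
```

which writes `strata.tsv`, `yearly_trend.tsv`, `top_drugs.tsv`,
`signals.tsv`, `ranked_signals.tsv` and a run manifest with config hash,
input checksums and removal tallies.

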