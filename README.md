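# painnet

Analysis pipeline for biopsychosocial pain measures around total joint
replacement (TJR) in knee (KOA) and hip (HOA) osteoarthritis. It is written
for clinical-outcomes researchers who collect a battery of questionnaire
subscales and performance tests before and after arthroplasty and want to
ask two questions: *do pre-surgical characteristics predict post-surgical
pain?* and *how does the web of inter-relations between those
characteristics — the patient's "pain personality" — reorganize after
surgery?*

## What it computes

**Residual pain.** For each subject and pain scale (NRS, BPI severity,
KOOS/HOOS pain, SF-36 bodily pain, all on 0–10),

```
%residual pain = 100 · post / pre
```

so 100% = no change, 0% = complete relief, >100% = worsening; undefined at a
pain-free baseline. A composite pain score averages the four scales.

**Factor reduction.** PCA on the correlation matrix of 21 behavioural
measures (KMO adequacy; eigenvalue > 1 retention; Promax oblique rotation,
κ = 4; membership at |loading| ≥ 0.5), yielding five oblique components —
Affect, Pain Catastrophizing, Pain Quality, Health, Physical Performance —
with regression-method scoring weights so the small hip arm can be scored
with the knee-arm solution.

**Outcome models.** Stepwise multiple regression (α-enter 0.05, α-remove
0.10) of pain and residual pain on the five component scores plus
demographics, with studentized-deleted-residual outlier pruning (±3 SD, at
most 3 cases), and re-testing of knee-selected predictor sets on the hip
arm.

**Correlation networks.** Per arm and visit, the 21×21 Pearson matrix is
binarized at the top 25% of |r| (53 of 210 pairs). Reorganization is
quantified by the mean local clustering coefficient, Louvain modularity Q
averaged over 100 repetitions, and mean Δr — the mean absolute change in
correlation over all measure pairs between visits — with inference by
10,000-draw permutation resampling (within-subject visit swaps for change
statistics, group-label shuffles for between-arm contrasts).

**Synthetic cohorts.** A generator plants the five-factor structure, the
published pain means/SDs, group imbalance (84 knee / 22 hip), a surgery
effect that lowers pain and rewires the correlation structure (more
strongly in the hip arm), and MCAR missingness — so the whole pipeline is
testable without any patient data. See `docs/methods.md`.

## Worked example

```python
import painnet as pn

# a synthetic two-arm cohort at the default study conditions
cohort, truth = pn.generate_cohort(pn.SyntheticSpec(rng_seed=7))

# residual pain per subject and scale
traj = pn.pain_trajectories(cohort)
print(traj.table.groupby(["group", "scale"])["residual_m3"].mean().round(1))

# factor model on the knee arm at baseline
harm = pn.harmonize(cohort, measure_ids=cohort.registry.network_ids)
grp = cohort.group_of()
base = harm.matrix("baseline")
koa = base.loc[[s for s in base.index if grp[s] == "KOA"]]
model = pn.fit_factor_model(koa, community_labels=cohort.registry.communities)
print(model.retained_k, round(model.kmo_overall, 2))

# network reorganization, baseline -> 3 months, knee arm
m3 = harm.matrix("m3")
koa3 = m3.loc[[s for s in m3.index if grp[s] == "KOA"]]
res = pn.permute_within_subject(koa, koa3, pn.stat_mean_delta_r,
                                reps=2000, seed=1)
print(round(res.observed, 3), round(res.probability, 4))
```

Output (seed 7):

```
group  scale
HOA    BPI-PS        7.9
       KOOS-Pain    12.0
       NRS           9.3
       SF36-BP      33.2
       aggregate    15.3
KOA    BPI-PS       33.5
       KOOS-Pain    35.3
       NRS          25.4
       SF36-BP      57.3
       aggregate    36.6
5 0.75
0.123 0.006
```

Reading it: hip-arm subjects retain ~15% of their baseline composite pain at
3 months versus ~37% in the knee arm (pain relief after hip replacement is
larger); the eigenvalue rule retains exactly the 5 planted components at
adequate sampling (KMO 0.75); and the knee arm's inter-measure correlations
shift by 0.123 on average — small but detectably beyond what within-subject
visit swaps produce (p = 0.006).

A full run — preprocessing, factors, stepwise tables, six networks and all
comparisons — from one config:

```bash
painnet run-all --config config.yaml --seed 7 --out results/run1
```

where `config.yaml` contains an `analysis:` section (thresholds, repetition
counts) and either `cohort_csv: path.csv` or a `synthetic:` section.
Subcommands `simulate`, `preprocess`, `factors`, `network` run single stages.

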