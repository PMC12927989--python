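# myoentropy

Entropy of skeletal-muscle fiber histology, quantified from segmented
cross-section images and linked to physical performance.

Aging muscle becomes visibly disorganized: fiber sizes diverge, same-type
fibers cluster into groups, and the spatial arrangement of fibers loses its
regular mosaic. `myoentropy` quantifies this disorganization per fiber with
a **homeostatic dysregulation index of muscle (HDI_M)** and provides the
full analysis pipeline around it, for muscle physiologists and aging
researchers working with MHC-immunostained vastus lateralis sections (or
any labeled cell segmentation of a tissue mosaic).

## The index

From a labeled segmentation mask and aligned 3-channel myosin-heavy-chain
intensity image, each fiber *i* gets three features:

- **CSA** — cross-sectional area, pixel count × pixel_size² (µm²);
- **fiber-type heterogeneity** — the fraction of adjacent fibers whose type
  (I / IIA / IIX, by arg-max channel intensity) differs from fiber *i*
  (range 0–1; low values indicate fiber-type grouping);
- **node-specific average path length (APL)** — the mean hop-count
  shortest-path distance from fiber *i* to every reachable fiber in the
  sample's adjacency network (edges = shared segmented boundaries).

Features are z-scored within sex × fiber-type strata (up to six strata),
and each fiber's Mahalanobis distance from the zero centroid is taken with
the covariance matrix *S* fitted on the entire pooled fiber population:

    D_M(x) = sqrt( xᵀ S⁻¹ x ),      HDI_M = ln D_M

The participant-level HDI_M is the mean of the sample's fiber-level values.
Two validation layers accompany the index:

1. **Shannon-entropy agreement** — fibers are sorted by HDI_M into *k*
   near-equal groups (≈500 fibers each); within each group the plug-in
   entropy H = −Σ pᵢ ln pᵢ of each feature is computed on one global
   Freedman–Diaconis grid (width 2·IQR/n^⅓ on the pooled population).
   Group median HDI_M correlates strongly with group entropy.
2. **Outcome associations** — standardized-β OLS (SD of outcome per SD of
   participant HDI_M), univariate and with two covariate sets: Model 1 =
   age + sex + BMI (height instead of BMI for weight-standardized outcomes,
   i.e. leg power and VO₂ peak); Model 2 = age + sex + thigh muscle volume
   index + total abdominal adipose tissue index; plus a sex × HDI_M
   interaction test.

Because real biopsy cohorts are access-restricted, the package ships a
seeded synthetic generator: Voronoi tessellations of jittered lattice
points as fiber mosaics, clustered fiber types, log-normal areas, optional
3-channel renders, and a cohort whose outcomes are linear in a planted
per-participant disorganization parameter θ ∈ [0, 1] (θ drives both area
dispersion and type clustering).

## Worked example

```python
import myoentropy as me
from myoentropy import pipeline
from scipy import stats

cohort = me.generate_cohort(n_participants=100,
                            fibers_per_participant=(300, 300), seed=11)
fib = pipeline.compute_fiber_metrics(cohort.fibers)   # heterogeneity, APL
fib = me.stratified_zscore(fib)                       # 6 sex x type strata
model = me.fit_reference_model(fib)                   # pooled covariance
res = me.fiber_hdi(fib, model, on_zero_distance="drop")
print(f"mean fiber HDI_M {res['hdi'].mean():.3f} +- {res['hdi'].std():.3f}")

ph = me.participant_hdi(res["hdi"], fib["participant_id"])
merged = cohort.participants.merge(ph.reset_index(), on="participant_id")
rho = stats.spearmanr(merged.theta, merged.hdi).statistic
print(f"Spearman(theta, participant HDI_M) = {rho:.3f}")
```

prints

```
mean fiber HDI_M 0.322 +- 0.490
Spearman(theta, participant HDI_M) = 0.983
```

i.e. the average fiber sits at ln-distance ≈ 0.32 from the population norm,
and the planted disorganization parameter is recovered almost perfectly by
the participant-level index. Continuing with the entropy validation on the
same cohort (groups of ≈500 fibers):

```python
retained = fib.loc[res.index]
groups = me.stratify_by_hdi(
    res["hdi"].reset_index(drop=True), len(retained) // 500)
c = me.entropy_hdi_correlation(groups, "area", retained["z_area"].to_numpy())
print(f"r(median HDI_M, H_area) = {c.r:.3f}")   # -> 0.995
```

The full pipeline — simulate → extract → graph → HDI → entropy → associate,
with per-stage bookkeeping and CSV/JSON outputs — runs from one config:

```
myoentropy run --out run1 --seed 11
myoentropy simulate --out sim --seed 3 --n-participants 20
myoentropy extract --mask mask.tif --channels mhc.tif --pixel-size 0.65 --out fibers.csv
```

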