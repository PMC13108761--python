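# gmltwin

Generative-manifold digital twins for normative brain morphometry.

Radiologically isolated syndrome (RIS) is the presymptomatic face of
multiple sclerosis: incidental MRI lesions in people with no clinical
deficit, a minority of whom later convert to clinical MS. `gmltwin`
implements an unsupervised analysis stack for stratifying such subjects from
cross-sectional regional brain volumes (196 ROIs plus left/right asymmetry
indices, the output schema of a whole-brain T1 segmentation pipeline):

* **Digital twins.** A manifold embedding (UMAP by default) is learned on a
  healthy reference population. A subject's *digital twin* is the unweighted
  mean feature vector of their k = 30 nearest reference neighbors in
  embedding space — a personalized "what this brain would look like if
  healthy".
* **GeoNorm z-scores.** Each of the 30 neighbors is itself twinned by
  leave-one-out; the per-feature SD of the neighbors' actual-minus-twin
  residuals is the *local normal variability* σ. The subject's deviation per
  ROI is z = (x − twin)/σ, flagged when |z| > 1.96 (two-sided 5%).
* **Brain age gap (BAG).** Brain age = mean chronological age of the 30
  neighbors; BAG = brain age − chronological age. Positive BAG means an
  older-appearing brain.
* **Risk clustering.** RIS deviation profiles are reduced to 2-D and
  k-means-clustered (K = 4); clusters are numbered by ascending conversion
  rate, given percentile-bootstrap 95% CIs, compared pairwise by Fisher's
  exact test, and labeled red (≥ 25%), orange (10–25%) or low.
* **Pseudo-temporal trajectories.** Subjects are ordered by graph-geodesic
  distance from the healthy-control centroid (shortest path on a k-NN graph,
  min-max normalized). Penalized-spline GAMs model ROI z-scores along this
  axis, sampled at 10 points, with the first |z| ≥ 1.96 crossing located by
  bisection.

Because cohorts of this kind are not publicly downloadable, the package
ships a first-class synthetic cohort generator (`gmltwin.cohort`) that
plants the structure the analysis is meant to recover: a lifespan healthy
reference, three matched clinical groups of 152 (HC / RIS / MS) with a
monotone severity gradient, four latent RIS subgroups with conversion risks
10–39% and distinct ROI signatures, 77% female composition, and joint
biomarker availability for 94/152 RIS subjects. Every downstream claim is
tested as a parameter-recovery exercise against this generator.

## Worked example

```python
from gmltwin import (CohortConfig, generate_cohort, build_features,
                     DigitalTwinModel, RiskStratifier)

cfg = CohortConfig(seed=11, n_reference=400)
records, volumes = generate_cohort(cfg)
table = build_features(volumes, records)

ref = (records["cohort"] == "reference").to_numpy()
model = DigitalTwinModel(table.subset(ref), records.loc[ref, "age"].to_numpy(),
                         k=30, random_state=5).fit()
dev = model.score(table.subset(~ref), records.loc[~ref, "age"].to_numpy(),
                  groups=records.loc[~ref, "group"].to_numpy())
print(dev.summary().loc[["HC", "RIS-NC", "RIS-C", "MS"]].round(2))
```

```
          n  median_bag  mean_bag  mean_n_abnormal  median_n_abnormal
group
HC      152        0.21      0.46            11.82               12.0
RIS-NC  116        6.86      6.97            20.84               20.0
RIS-C    36       10.60     10.76            26.61               25.0
MS      152       11.98     12.78            41.79               37.0
```

Both the brain age gap and the abnormal-region burden rise monotonically
from healthy controls through RIS non-converters and converters to MS —
the planted disease gradient, recovered by the digital-twin deviations.

```python
is_ris = dev.profiles["group"].isin(["RIS-NC", "RIS-C"]).to_numpy()
ris = records.loc[~ref].loc[is_ris]
res = RiskStratifier(dev.z_roi.to_numpy()[is_ris],
                     ris["converted"].to_numpy(dtype=bool),
                     k_clusters=4, n_boot=2000, seed=3).fit()
print(res.summary().round(3))
```

```
          n  converters   rate  ci_low  ci_high  unstable risk_label
cluster
1        39           3  0.077   0.000    0.154     False        low
2        35           5  0.143   0.029    0.257     False     orange
3        41          10  0.244   0.122    0.390     False     orange
4        37          18  0.486   0.324    0.649     False        red
```

The four recovered clusters match the generator's latent subgroups and
their conversion rates bracket the planted 10–39% risk span (cluster 4 drew
an unusually converter-rich sample at this seed — the planted risk 0.39 is
inside its CI).

The same pipeline is scriptable end to end:

```bash
gmltwin run-all --seed 17 --out out/
gmltwin simulate --seed 17 --out cohort/          # or stage by stage
gmltwin features --cohort cohort/ --out feats/
```

`run-all` writes a manifest (config hash, per-stage seeds, file hashes);
two runs with the same config are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `gmltwin.atlas` / `gmltwin.cohort` | 196-ROI synthetic atlas and seeded cohort generator + CSV round trip |
| `gmltwin.features` | ICV normalization, asymmetry indices, frozen reference scaling |
| `gmltwin.manifold` | `DigitalTwinModel` / `DigitalTwinResults`: embedding, neighbors, twins, GeoNorm z, BAG |
| `gmltwin.devstats` | abnormality maps, Kruskal–Wallis / Mann–Whitney, top-10 ROI ranking, column similarity |
| `gmltwin.risk` | `RiskStratifier`: 2-D reduction, k-means, bootstrap CIs, Fisher tests, enrichment, multinomial regression |
| `gmltwin.trajectory` | geodesic pseudotime, GAM trajectories, threshold crossings |
| `gmltwin.pipeline` / `gmltwin.cli` | end-to-end orchestration, manifest, `gmltwin` CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
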