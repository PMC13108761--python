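# Methods

This note documents the models implemented in `gmltwin`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not demonstrate.

## Normative model

**Feature space.** Each subject contributes 196 regional volumes divided by
intracranial cavity volume (ratio normalization, matching the head-size
output of volumetric segmentation pipelines) plus one asymmetry index
AI = 2(L − R)/(L + R) per left/right pair. AI is bounded in [−2, 2] for
positive volumes and antisymmetric under hemisphere swap. All features are
standardized with mean/SD estimated on the healthy reference only and
frozen before any clinical subject is transformed; this prevents leakage of
clinical-group structure into the normative scale. Standardizing before the
manifold step is a design choice: UMAP's Euclidean metric is otherwise
dominated by the large structures.

**Embedding.** The reference population is embedded with UMAP
(n_components = 10, n_neighbors = 15, min_dist = 0.1, fixed random_state;
all configurable). PCA is available as a deterministic linear alternative
(`method="pca"`), and is what several unit tests use because its transform
is closed-form. Out-of-sample subjects go through the embedder's transform;
a query row that exactly equals a reference row returns the stored training
coordinate, since UMAP's out-of-sample optimizer does not reproduce
training points exactly.

**Digital twin.** For a subject s, the k = 30 nearest reference subjects in
embedding space (Euclidean; ties broken toward the lowest reference index;
a reference subject is excluded from its own neighborhood) define the twin:
the unweighted mean of the neighbors' feature vectors. A distance-weighted
mean is available as an option but is not the default — the unweighted mean
is the simplest estimator consistent with the k-neighbor construction and
keeps the hand-computable oracle (mean of {1, 3, 5} = 3) exact.

**Local variability and GeoNorm z.** Each of the 30 neighbors j is twinned
by leave-one-out: j's own 30 nearest reference neighbors excluding j, full
recomputation rather than reusing the patient's remaining 29. The
per-feature SD of the 30 residuals (actual − twin) is the local sigma,
floored at 10⁻⁶ standardized units to keep z finite in degenerate
neighborhoods. z = (x − twin)/σ per feature; |z| > 1.96 flags a deviation
at the two-sided 5% level. z is computed in standardized units; because the
same affine scaling applies to x, twin and σ, the ratio is identical in
original units. Asymmetry-index features participate in the manifold but
are not counted in `n_abnormal`, which is defined over the 196 anatomical
ROIs.

Because σ is a 30-sample estimate and out-of-sample embedding adds a little
neighbor mismatch, the realized null flag rate is slightly above the
nominal 5% — measured at ≈ 5.7–6.2% on held-out null controls, inside the
[3%, 8%] band the calibration check uses.

**Brain age.** Brain age = mean chronological age of the 30 neighbors;
BAG = brain age − age. Averaging neighbor ages shrinks predictions toward
the cohort center, so reference subjects at the age extremes show a
center-ward BAG bias (positive for the youngest, negative for the oldest).
This is a structural property of k-NN age prediction; the tests assert its
sign instead of pretending it is absent.

## Group statistics

Abnormality maps report, per ROI and group, the percentage of subjects with
|z| > 1.96 (two-sided, consistent with the deviation definition). Group
BAG differences use Kruskal–Wallis with tie correction (all-identical input
returns H = 0, p = 1 as an explicit degenerate contract). Pairwise ROI
screens use the two-sided Mann–Whitney test — exact for small untied
samples, normal approximation with tie correction otherwise — ranked by
ascending p with ties broken by |rank-biserial| effect size, then column
order; the top 10 ROIs (~5% of 196) are retained, with direction =
sign of median(z_b) − median(z_a) (increase vs atrophy). "Column
similarity" between comparisons is the Jaccard overlap of top-10 sets. No
multiple-testing correction is applied to the per-ROI screen; it is
descriptive ranking, not inference, and the reports say so.

## Risk clustering

RIS z-profiles are reduced to 2-D with UMAP (any neighbor-graph reducer
balancing local and global structure would serve — the downstream contract
is reducer-agnostic) and clustered with k-means, K = 4
by default, best of 10 initializations. Clustering the full z-profile
instead of the 2-D coordinates is a config option. Clusters are renumbered
by ascending conversion rate so the report is invariant to k-means label
permutation. Conversion rates get percentile-bootstrap 95% CIs (n_boot =
2000; clusters under 5 subjects are flagged unstable). Pairwise converter
counts are compared with Fisher's exact test, two-sided by the
sum-of-probabilities-≤-observed convention (the common definition; the
doubling alternative exists and would give different values). Risk labels:
red if rate ≥ 0.25 (boundary inclusive), orange in [0.10, 0.25), low below.

Biomarker enrichment across clusters uses an exact conditional K×2 test
(Freeman–Halton: full enumeration of tables with the observed margins) with
a chi-square fallback, flagged, when the enumeration budget is exceeded;
missing biomarkers are excluded per subject with denominators reported.
Cluster membership is additionally modeled with multinomial logistic
regression (reference = cluster 1) on age, sex, BAG, lesion load and
spinal-cord lesion; complete cases only, with non-convergence or huge
coefficients flagged as possible separation and an L1-penalized refit
offered.

## Pseudo-temporal trajectories

Pseudotime is the graph-geodesic distance from the healthy-control centroid:
a symmetric k-NN graph (k starts at 10 and grows until connected; the value
used is reported) over all embedded subjects plus the centroid node, edge
weights Euclidean, shortest paths by Dijkstra, min-max normalized to [0, 1].
The graph is built explicitly from the pairwise distance matrix so that
coincident points keep their zero-length edges (floored at 10⁻¹²). Geodesic
distance is the standard graph surrogate for manifold geodesics; pseudotime
is invariant under rigid motions of the embedding.

ROI z-trajectories are penalized B-spline GAMs (df = 10, cubic; basis
shrunk with a logged warning when subjects are scarce) with the roughness
penalty chosen by GCV via a deterministic Nelder–Mead search. A noiseless
response makes the IRLS declare perfect separation; the fit then falls back
to unpenalized least squares on the same basis, which interpolates it. Each
trajectory is sampled at 10 equally spaced pseudotimes and the first
crossing of |z| ≥ 1.96 (the same threshold as the deviation analysis) is
located by grid scan plus bisection; a trajectory that never reaches the
threshold is reported censored.

Cluster onset comparison fits one trajectory per cluster, optionally
anchored by a shared backbone (the HC and MS subjects): RIS members alone
occupy the middle of the progression axis and rarely reach the threshold,
while the anchored curve spans HC-like to MS-like profiles and the
cluster's members bend its mid-course. Bootstrap CIs resample cluster
members (reusing the point estimate's penalty — re-running the GCV search
per resample adds cost but essentially no variance information). Calendar
time is *not* identified by a cross-sectional ordering; the package reports
normalized pseudotime and accepts an optional user-supplied
months-per-unit calibration rather than inventing one.

## Synthetic cohort generator

The generator is the package's study design, not a test fixture. Volumes
follow a multiplicative structural model on a fixed 196-ROI atlas
(paired/midline names, plausible baseline volumes): baseline × head-size
scale × age factor × sex factor × disease factor × log-normal noise
(noise_sd = 0.03, ~3% volumetric error, the order of scan-rescan
variability of automated segmentation). Age effects are log-linear —
parenchyma declines 0.1–0.4%/year, CSF spaces grow 0.8–1.8%/year — the
simplest monotone lifespan model. Disease scales per-ROI log-effects
(atrophy 3–9% per unit severity on about half the parenchymal ROIs,
ventricular enlargement 10–20%, the 3rd ventricle strongest at 25%) by a
group severity: HC = 0 < RIS-NC = 0.35 < RIS-C = 0.55 < MS = 1. Severity is
further dispersed per subject (log-normal, CV 0.30): individuals sit at
different points of the disease continuum, which is precisely what the
pseudo-temporal axis orders — without it there is no within-group
progression to model.

Each of the four latent RIS subgroups atrophies a private set of 20
parenchymal ROIs (6% effect; the size is the separability knob — tests can
choose a harder regime) and multiplies the shared severity by its own scale
(0.80 / 0.93 / 1.07 / 1.20), planting an onset ordering. Subgroup
conversion risks are 0.10 / 0.15 / 0.25 / 0.39; conversion is drawn per
subject and *then* defines the RIS-C / RIS-NC label, so converters are both
more numerous in high-risk subgroups and slightly younger (mean shift
−6 years). Biomarker panels are present jointly for a Bernoulli(94/152)
subset of RIS subjects; the spinal-cord-lesion rate varies by subgroup
(planted enrichment), the others are homogeneous.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates that the implementation recovers structure it is
told to plant, under log-normal noise, exact group sizes and geometrically
clean subgroups. Real morphometric data add scanner/site effects,
non-monotone lifespan trajectories, heavier-tailed segmentation failures,
label noise in conversion outcomes and censored follow-up — none of which
the generator emulates. Recovery here is a necessary software check, not
evidence about clinical performance.

## Numerical and reproducibility choices

* All randomness flows from explicit seeds; pipeline stages derive seeds
  from the master seed via `SeedSequence`. Two runs with one config produce
  byte-identical outputs, verified by manifest hash.
* Neighbor ties break toward the lowest reference index (stable argsort);
  top-ROI ties break by effect size then column order — rankings are
  deterministic.
* sigma floor 10⁻⁶; feature-scale floor 10⁻¹²; k-NN-graph edge floor 10⁻¹².
* At the default scales (1000-subject reference, 3 × 152 clinical, 196
  ROIs) the full pipeline runs in a few minutes on one CPU; the calibration
  check uses a 500 + 100 null cohort.

## Known limitations

* The digital twin absorbs deviation components parallel to the aging
  manifold into brain age (that is what BAG measures), so per-ROI z
  understates disease effects on strongly age-varying structures —
  visible in the generator as small inferior-lateral-ventricle z despite a
  planted enlargement.
* Adjacent planted onset scales (15% apart) are not distinguishable in
  per-cluster crossing times at n ≈ 38 per cluster; only the extreme
  clusters order reliably. The onset-recovery check is framed accordingly.
* K = 4 is a fixed default, not a data-driven choice; silhouette-based
  selection is available as a diagnostic, not a default.
* Exact K×2 enumeration is feasible for the cohort sizes here; larger
  tables fall back to chi-square with an explicit flag.
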