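# trajphen

Dynamic behavioral phenotypes from longitudinal adherence trajectories.

`trajphen` is a hybrid two-stage analysis pipeline for mHealth intervention
studies in which adherence to several daily behavior goals ("missions") is
rated repeatedly on a 5-point Likert scale — the setting of a pediatric
obesity intervention with five goals (screen time, fruit/vegetable intake,
exercise, water instead of sugary drinks, sleep) rated biweekly over weeks
1–25, and a continuous outcome ΔBMI z-score (post − pre).

**Stage 1 — functional phenotypes.** Each participant's discrete series
y_i(t_j) is smoothed with a penalized cubic B-spline, minimizing
Σ_j (y_ij − f_i(t_j))² + λ ∫ f_i″(t)² dt, with λ chosen by GCV and shared per
mission. Functional PCA of the smooth curves — the eigendecomposition of the
sample covariance operator K(s,t) = (n−1)⁻¹ Σ_i c_i(s)c_i(t) under a
trapezoidal inner product — yields orthonormal eigenfunctions φ_k,
eigenvalues λ_k, and per-participant scores ⟨c_i, φ_k⟩. Components are kept
up to 70% cumulative variance (capped at two) and oriented so PC1 means
*high vs low adherence level* and PC2 *late vs early behavior change*.

**Stage 2 — outcome model.** The 5 × 2 PC scores plus 22 baseline covariates
form a standardized design for an elastic net,

  (2n)⁻¹‖y − β₀ − Xβ‖² + λ[α‖β‖₁ + ((1−α)/2)‖β‖²],  α = 0.01,

with λ tuned by 10-fold CV over a 100-point log path. Stability is assessed
by repeating the CV+fit cycle (default 1000×) to get per-predictor
nonzero-survival fractions, and by participant bootstrap (default 500×) for
median coefficients and 95% percentile intervals; predictors surviving in
more than 10% of repetitions are flagged as selected. Finally, k-means (k=4)
on a mission's (PC1, PC2) plane partitions participants into the 2×2
high/low-level × late/early-change phenotype quadrants.

Because no participant-level data are distributed with the study design this
emulates, the package ships a seeded synthetic-cohort generator
(`trajphen.synthetic`) whose ground truth — latent level/timing scores, true
eigenfunctions, true outcome coefficients — makes every stage testable.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
120-participant demonstration cohort (master seed 7) and write their tables
under `results/pipeline/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_smooth_curves.py
python analysis/04_fpca_phenotypes.py
python analysis/05_outcome_stability.py
python analysis/06_cluster_phenotypes.py
```

Key lines of output, and what they mean:

```
M1: PC1 60% / PC2 23% of variance; alignment with generating modes: level 0.995, timing 0.943
```

FPCA on mission 1 attributes 60% of curve-to-curve variation to the overall
adherence level and 23% to the timing of change; the estimated
eigenfunctions align with the generator's true modes at cosines 0.995/0.943
(the 5-point quantization of the ratings caps the timing mode below the
noiseless ideal).

```
true-effect rows (generator planted M1_pc1 -, M2_pc2 +, M3_pc1 +, M5_pc2 -):
           beta_std_median  beta_std_lo  beta_std_hi  survival_fraction  selected
M1_pc1             -0.2627      -0.4337      -0.1336                1.0      True
M3_pc1              0.1995       0.0789       0.3115                1.0      True
```

The stability-selection table recovers the planted effects with the right
signs and bootstrap intervals excluding zero, while planted-null covariates
center near zero.

```
k-means on M5 scores, k=4 (WCSS 65.1):
          pc1   pc2   n
1        1.88 -0.30  21
...
```

Cluster centroids in PC-score units; cluster 1 is always the
highest-adherence corner because clusters are renumbered deterministically
by descending centroid PC1 then PC2.

The same stages are available as a CLI (`trajphen simulate | preprocess |
smooth | fpca | fit | cluster | run`) operating on the identical CSV/JSON
artifacts, e.g. `trajphen run --config run.yaml --out out/`.

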