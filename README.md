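# phasegraph

Multiscale phase-synchrony network analysis of regional brain signals, and
its association with regional PET covariates.

`phasegraph` implements a complete analysis pipeline for asking how regional
molecular measures — protein synthesis rate (rCPS, from L-[1-¹¹C]leucine
PET, nmol/g/min) and glucose uptake (SUV, from [¹⁸F]FDG PET) — relate to the
static and dynamic graph-theoretic structure of resting-state functional
connectivity. It is aimed at researchers who have (a) regional BOLD time
series (or a 4-D NIfTI plus an integer-label parcellation such as the
82-region Desikan-Killiany + subcortical atlas) and (b) one regional PET
value per region, and want node-level statistics out the other end. A
synthetic-data generator with planted ground truth makes the whole pipeline
runnable and testable without any imaging data.

## Method

1. **Multiscale instantaneous phase.** Each regional series is decomposed
   into dyadic frequency bands by two parallel maximal-overlap (undecimated)
   discrete wavelet transforms whose filter banks form an approximate
   Hilbert wavelet pair (HWP, common-factor design). The complex
   combination of the two banks' coefficients is an approximately analytic
   band-limited signal; its argument is the instantaneous phase Θ(t) within
   that band. With TR = 0.72 s and 1200 volumes this gives 11 scales, scale
   *j* labelled (fs/2ʲ, fs/2ʲ⁻¹) Hz. Phases are decimated by 4 through an
   anti-aliasing FIR applied on the unit circle.
2. **Phase-synchrony FC.** For every region pair the pairwise Kuramoto
   order parameter
   R_xy(t) = |(e^{iΘx(t)} + e^{iΘy(t)})/2| = |cos((Θx−Θy)/2)| ∈ [0, 1]
   gives dynamic FC; its temporal mean is static FC.
3. **Graph metrics.** Each FC matrix is thresholded at the weight that
   maximizes cost-efficiency (binary global efficiency minus wiring cost)
   and four weighted node metrics are computed on the surviving graph:
   node strength, clustering coefficient (Onnela), local efficiency and
   betweenness centrality (reciprocal-weight path lengths).
4. **Temporal stability.** Per-timepoint metrics from dynamic FC are
   summarized per node by the coefficient of variation CV = sd/mean.
5. **Association statistics.** Population-mean metric-by-scale matrices are
   fit by a repeated-measures GLM with regions as units, scale as the
   within factor and the PET values as continuous covariates: main-effect
   F(1, n−1−p), covariate × scale interaction with Mauchly's sphericity
   test and Greenhouse-Geisser correction, and per-scale post-hoc (partial)
   Pearson correlations with Bonferroni control.

## Worked example

```python
import numpy as np
import phasegraph as pg

# dyadic bands for HCP-style sampling (TR = 0.72 s)
for j in (1, 2, 5, 11):
    b = pg.scale_band_edges(j, tr_seconds=0.72, n_scales=11)
    print(f"scale {j:2d}: {b.f_lo:.4f} - {b.f_hi:.4f} Hz")

# synthetic cohort: 82 regions, 1200 volumes, 4 planted hub regions
coupling = pg.make_planted_hub_network(82, hub_ids=(0, 1, 2, 3), seed=0)
ts = pg.simulate_coupled_bold(pg.SimulationSpec(coupling_matrix=coupling, seed=1))
rcps, suv = pg.synth_pet_vectors(coupling.sum(axis=1), rho_hub=0.6,
                                 rho_between=0.63, seed=2)

# phase -> synchrony -> thresholded graph at the intrinsic 0.04-0.08 Hz scale
phases = pg.multiscale_phase(ts, n_scales=6)
sync = pg.dynamic_fc(phases, scale_index=5)
fc = pg.static_fc(sync)
thr = pg.cost_efficiency_threshold(fc)
strength = pg.node_strength(pg.apply_threshold(fc, thr))
print("top-6 strength regions:", list(np.argsort(strength)[-6:][::-1]))

# stability and PET association
dyn = pg.compute_dynamic_metrics(sync, thr, metrics=("node_strength",))
cv = pg.temporal_cv(dyn[:, :, 0], axis=0)
print(f"hub CV {np.nanmean(cv[:4]):.3f} vs non-hub median {np.nanmedian(cv[4:]):.3f}")
```

Output:

```
scale  1: 0.6944 - 1.3889 Hz
scale  2: 0.3472 - 0.6944 Hz
scale  5: 0.0434 - 0.0868 Hz
scale 11: 0.0000 - 0.0014 Hz
top-6 strength regions: [0, 3, 1, 2, 47, 63]
hub CV 0.164 vs non-hub median 0.305
```

The four planted hubs (regions 0–3) occupy the top strength ranks and are
roughly twice as temporally stable as the periphery. Fitting the
repeated-measures GLM of node strength on both tracers simultaneously
(`pg.rm_glm(table.metric_by_scale("node_strength"), [rcps, suv])`) on this
dataset prints `F(1,79) = 11.63, p = 1.02e-03` for the rCPS main effect —
the planted rCPS–hubness coupling is recovered with the degrees of freedom
a two-covariate, 82-region design implies.

The same analysis is available from the shell:

```bash
phasegraph simulate --n-regions 82 --n-subjects 4 --out synthetic/
phasegraph run --bold synthetic/bold_subject00.tsv --tr 0.72 \
    --pet-rcps synthetic/pet_rcps.tsv --pet-suv synthetic/pet_suv.tsv \
    --out results/
```

`run` writes per-scale static FC matrices, long-format node-metric and
stability tables, association and post-hoc tables (TSV) and a JSON manifest
recording versions, seed, configuration and region order.

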