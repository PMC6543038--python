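# scentstress

Analysis pipeline for longitudinal predator-scent stress experiments in rats:
who is vulnerable to developing PTSD-like behavior after a single traumatic
exposure, and can pre-trauma brain state predict it?

The package is written for behavioral/systems neuroscientists running the
predator-scent paradigm: animals are scanned with awake resting-state fMRI,
then exposed for 10 min to fox urine in an inescapable cage, blood-sampled for
corticosterone (CORT), and tested on the elevated plus maze (EPM) days later.
It implements the full quantitative chain from raw measurements to results
tables, together with a seeded synthetic-cohort generator that plants known
ground truth so every stage can be validated by recovery tests.

## What it computes

**Behavior** — per-frame speed from tracking coordinates; freezing as maximal
runs of sub-threshold speed (default < 1 cm/s for ≥ 2 s); exposure-phase
freezing totals and per-minute course; avoidance as distance from the scent
pad along the 45 cm cage, 12-zone occupancy/freezing distributions and
occupancy heat maps; the EPM anxiety score open/(open + closed).

**Phenotyping** — Gaussian-mixture evidence that freezing times across exposed
animals are bimodal: EM fits with k = 1..3 components, model selection by
AIC (p_k = 3k − 1 free parameters) with Akaike weights
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2); subgrouping by freezing tertiles
(62 animals → 21 low / 20 middle / 21 high) or a median split for small
cohorts.

**Endocrine** — the total CORT response Σ_{t∈{30,60,120}} (C_t − C_0) in
ng/ml, which integrates amplitude and duration of the
hypothalamic–pituitary–adrenal output, plus its Pearson correlations with
freezing and the EPM score.

**Connectome** — ROI-level rsfMRI preprocessing (drop the first 10 volumes;
scrub volumes with framewise displacement > 0.2 mm and their neighbors,
excluding runs losing > 20%; zero-phase 0.01–0.1 Hz band-pass; regression of
motion and white-matter/ventricle signals), per-subject Pearson/Fisher-z
connectivity over 67 regions, and the brain-wide screens: across-subject
correlation of each of the 2211 edges with freezing (BH-FDR at α = 0.05),
high-vs-low group differences (BH-FDR at α = 0.01), batch-adjusted contrasts
via a mixed model with a random intercept per batch, and seed connectivity
profiles.

**Statistics** — pooled-variance t tests, one-way ANOVA with Tukey–Kramer
post hocs, mixed-design repeated-measures ANOVA, Pearson correlation with the
t-transform p, and Benjamini–Hochberg FDR control, shared by all stages.

## Worked example

```python
import numpy as np
from scentstress import (SyntheticConfig, simulate_tracking, compute_speed,
                         detect_freezing, summarize_exposure, simulate_roi_runs,
                         preprocess_run, rsfc_matrix, edgewise_behavior_screen,
                         akaike_weights)

cfg = SyntheticConfig()  # 23 controls + 62 exposed, 67 regions, 2400 volumes

trace = simulate_tracking(cfg, "high", seed=1, target_freezing_pct=60.0)
mask, bouts = detect_freezing(compute_speed(trace), trace.rate)
summary = summarize_exposure(trace, mask)
print(f"freezing: {summary.freezing_pct:.1f}% in {len(bouts)} bouts, "
      f"mean distance to pad {summary.mean_dist_pad_cm:.1f} cm")

print("Akaike weights (k=1,2,3):", np.round(akaike_weights([11, 0, 6]), 4))

rng = np.random.default_rng(0)
freezing = np.clip(rng.normal(40, 20, cfg.n_exposed), 2, 95)
runs = simulate_roi_runs(cfg, freezing, seed=0)
z = [rsfc_matrix(preprocess_run(r)).z for r in runs]
screen = edgewise_behavior_screen(z, freezing, alpha=0.05)
hits = screen[screen.significant]
planted = {tuple(e) for e, _ in cfg.roi.coupled_edges}
found = {(i, j) for i, j in zip(hits.region_i, hits.region_j)}
print(f"screened {len(screen)} edges; {len(hits)} significant, "
      f"{len(found & planted)}/{len(planted)} planted edges recovered")
```

Output:

```
freezing: 61.7% in 68 bouts, mean distance to pad 30.5 cm
Akaike weights (k=1,2,3): [0.0039 0.9489 0.0472]
screened 2211 edges; 13 significant, 12/15 planted edges recovered
```

The first line shows the bout-level freezing detector recovering the planted
60% freezing phenotype and the avoidance of the pad end (cage midpoint is
22.5 cm). The Akaike weights quantify the evidence split across 1/2/3-component
mixtures for the given AIC differences — essentially all weight on the bimodal
model. The last line is the brain-wide screen on one synthetic cohort: 12 of
the 15 planted behavior-coupled circuits survive FDR, with one false positive.

## Command line

```bash
scentstress simulate --out data/ --seed 1          # synthetic dataset + manifest
scentstress report --data data/ --out results/     # every stage, all tables
scentstress all --out study/ --seed 1              # simulate + analyze
```

Stage subcommands (`behavior`, `phenotype`, `cort`, `connectome`) emit just
their tables. All outputs are CSV with a one-line provenance header
(package version, config hash, seed); rerunning with the same config and seed
reproduces them byte-for-byte.

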