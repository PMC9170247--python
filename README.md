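# notopattern

Tools for studying Notch-driven lateral-inhibition patterning in the
zebrafish notochord — a tissue whose coin-shaped precursor cells form a
true 1-D stack, so every cell signals to exactly two neighbors.

The package is aimed at quantitative/systems biologists who want to

* simulate juxtacrine gene-regulatory circuits (lateral induction, lateral
  inhibition, and a cis/trans mutual-inactivation model with an explicit
  receptor) on a 1-D cell lattice;
* determine *when* those circuits pattern, via linear stability analysis of
  the homogeneous steady state (HSS) — the Maximal Lyapunov Exponent (MLE)
  over spatial modes, and its phase diagram in the cis- and trans-
  interaction strengths `K_cis`, `K_trans`;
* quantify mosaic-overexpression fluorescence images with a reproducible
  threshold/morphology pipeline (three nested segmentations plus relative-
  intensity readouts);
* rank genes by organ specificity from labeled single-cell UMI counts with
  the score `Expr_N^2 / Expr_NN` (expression times enrichment);
* generate seeded synthetic data (lattice profiles, two-channel mosaics,
  negative-binomial count matrices) with ground truth, so every pipeline
  stage is testable offline.

The headline model result: in the mutual-inactivation circuit without
transcriptional cooperativity (h = 1), the homogeneous state only
destabilizes — i.e. an alternating pattern only forms — where
cis-interactions are stronger than trans (`K_cis > K_trans`); with
cooperativity (h = 3) patterning is possible without cis-interactions.
See `docs/methods.md` for the equations, defaults, and numerical choices.

## Worked example

```python
import numpy as np
from notopattern.config import default_config, model_params_from_config
from notopattern.stability import find_hss, jacobian_blocks, mode_mle, default_modes
from notopattern.simulate import perturb_hss, integrate, classify_pattern

cfg = default_config()
params = model_params_from_config("inhibition", cfg)

hss = find_hss("inhibition", params)
res = mode_mle(jacobian_blocks("inhibition", params, hss), default_modes(30), hss=hss)
print(np.round(hss.concentrations, 4), round(res.mle, 4), res.argmax_mode)
# [0.7399 0.7399 3.5377] 0.3377 -1.0

state0 = perturb_hss(hss, n_cells=30, epsilon=0.01, seed=0)
traj = integrate("inhibition", params, state0)
call = classify_pattern(traj.final_lattice(), steady=traj.steady)
print(call.label, call.adjacency, round(call.positive_fraction, 2))
# alternating 0.0 0.47
```

Reading the output: the lateral-inhibition circuit has a homogeneous steady
state at (L, S, R) ≈ (0.74, 0.74, 3.54), but its most unstable coupling
mode is m = −1 with escape rate MLE ≈ 0.34 > 0 — the homogeneous state is
unstable and the period-2 mode grows.  Integrating from a 1% perturbation
indeed ends in an alternating ligand pattern: no ligand-positive cell
touches another (adjacency statistic 0) and about half the cells are
positive.  Swapping in `"induction"` yields MLE < 0 and a homogeneous
high-ligand pattern instead.

The same analyses are available from the shell:

```bash
notopattern simulate --model inhibition --seed 0 --out runs/inhib
notopattern mle-map --out runs/map          # K_cis x K_trans MLE diagram
notopattern synth image --seed 1 --out runs/img
notopattern segment --image runs/img/image.tif --mask runs/img/organ_mask.tif --out runs/seg
notopattern synth counts --seed 1 --out runs/counts
notopattern score --counts runs/counts/counts.mtx --labels runs/counts/labels.csv --out runs/scores
```

Every run writes its resolved configuration and a provenance JSON next to
its outputs.

## The specificity score

For a gene g with mean CPM-normalized expression `Expr_N(g)` across
notochord cells and `Expr_NN(g)` across all other cells,

    score(g) = Expr_N(g)^2 / (Expr_NN(g) + 1)  =  Expression x Enrichment

A 15-gene reference ranking of notochord-enriched genes at 18 hpf ships
with the package (`scrna_score.load_reference_markers()`); scores are
displayed in the table's 10^-3 units.  Recomputing each row's score from
its printed expression and enrichment reproduces the printed column to
±0.05 for 13 of 15 rows (the col2a1a and si:dkey-12l12.1 rows are
internally inconsistent with their own product — apparent print typos) and
exactly at two decimals for cmn (508.22), loxl5b (418.28), and ta (234.74),
with emilin3a ranked first.

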