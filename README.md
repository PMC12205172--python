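# sonata

**Diagnosing ambiguous mappings in diagonal integration of multimodal
single-cell data.**

Diagonal integration aligns single-cell modalities that share *neither
cells nor features* (say, scRNA-seq and scATAC-seq from different cells)
purely through the shape of their latent manifolds. That flexibility has
a failure mode: when two regions of a manifold are geometrically
interchangeable — mirrored differentiation branches, rotated cycles —
an integration method can map either region onto the other modality's
counterpart at near-identical cost, and silently report a *biologically
wrong* alignment that is mathematically indistinguishable from the right
one.

This package is a diagnostic add-on for any such pipeline. Given one
modality as a cell x feature matrix it:

1. builds the cell manifold (weighted k-NN graph, graph-geodesic
   distances `K`);
2. self-aligns the modality against noise-perturbed *variational copies*
   of itself with entropic Gromov-Wasserstein optimal transport,

   `min_{Γ ∈ Π(p, p̃)}  Σ_{i,j,k,l}  ½ (K_ik − K̃_jl)²  Γ_ij Γ_kl`

   so that congruent far-apart regions reveal themselves by exchanging
   transport mass;
3. tests every cell pair against an antitonic null — correspondence
   probability may only decay with geodesic distance, fit as a monotone
   cubic smoothing spline — and calls pairs that are significant
   (one-sided p ≤ 0.01), geodesically distant, and carry at least 2× the
   same-distance typical mass;
4. aggregates ambiguous pairs into substitutable cell groups by
   cannot-link constrained clustering (COP-k-means, elbow-selected group
   count);
5. for each confused group pair (Gs, Gt) emits an alternative
   integration `Γ_alt = P · Γxy`, where the soft permutation `P` swaps
   the groups according to the self-alignment coupling;
6. scores candidates with FOSCTTM and label-transfer accuracy when
   ground truth is available — and otherwise leaves ranking to the user,
   because geometry cannot decide which solution is biologically true.

A built-in GW baseline aligner and a generator for four simulated
two-modality benchmarks (T-/Y-/X-shaped branching trajectories with
planted ambiguity and an unambiguous decaying hook) make the whole
pipeline exercisable end to end without external data.

## Worked example

```python
import numpy as np
from sonata import (RunConfig, cross_modality_align, diagnose,
                    generate_alternatives, score_coupling, simulate)

# two modalities of 300 cells on a T-shaped manifold whose two arms are
# exact mirror images -- the classic ambiguous case
pair = simulate("t_branch", seed=1)

report = diagnose(pair.modality_x, RunConfig(seed=1))
print(report.summary())

gamma = cross_modality_align(pair.modality_x, pair.modality_y, seed=1)
orig = score_coupling(gamma, pair.manifold_coords_y,
                      labels_x=pair.branch_labels, labels_y=pair.branch_labels)
cands = generate_alternatives(report.groups, report.ensemble.consensus, gamma,
                              null_spline=report.spline,
                              geodesic=report.ensemble.source_geodesic)
scores = [score_coupling(c.gamma_alt, pair.manifold_coords_y,
                         labels_x=pair.branch_labels,
                         labels_y=pair.branch_labels) for c in cands]
for cand, sc in zip(cands, scores):
    print(f"{cand.name}: FOSCTTM={sc['foscttm']:.3f}  LTA={sc['lta']:.3f}")
```

Output:

```
cells: 300
significant ambiguous pairs: 8604 of 44850 (19.18%)
integration FLAGGED AS AMBIGUOUS: 2 substitutable cell groups
original: FOSCTTM=0.431  LTA=0.330
swap_0_1: FOSCTTM=0.030  LTA=0.897
```

Reading this: 19% of cell pairs are significantly ambiguous and they
aggregate into 2 substitutable groups — the two mirrored arms. At this
seed the baseline aligner indeed fell into the branch-swapped solution
(FOSCTTM 0.43 ≈ the value a mirror flip produces; label transfer 33%),
and the alternative obtained by swapping the two diagnosed groups is the
correct integration (FOSCTTM 0.030, label transfer 90%). On the
unambiguous decay-path dataset the same pipeline reports
"integration not flagged as ambiguous" and emits no alternatives.

The same workflow is available from the shell:

```bash
sonata simulate --shape t_branch --n 300 --seed 1 --out sim/
sonata run --data-x sim/X.tsv --data-y sim/Y.tsv --seed 1 --out run/
cat run/summary.txt
```

`run/` then contains the consensus self-coupling, geodesic matrix,
per-pair ambiguity table, group assignments, elbow curve, the baseline
coupling and one `alt_<s>_<t>.tsv` per alternative, plus the resolved
`config.yaml` that reproduces the run bit-for-bit.

## Layout

| module | contents |
| --- | --- |
| `sonata.manifold` | data container, k-NN graph, geodesics, variational copies |
| `sonata.selfalign` | entropic GW solver, self-alignment ensemble, baseline aligner |
| `sonata.ambiguity` | antitonic null spline, per-pair p-values and calls |
| `sonata.groups` | constrained clustering, elbow selection |
| `sonata.alternatives` | soft permutations, alternative solutions |
| `sonata.metrics` | FOSCTTM, label-transfer accuracy, barycentric projection |
| `sonata.simdata` | simulated two-modality benchmarks |
| `sonata.io`, `sonata.pipeline`, `sonata.cli` | files, orchestration, CLI |

See `docs/methods.md` for the model, parameter meanings, numerical
choices, and limitations.
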