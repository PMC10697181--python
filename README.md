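# wconn — weighted structural brain connectome analysis

`wconn` builds and characterizes weighted structural connectivity (SC)
networks of the kind produced by diffusion-MRI tractography, together with
functional connectivity (FC), and asks how the choice of edge weighting
changes what a brain network looks like. It is aimed at network-neuroscience
researchers who want a tested, scriptable implementation of this analysis —
and, because real multimodal MRI cohorts are large and access-controlled, it
ships a first-class synthetic-cohort generator so every stage can be
exercised and validated without any download.

## What it computes

**Edge-weight construction.** From per-streamline records (endpoints, length
`l_k`, per-method weights, per-metric medians) it builds eight SC weightings
per subject: NoS (streamline count), LoS (mean streamline length), SIFT2
(sum of SIFT2 streamline weights), COMMIT (the length-weighted sum of COMMIT
streamline weights),

```
alpha_ij = sum_{k=1..N_ij} x_ijk * l_k / Lbar_ij
```

and four tractometry weightings (R1, FA, RD, ICVF; median along each
streamline, mean across streamlines). NoS, SIFT2 and COMMIT are normalized
by node volume. FC is the Fisher-Z Pearson correlation of node time series.
Post-processing removes streamlines with COMMIT weight < 1e-12, zeroes those
edges in *all* weightings within subject (so the binary map is identical
across weightings), applies a 50% group-consensus mask, and averages across
subjects excluding zeros.

**Edgewise statistics.** Variability via the quartile coefficient of
dispersion, `CQD = (Q3 - Q1) / (Q3 + Q1)`, intra-subject (across a subject's
edges) and inter-subject (across subjects per edge); edge-length binning
(five bins of width `w = range/8` plus one of width `3w`); module-resolved
summaries (within/between module; unimodal VIS+SMN vs transmodal
DMN/CONT/DAN/SVAN); Spearman correlations of length-residualized edge
weights (OLS on edge length) with FC and with the myelin-sensitive R1
weighting; one-sided permutation p-values.

**Null-normalized topology.** Degree-preserving (Maslov–Sneppen double-edge
swap) and degree-and-strength-preserving (rewire, then simulated-annealing
placement of the original weight multiset) surrogate networks normalize:
small-worldness `S = (C/C_null) / (L/L_null)` with Onnela clustering and
`-log` weight-to-length shortest paths; the weighted rich-club curve
`phi_norm(k) = phi(k) / <phi_null(k)>` with a rich club detected where
`phi_norm > 1`; and a 0–5 hubness score per node (top-20% strength,
betweenness, closeness, eigenvector centrality; bottom-20% clustering), with
Euclidean distances between the hubness vectors of different weightings.

## Worked example

```python
from wconn import GeneratorConfig, simulate_cohort, edge_vectorize
from wconn import stats as st

cohort = simulate_cohort(GeneratorConfig(seed=1))   # 90 nodes, 10 subjects
mask = cohort.mask
lengths = edge_vectorize(cohort.group["LoS"], mask)
fc_res = st.residualize_on_length(edge_vectorize(cohort.group["FC"], mask), lengths)
for name in ("NoS", "SIFT2", "COMMIT", "R1"):
    res = st.residualize_on_length(edge_vectorize(cohort.group[name], mask), lengths)
    print(name, round(st.spearman(res.values, fc_res.values), 3))
```

prints

```
NoS 0.449
SIFT2 0.386
COMMIT 0.772
R1 -0.08
```

i.e. after regressing out edge length, the connection-strength weightings
(NoS, SIFT2, COMMIT) remain *positively* correlated with FC while the
myelin-sensitive R1 weighting is *negatively* correlated — the qualitative
dissociation this analysis is designed to expose. On the same cohort the
median intra-subject CQD is ~0.56 for COMMIT versus ~0.07 for R1
(streamline-specific weights are far more dispersed than tractometry), and
the binned R1–COMMIT correlation flips sign from −0.63 in the shortest
edge-length bin to +0.09 in the longest.

The same pipeline is scriptable from the shell:

```
wconn run --preset desk --seed 1 --out runs/demo
wconn topology --network runs/demo/networks/group/COMMIT.csv --n-nulls 20 --out runs/topo
```

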