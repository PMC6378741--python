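# synscreen

Statistical analysis of large, sparse drug-combination screens: solve
single-drug (singlet) viabilities from the combination wells themselves via a
log-linearized Bliss independence model, call synergy and antagonism with
p/q values calibrated on DMSO control wells, and summarize a screen with
absolute and specificity synergy scores plus randomization nulls.

## Who this is for

High-throughput combination screens trade dose coverage for breadth: all
pairwise combinations of ~100 drugs across tens of cell lines leave one well
per drug pair and dose, with no replicates. At that sparsity the classical
excess-over-Bliss score inherits the full measurement error of the two
singlet wells — one badly measured singlet poisons the synergy score of every
combination involving that drug — and thresholding it produces call counts
that track assay noise rather than biology. `synscreen` implements a
statistical pipeline for exactly this regime, working from long-format CSV
plate tables (1536-well or smaller) of nuclei counts.

## The model

Viability is `V = count / trimmed-mean DMSO count` per plate. Bliss
independence states `V_ij = V_i · V_j` for non-interacting drugs; on
`W = -log10(V)` it is additive:

```
W_i + W_j ~ W_ij + ε        (one equation per combination well)
```

For one assay (one cell line at one dose pair) the C(n,2) combination wells
form an over-determined linear system in the n unknown singlet
log-viabilities — 5778 equations for 108 unknowns at full scale — solved by
ordinary least squares. Measured singlet wells are deliberately excluded, so
each `Ŵ_i` borrows strength from the n−1 combinations containing drug i.

The residual `r_ij = W_ij − (Ŵ_i + Ŵ_j)` measures departure from
independence (`r > 0` ⇔ synergy). Under the null it is Gaussian with mean 0
and variance `var_DMSO + se_i² + se_j²`, giving one-sided p values in each
direction, Benjamini–Hochberg q values per assay, and calls at `q < 0.05`; a
pair is synergistic in a cell line if either dose calls it. Per pair the
absolute synergy score `T_ij` counts synergistic cell lines, and the
specificity score

```
Sc_ij = min( (T_ij − ⟨T_ik⟩_k) / SD(T_ik)_k ,  (T_ij − ⟨T_kj⟩_k) / SD(T_kj)_k )
```

separates partner-specific synergy from broad sensitization by promiscuous
drugs. Two randomization nulls (within-cell-line permutation, and a binomial
matrix null that preserves each drug's total synergy count) test whether the
observed pair structure exceeds what drug-level promiscuity explains.

## Worked example

A synthetic 20-drug × 8-cell-line screen with three planted specific
synergies (`ΔW = 0.25` on pairs D01–D02, D03–D04, D05–D06), one planted
antagonism, and one promiscuous sensitizer (D07):

```python
import synscreen as ss

spec = ss.default_screen_spec(seed=0)
spec.row_col_artifact_sd = 0.0          # desk-scale plates: no spatial artifacts
plates, truth = ss.generate_screen(spec)
assays = ss.compute_viabilities(plates, polish=False)

fit = ss.fit_assay(assays[ss.AssayKey("CL1", "high")])
print(f"assay CL1:high  m={fit.m} pairs, n={fit.n} drugs, R^2={fit.r_squared:.3f}")

calls = {k: ss.infer_assay(ss.fit_assay(t), t) for k, t in assays.items()}
high = calls[ss.AssayKey("CL1", "high")]
print(high[high.synergistic][["drug1", "drug2", "z", "q_syn"]].to_string(index=False))

combined = ss.combine_all_doses(calls)
cube = ss.cube_from_calls(combined, drugs=spec.drug_names,
                          cell_lines=spec.cell_line_names)
print(ss.score_screen(cube).head(5).to_string(index=False))
```

prints

```
assay CL1:high  m=190 pairs, n=20 drugs, R^2=0.853
drug1 drug2        z    q_syn
  D01   D02 4.375570 0.000384
  D03   D04 3.786386 0.003630
  D05   D06 4.905180 0.000044
  D07   D15 5.047275 0.000043
  D07   D20 3.314052 0.017471
 rank drug1 drug2  absolute_score  specificity_score  sc_percentile
    1   D05   D06               7           4.087451     100.000000
    2   D01   D02               7           3.557760      99.473684
    3   D07   D15               6           2.163462      97.894737
    4   D03   D07               5           1.690982      97.368421
    5   D04   D07               5           1.690982      97.368421
```

The Bliss model fits the assay well (R² = 0.85 against the mean-model
baseline). In cell line CL1 at high dose the three planted pairs are all
recovered at q ≪ 0.05, along with two combinations of the promiscuous
sensitizer D07. After combining doses and counting across the 8 cell lines,
the two screen-wide planted pairs top the ranked list with specificity
scores near 4, while D07's many pairs — synergistic, but explained by one
drug's promiscuity — are pushed down to specificity ~1.7–2.2.

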