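# specisite

Comparative-sequence discovery of **specificity-determining positions**
in enzyme families, modelled on the evolution of substrate
multispecificity in the NAD⁺-dependent deacetylase SIRT1.

A single enzyme like SIRT1 deacetylates dozens of substrates — histones,
p53, RelA/p65 — yet its substrate repertoire expanded over evolution:
histone activity is ancient and universal, while activity toward p53-like
substrates appears only in complex metazoans. The residues that control
this expansion are *semiconserved*: conserved within major clades
(e.g. Metazoa vs. Fungi) but divergent between them, solvent-exposed, and
clustered near functional regions. `specisite` implements the full
desk-side workflow for finding and interpreting such positions:

1. **Candidate positions** — per-column Shannon entropy
   `H = −Σₐ pₐ log₂ pₐ` (and class entropy over a 5-class
   physicochemical partition), clade-divergence score
   `D = min(f_A, f_B)` for differing clade consensus residues,
   surface-accessibility and gap filters, and single-linkage spatial
   clustering of the survivors (10 Å C-β cutoff).
2. **Coevolution** — mutual information between column pairs with the
   average-product correction, `MIp(i,j) = MI(i,j) − MIᵢ·M·ⱼ/M··`,
   reported mean-scaled so that 1 marks the average pair.
3. **Ancestral sequence reconstruction** — Felsenstein pruning under a
   reversible amino-acid model (`Q_ij = s_ij π_j`, mean rate 1), marginal
   posteriors at any internal node by up–down message passing, text
   sequence logos, and combinatorial mutant panels that take the top-two
   states wherever the MAP posterior falls below a threshold.
4. **Substrate phylogenetic profiling** — best-hit Smith–Waterman
   (BLOSUM62, affine gaps 11/1), Karlin–Altschul bit conversion
   `bits = (λS − ln K)/ln 2`, conservation = bits per alignment column,
   presence calls with a coverage requirement, and acetyl-lysine
   fixation tracking through the alignment column map.
5. **Kinetics** — Michaelis–Menten fits `v = V_max[S]/(K_M+[S])` by
   nonlinear least squares, per-replicate fits averaged (mean ± SD),
   catalytic efficiency `k_cat/K_M` (mM⁻¹ s⁻¹), and mutant-vs-wild-type
   fold changes; fluorogenic-assay slopes normalized to wild type.
6. **Synthetic data** — a seeded generator producing every input with
   ground truth (planted divergent sites, planted covarying pairs,
   branch-specific substrate gains, true ancestral sequences, true
   kinetic parameters), so each stage's recovery can be scored.

## Worked example

Generate a synthetic study (64 species in two clades, 200 sites, five
planted divergent positions) and run the full pipeline:

```bash
specisite simulate --seed 42 -o data/
specisite run config.yaml      # paths to data/, clades CladeA,CladeB
```

`positions.tsv` flags exactly the five planted positions as candidates
(all clustered in space — they were planted near one pocket):

```
residue_number       H       D    rsa  cluster_id
            20 1.00000 1.00000 0.7321           1
            55 1.00000 1.00000 0.3777           1
            90 1.30021 0.93750 0.7176           1
           130 1.10031 0.96875 0.4915           1
           170 1.10031 0.96875 0.4233           1
```

`D = 1.0` at position 20 means every CladeA sequence carries one residue
(R) and every CladeB sequence another (A). `couplings.tsv` shows the
candidate pairs' mean-scaled couplings, all far above the average-pair
score of 1 (the planted clade switch makes the candidates co-vary as a
block, exactly the signature the scaled-score convention highlights):

```
i   j    MI        MIp       scaled
20  55   1         0.884693  9.71617
20  170  1         0.869077  9.54466
...
```

`asr_variants.tsv` renders the ancestor-guided mutant panel against the
reference sequence; the CladeA ancestor is wild-type at the focal sites
and the CladeB ancestor prescribes the full residue swap:

```
ancestor  variant  mutations                   min_posterior
N31       N31_v1   WT                          0.990959
N62       N62_v1   R20A/L55E/N90D/K130Q/F170S  0.999807
```

`kinetics.tsv` and `kinetics_folds.tsv` recover the generator's true
parameters (WT: k_cat 0.4 s⁻¹, K_M 17.4 µM; variant: 0.3 s⁻¹, 42.2 µM)
from noisy rate data and express the variant as fold change over WT:

```
enzyme  k_cat_per_s  K_M_uM   efficiency_mM_s     K_M_fold
WT      0.396        15.9     25.0                1.00
VAR     0.305        44.3     6.9                 2.79
```

A rise in K_M with little change in k_cat — reduced substrate affinity
at preserved turnover — is the signature expected when active-site
vicinity residues are swapped to another clade's states.

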