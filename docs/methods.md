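# Methods

This note documents the models, defaults and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinate frame

All analyses report positions in the numbering of a designated reference
sequence. The column map is built from the reference row of the
alignment (gap columns unmapped); a `start=N` tag in the reference FASTA
header offsets the numbering, which matters when the construct analysed
is a fragment of the full-length protein. Gap characters are `'-'` only
(`'.'` is converted on read); `'X'` and other ambiguity codes are
rejected rather than guessed at.

## Candidate-position filters

A specificity-determining position is operationalized as a column that
is (i) *semiconserved*, (ii) chemistry-switching, (iii) clade-divergent,
(iv) solvent-exposed, and (v) observed (not gap-dominated). Each
criterion is an independent filter with a logged verdict, so loosening
any one threshold can only grow the candidate set.

| filter | default | status |
|---|---|---|
| entropy window `H ∈ [H_lo, H_hi]` | [0.3, 2.5] bits | operational stand-in |
| class entropy, polarity "across" | `H_class > 0.5` bits | operational stand-in |
| clade divergence `D ≥ d_min` | 0.8 | operational stand-in |
| relative solvent accessibility | `rsa ≥ 0.2` | operational stand-in |
| gap fraction | ≤ 0.5 | common practice |

All thresholds marked *operational stand-in* are explicit package
choices exposed in the filter config — they encode "semiconserved",
"surface" and "strong clade consensus" as concrete numbers and should be
recalibrated for other protein families. Entropies use gap-excluded
frequencies with no pseudocounts; the small-sample bias this leaves in
sparse columns is accepted and documented rather than smoothed away.
The physicochemical partition is hydrophobic AVLIMFWC / polar STNQYG /
positive KRH / negative DE / special P, replaceable via configuration.
Class polarity defaults to "across" because substrate-specificity
switches typically change residue chemistry; the "within" polarity is
available for conservative-variation screens.

The divergence score for clades A, B is `D = min(f_A, f_B)` where `f`
is the gap-excluded frequency of the clade's modal residue, and `D = 0`
when the modal residues agree. Modal ties break alphabetically, making
the score deterministic and symmetric in clade order. Columns where a
clade has fewer than 2 observations get `D` undefined and are excluded
from ranking rather than scored 0, so missing data is not mistaken for
conservation.

Spatial grouping of candidates is single-linkage clustering on
Euclidean distances between representative atoms (C-β, C-α for glycine)
at a 10 Å cutoff — a deterministic replacement for by-eye grouping of
proximal pairs on a structure. Only clusters of size ≥ 2 are reported.

## Coevolution

Couplings are mutual information in bits between column pairs, with
rows gapped at either column dropped per pair (pairwise deletion) and
pairs with fewer than 10 complete rows excluded. The average-product
correction `MIp(i,j) = MI(i,j) − M̄ᵢ M̄ⱼ / M̄` (means over off-diagonal
entries) removes the separable background that per-column entropy and
shared phylogeny induce; the corrected matrix is divided by the mean of
its positive off-diagonal entries so a score of 1 marks the average
pair and candidate couplings read on the same "scaled, threshold 1"
convention as regularized-pseudolikelihood coupling servers. The APC is
exactly zero on a constant background; it is *not* exactly invariant to
adding a constant to an arbitrary matrix (that identity requires equal
row means), and the test suite checks the exact special cases only. No
sequence weighting is applied by default. MI is a stand-in for
pseudolikelihood couplings: it reads the same way but is not expected
to agree score-for-score with them, and unlike them it does not
disentangle direct from transitive correlation — pairs that merely
co-follow a clade split score high together, which is visible (and
informative) when whole candidate blocks co-vary.

## Ancestral sequence reconstruction

The substitution model is reversible, `Q_ij = s_ij π_j` with symmetric
exchangeabilities, normalized to mean rate 1 so branch lengths are
expected substitutions per site. Defaults: Poisson (equal)
exchangeabilities with uniform or alignment-empirical frequencies
(+1 count floor); LG/WAG-style matrices load from PAML-format files.
Transition matrices come from the spectral decomposition of the
symmetrized generator `D^{1/2} Q D^{-1/2}`, which is exact, stable and
cheap for reversible models; eigenvalues are reused across branches.

Site likelihoods use Felsenstein pruning with gaps as missing data
(all-ones partial vectors). Marginal posteriors at a node multiply the
below-node partial by an outside message computed in pre-order; the
outside message carries the stationary prior, so at the root the
product reduces to `π_x L_root(x)`. Correctness is pinned by an
exhaustive-enumeration oracle (all internal-state assignments summed
explicitly) on 4-tip, 4-state instances, to 1e-10 on both
log-likelihood and posteriors, and by a re-rooting invariance check
(reversibility). One rate across sites; no rate heterogeneity — a
documented limitation that flattens posteriors at fast sites.
Reconstruction quality is claimed via recovery on simulated data, not
via model identity with any published analysis.

Variant panels admit, per focal position, the MAP state alone when its
posterior reaches the ambiguity threshold (default 0.8) and exactly the
top two states otherwise — never three. The Cartesian product across
positions is capped (default 8) with an error advising a higher
threshold, and each variant is rendered as a mutation list against the
reference (`R20A/L55E/...`; `WT` when empty).

## Substrate profiling

Conservation of a substrate in a species is the best-hit local
alignment (Smith–Waterman, BLOSUM62, gap open 11 / extend 1) converted
to bits with the standard gapped Karlin–Altschul parameters λ = 0.267,
K = 0.041, divided by alignment length *including gap columns*. A
substrate is called present when conservation ≥ 0.5 bits/column **and**
the alignment covers ≥ 50% of the substrate. The coverage requirement
is essential, not cosmetic: the best local alignment between unrelated
sequences is a short high-scoring island whose bits-per-column is high
(measured mean ≈ 2 bits/column on unrelated 60-mers) while its coverage
stays low, so a bare bits-per-column threshold cannot call absence.
Acetyl-lysine fixation is read through the alignment column map: the
human lysine position is traced to the aligned target residue, and the
cell records whether it is still a lysine. Both thresholds are
operational choices standing in for database-backed orthology calls
plus manual curation, which are outside this package's scope.

## Kinetics

Rates are fit untransformed (no Lineweaver–Burk linearization) by
unweighted nonlinear least squares with V_max initialized at the
maximum observed rate and K_M at the interpolated half-maximal
substrate concentration; optimizer tolerances are set to 1e-12 so fits
are invariant to point order and to rate rescaling at test precision.
Replicates are fit independently and parameters averaged (mean ± SD) —
the convention of kinetic parameter tables — which is why a mean
efficiency can differ from the ratio of mean parameters; the summary
table reports both. Units are fixed once: [S] and K_M in µM, k_cat in
s⁻¹, efficiency in mM⁻¹ s⁻¹. Errors on single fits are from the fit
covariance; the replicate SD is reported as the spread (whether a
published table's ± is SD or SEM is often unstated; SD is assumed and
labelled). Substrate depletion, coupled-assay chemistry and
inner-filter effects are not modelled.

## Synthetic-data generator

The generator defines the package's standard study conditions: 64 tips
in two equal clades, 200 sites, ultrametric tree of height 1.0
expected substitutions/site, five planted divergent sites, one planted
covarying pair, 5% multiplicative kinetic noise, all determined by one
mandatory seed.

*Tree.* Two equal-size clades joined at the root by stems of 5% of the
height, with split depths uniform over the top 90% of each clade's
height. The uniform-depth ("radiation") shape emulates a taxonomically
broad ortholog sample in which major lineages split in quick
succession, so several lineages cross every depth; a unit-rate
pure-birth clock instead concentrates nearly all depth in two or three
basal lineages, which both starves the root of independent signal
(root-state recovery caps below 90%) and makes the deepest split
between clades erratic. Equal clade sizes keep the divergence contrast
well-posed (both clades always have enough observations).

*Planted divergent sites.* The state is forced to the clade residue on
each stem branch; within clades the site is under purifying selection,
modelled as substitutions on terminal branches only, at the configured
rate multiplier (default 0.05). Terminal-only escapes are the
realistic signature of a clade-constrained site — a deep within-clade
substitution at such a site would have been purged, and mechanically it
would flip half a clade and destroy the planted pattern the generator
exists to produce. Planted sites end with within-clade consensus
≥ ~0.9 and D near 1, against a neutral background whose maximum D is
driven by rare stem substitutions.

*Planted covarying pair.* A latent binary state per lineage flips with
telegraph-process probability `(1 − e^{−2st})/2` per branch (switch
rate s = 1.0) and deterministically sets both sites to one of two joint
configurations — the simplest mechanism producing correlated
substitutions without direct physical modelling.

*Substrates and proteomes.* Each substrate (default length 150 aa, one
fixed acetyl-lysine) is gained on a designated branch and evolves by
per-site point substitutions (rate 0.2 per unit branch length) down to
exactly the species below the gain; other species carry only random
decoy proteins. Substrate length matters: at unrealistically short
lengths (~60 aa) spurious decoy alignments occasionally satisfy both
presence criteria, an artifact of scale rather than of the method.
A configurable lysine→arginine toggle exercises fixation-loss cells.

*What is not emulated.* No indels (alignments are gap-free unless
configured), no rate heterogeneity across neutral sites, no
compositional biases, no alignment or tree-inference error (the true
alignment and tree are handed to the pipeline), no database-search
stage. Passing recovery tests therefore demonstrates the statistical
machinery under clean conditions; on real data, alignment quality,
taxon sampling and model misfit dominate, and thresholds must be
recalibrated.

## Problem sizes and determinism

The test suite and acceptance script use the generator's standard
conditions throughout: 100 replicates for ranking/recovery rates, 100
random instances for the enumeration oracle, 20 replicates for
presence concordance, and single runs for the end-to-end pipeline;
the full acceptance script completes in about two minutes on one CPU.
Every stochastic step draws from an explicit seed, pipeline outputs
embed a config hash, and reruns with an unchanged config are bitwise
identical (checksums recorded in the run manifest).
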