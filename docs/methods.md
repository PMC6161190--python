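# Methods

`psdnet` analyses how the postsynaptic density (PSD) proteome differs
between brain regions and how those differences reorganise the weighted
protein–protein interaction (PPI) network. This note documents the
statistical models, the numerical choices, and what the synthetic data
do and do not establish.

## Quantification model

Input is a tensor of strictly positive summed peptide-ion intensities
I(p, r, k) for protein p, region r and replicate brain k, with a
unique-peptide count per protein. Zero or missing intensities are
rejected at load; no imputation is performed.

**Normalisation.** Each LC-MS run (one region × brain sample) is
multiplied by a single scalar `exp(median(log I_ref) − median(log I_run))`
so that all runs share the reference run's median log intensity. The
operation is idempotent; the reference defaults to the first run.

**Transform.** Test statistics use the ArcSinH transform
`arcsinh(x) = ln(x + √(x²+1))`, a variance-stabilising map that behaves
like `ln(2x)` for large intensities but is defined at zero. Fold changes
are ratios of *raw* (normalised, untransformed) group means; the two
scales are deliberately separate.

**Tests.** Per protein, a one-way ANOVA across regions on transformed
values gives the omnibus F and p; each region pair gets a Welch
two-sample t (the pairwise contrast procedure is not dictated by the
upstream software we emulate; Welch is the robust default consistent
with ANOVA on transformed values). Contrasts with zero variance in both
groups are flagged degenerate and reported as p = 1 (equal means) or
p = 0 (unequal), never NaN. Benjamini–Hochberg step-up adjustment is
applied across proteins within each contrast (statsmodels implementation;
an independently hand-coded step-up formula serves as the test oracle).

**DE rules.** A protein is differentially expressed (DE) in region r
when (i) BH-adjusted pairwise p < α (default 0.05), (ii) it was
quantified with ≥ 2 unique peptides, and (iii) its fold change against
comparison regions is ≥ the threshold (default 1.5; 1.3 with the
reciprocal 0.667 bound is the documented alternative) or ≤ its
reciprocal. The default mode (`all`) requires the fold and significance
conditions against *every* other region in a consistent direction — the
protein stands out from the whole brain; `any` accepts a single
qualifying contrast.

## Differential stability

For each protein, the Pearson correlation of its R-vector of regional
intensities is computed for every pair of replicate brains and averaged
over all C(B, 2) pairs (15 for six brains). Pairs in which either
brain's profile is constant have undefined correlation; they are skipped,
the pair count decremented and the protein flagged. The high-DS cutoff
defaults to the median avgCor, structurally reproducing a "reproducible
half" split; it is configurable.

## Modules (PPMs) and Circos links

The protein × region mean-abundance matrix is row Z-scored (pattern,
not level, defines a module) and clustered agglomeratively with
Euclidean distance and complete linkage — the classic heatmap defaults.
The module count K is chosen by majority vote of three internal indices
(silhouette, Calinski–Harabasz, Dunn) over dendrogram cuts, ties toward
the smallest K. Region dendrograms use the columns of the same Z-scored
matrix.

For Circos links, a protein is "positive" in the regions where its
Z-scored profile is above zero. A protein positive in k > 1 regions
contributes weight 1/(k−1) to each unordered pair of its positive
regions; the link width for (A, B, module) is the summed contribution of
that module's proteins positive in both, divided by the number of
proteins positive in A. The fractional contribution guarantees that the
widths emitted from any source region sum to at most 1, which a raw
pair count would violate for proteins spanning three or more regions.

## Weighted PPI networks and spectral community detection

The PPI graph keeps edges whose endpoints are both quantified, without
self-loops or duplicates. Each region reuses the same topology with
edge weights w_r(a,b) = (Exp_r(a) + Exp_r(b))/2, the mean of the
endpoints' mean regional abundances.

Partition quality is weighted Newman–Girvan modularity

    Q = (1/2m) Σ_ij [w_ij − s_i s_j / (2m)] δ(c_i, c_j)

with node strengths s in place of degrees (the standard weighted
generalisation) and m the total edge weight. Communities are found by
recursive bipartition: each group's generalised modularity matrix
B(g) = B_sub − diag(row sums) is formed, the group is split by the sign
of B(g)'s leading eigenvector, and a Kernighan–Lin fine-tuning pass
repeatedly sweeps all nodes (each moved at most once per pass, best
intermediate state kept) until no sweep improves the split. Recursion
stops when the best split does not increase total Q. Numerical choices:

* the leading eigenpair comes from a dense symmetric eigendecomposition
  with a fixed sign convention (largest-magnitude entry positive) —
  deterministic and robust on indefinite matrices at these graph sizes
  (≈10³ nodes);
* eigenvector entries equal to zero are assigned to group 1;
* if the eigenvector does not split the group, fine-tuning starts from a
  deterministic alternating seed split and the result is accepted only
  if it increases Q;
* connected components are partitioned independently; isolated nodes are
  singleton communities;
* improvement tolerance 1e−12.

The procedure is a heuristic: on random graphs of ≤ 10 nodes it attains
the exhaustively enumerated optimum in ≥ 90% of instances (tested), not
all.

## Stable core network

For each edge, each region contributes 1 when the endpoints fall in
different communities of that region's partition; the sum over R regions
is the edge's stability score (0 = always co-clustered). Only
within-region co-membership is used, so no community-label alignment
across regions is needed. The stable network keeps scores ≤ max_score
(default 2 with R = 7, i.e. co-clustered in ≥ 5/7 regions; for other R a
cutoff near 2R/7 preserves the same "large majority" reading), is
re-clustered with the same spectral method, and its communities are
compared with the PPMs by one-sided hypergeometric tests, BH-adjusted
across all community × module pairs.

## Connectome correlation

The connectivity vector is the row mean of the region × region
projection-volume matrix, self-projection included. Each protein's
per-region mean abundance (brains pooled) is Pearson-correlated with
that vector; proteins with r² ≥ 0.6 (configurable) are
connectivity-correlated. Fisher z = atanh(r) is reported alongside raw
r (clipped at |r| = 1 − 1e−12). Constant profiles are flagged and never
selected. The region-level clustered matrix correlates each region's
abundance-similarity profile with each region's projection row over the
shared region axis; its diagonal dominates when molecular similarity
tracks anatomical connectivity.

## Enrichment

Classic over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) for overlap k between a study set (size n) and a term's
proteins (K) in a universe of N. Annotations are first closed over
is_a ancestors (true-path rule). The elimination variant processes
terms bottom-up by longest-path-to-root level (ties in lexicographic id
order); a term significant at alpha_elim (default 0.01, the customary
elimination threshold) has its proteins removed from all ancestors
before they are tested, so parents are judged on signal their
significant children do not explain. Universes are explicit: network
node set for network-cluster enrichment, full quantified proteome for
PPM/DE enrichment.

## Synthetic data

The generator emulates the study's structure — 1173 proteins × 7
regions (CxF, CxM, CxCA, Hip, ST, Hyp, CB) × 6 brains by default — with
known ground truth. Intensities are multiplicative:
baseline (log-normal, ln-mean 13, ln-sd 1.5, spanning the right-skewed
intensity range of label-free data) × per-(module, region) effect
(log-normal, sd 0.4; the three cortex-like regions share a group value
with jitter sd 0.1, planting a cortical clade) × planted DE effect
(fold 2 up or down in one region for 20% of proteins) × replicate noise
(log-sd ln(1 + CV), CV 0.1 — the low single-digit-percent precision of
summed intensities). Optional switches: a fraction of proteins with a
single unique peptide (10%, exercising the peptide filter), per-brain
region-shuffled "unstable" proteins (0% by default), and
connectome-coupled proteins (10%) whose regional effect follows a shared
profile that also sets the connectome's row means, so their abundance is
affine in the connectivity vector. The PPI graph is a stochastic block
model on the module labels (p_in 0.05, p_out 0.005 → ≈8×10³ edges over
≈10³ proteins); the ontology is a small rooted DAG whose leaf terms
annotate planted modules (90% coverage, 2% noise). A single seed is
split into per-component substreams, so changing one component never
reshuffles the others.

The generator does **not** model missing values, peptide-level
variation, retention-time artefacts, shared-peptide ambiguity, or
database-snapshot idiosyncrasies of mined PPIs. Passing tests therefore
establish correctness of the computations and recoverability of planted
structure under clean conditions — not performance on real LC-MS data.
Test configurations isolate the mechanism under study: DE-recovery runs
disable module effects and coupling so the planted DE map is the entire
truth; DS-separation runs shuffle half the proteins per brain.

## Problem sizes and determinism

Default runs use the full emulated scale (1173 × 7 × 6; ≈8.6k-edge
networks), which completes in well under a minute per pipeline run;
oracle-based checks use graphs of ≤ 50 nodes (brute-force Q) and ≤ 10
nodes (exhaustive partition enumeration). Every stage is deterministic
given the configuration: repeated runs produce byte-identical run
reports (timestamps appear only in logs, never in outputs).

## Known limitations

* The spectral heuristic can miss the global modularity optimum, and
  recursive bipartition cannot represent some optimal non-hierarchical
  partitions.
* K-selection by three internal indices is a reduced stand-in for
  exhaustive index batteries; on weakly separated data it tends toward
  small K.
* The DE "all-others" rule is conservative for proteins elevated in two
  regions at once; `mode="any"` trades specificity for that case.
* Hypergeometric enrichment treats annotations as independent draws;
  correlated annotation structure inflates significance, which the
  elimination step only partially mitigates.
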