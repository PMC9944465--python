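# Methods

## The measurement model

A PamChip-style tyrosine-kinase array exposes 144 substrate peptides to a
tissue lysate; phosphorylated spots bind a fluorescent anti-phosphotyrosine
antibody and are imaged at increasing camera exposure times
(10, 20, 50, 100, 200 ms).  Within this exposure range the collected signal
is, to good approximation, proportional to exposure time on top of a
non-zero background, so each spot is summarized by the ordinary
least-squares line

    I(t) = a + b · t

fitted *with* intercept: background fluorescence at zero exposure is
physically non-zero, and forcing the line through the origin would bias the
slope whenever background varies between arrays.  The activity value is
`log2(100 · b)`.  The ×100 rescaling puts typical slopes (order 0.01–1
intensity/ms) onto a convenient log2 range.  The transform is undefined for
b ≤ 0, so slopes below a floor ε (default 10⁻³ intensity/ms) are clamped to
ε and the cell flagged `floored` — flagged, never silently dropped, so
downstream consumers can audit them.  Kinetic reads taken while the lysate
is still being pumped through the array are accepted in the input format but
not used for slope fitting; only the post-wash exposure series carries the
activity signal.

**QC.**  A peptide that shows no increase of signal with exposure time
carries no kinase-activity information.  The default filter removes a
peptide when the *median* of its fitted slopes across all sample×replicate
spots is ≤ 0; the median is robust to a single bad array.  `mean` and
`all_positive` variants are selectable.  On the default synthetic panel (42
flat peptides of 144) the filter leaves exactly the 102 informative
peptides in the zero-noise limit.  With symmetric measurement noise a truly
flat peptide has a fitted-slope median that falls on either side of 0 with
equal probability, so under noise the flat set is removed only in
expectation — an intrinsic property of any "no increase" rule applied to
zero-slope kinetics, not an implementation artifact.

**Duplicates.**  Arrays are technical replicates of one lysate, so
replicate averaging happens on the log2 scale (the geometric mean of
linear-scale activities); a linear-scale mode exists behind a flag.  A
missing replicate leaves the surviving value flagged `missing`; a floored
replicate propagates `floored` to the averaged cell.

## Profiling

Clustering is agglomerative with Euclidean distance (UPGMA/average linkage
by default; Ward, complete and single are selectable).  Peptides are cut
into k = 3 strata and samples into k = 2 groups; flat cuts use scipy's
maxclust criterion with a distance-threshold fallback when exactly tied
merges make maxclust undershoot.  Cluster identities are then named
semantically by mean activity — peptide clusters B (high), A
(intermediate), C (low), and sample groups 1 (low) / 2 (high) — so labels
are stable across runs and match how such heatmaps are usually read.

Differential phosphorylation between the two sample groups uses Welch's
unequal-variance t-test with Satterthwaite degrees of freedom (the safer
default when group variances differ; Student's pooled test is available),
two-sided p-values, and Benjamini–Hochberg q-values.  The significant set is
selected by p < α (default 0.05) with the realized FDR of that selection
(the largest q among selected rows) reported alongside, rather than by
q-thresholding; both modes are supported.  Fold change is computed on the
linear scale, `mean(2^v)` in the globally higher-activity group over the
lower one, so a planted log2 shift of 1 reads as fold change 2.

## Upstream-kinase consensus

Kinase–substrate annotation databases disagree in coverage and spelling.  A
kinase is *positively identified* for a peptide only when both configured
sources propose it.  Before intersecting, names are uppercased and folded
through a shipped, user-extensible alias table (HER4→ERBB4, Abl→ABL1,
Ron→MST1R, FAK→PTK2, …): without alias folding the ERBB4 peptide, annotated
"ERBB4" by one source and "HER4" by the other, would lose its consensus
call.  An empty intersection is a valid outcome (the peptide is carried
forward under its own identity but excluded from kinase-level summaries);
with more than two sources the rule generalizes to intersection over all.
A 36-peptide dual-source snapshot of the PTK panel ships with the package
as a reference fixture.  The Venn partition assigns each consensus kinase
to the exact set of peptide clusters containing at least one peptide that
calls it; regions are disjoint and exhaustive by construction and asserted
on every run.

## Network analysis

The PPI network is the induced subgraph of a confidence-filtered edge list
(default minimum confidence 0.4, the conventional "medium" threshold) on
the study's protein identifiers; identifiers with no retained interaction
remain as isolated nodes because the reported networks count them.  Edge
confidences do not enter shortest-path computations (unweighted paths, the
default of the standard network-analyzer tools); a weighted mode exists
behind a flag.

Centralities per node: degree; shortest-path betweenness normalized by
2/((n−1)(n−2)) with n the node's *component* size; closeness (n−1)/Σd
computed within the component; and Shimbel stress, the raw number of
shortest paths passing through the node (endpoints excluded), counted as
σ(s,v)·σ(v,t) over pairs with d(s,v)+d(v,t)=d(s,t).  Component-local
normalization is what makes the values of disconnected networks
interpretable; isolated nodes score zero.  Stress is implemented directly
(BFS path counts, O(n³) accumulation) and is verified against an
exhaustive path-enumeration oracle on all suite graphs with ≤ 8 nodes.

Hubs are the top `ceil(0.10 × main-component size)` nodes by degree;
bottlenecks the top 10 by betweenness; hub-bottlenecks the intersection,
ordered by degree then betweenness.  Ties break deterministically (degree,
betweenness, then lexicographic id for hubs; betweenness first for
bottlenecks).  Both the fraction and the count are parameters.

## Enrichment

Over-representation uses the upper-tail hypergeometric test: with universe
N, gene set K, query n and overlap k, p = P(X ≥ k).  Strength is
log₁₀(observed/expected), expected = n·K/N; gene ratio is observed/n,
reported as a fraction and formatted as a percentage in reports.  The
default universe is every gene in the loaded collection — an explicit
choice users should override (e.g. with the array-design universe) when
appropriate, since both p and strength depend on it.  Q-values are BH
across all tested sets; the default report keeps the top 20 by q.

## Clinical outcomes

ORR = (CR+PR)/evaluable and DCR = (CR+PR+SD)/evaluable with NE excluded
from the denominator — the denominator convention under which 15 PR of 19
enrolled with 2 NE yields 88.24 %, matching how such trials report.  The
Kaplan–Meier estimator is the standard product limit; the median is the
first time S(t) ≤ 0.5 (undefined when the curve never reaches 0.5).  The
log-rank test is Mantel–Cox: at each distinct event time the observed
group-1 deaths are compared with their hypergeometric expectation given the
risk sets, χ² = (O₁−E₁)²/V with the usual variance sum.  The hazard ratio
is Mantel–Haenszel, (O₁/E₁)/(O₂/E₂), with CI exp(log HR ± z·√(1/E₁+1/E₂))
— the estimator behind common graphing software rather than a Cox model,
which is out of scope.  Contingency tests are Fisher's exact (two-sided,
summing hypergeometric probabilities of tables as or more extreme) or χ²
without Yates correction (flag available); `auto` picks Fisher when any
expected count is below 5; a zero margin returns the degenerate p = 1.

## The synthetic-study generator

The generator emulates the structure of the study design it models: 18
cases × 2 duplicate arrays × 144 peptides × 5 exposure times, 42
kinetically flat peptides (true slope exactly 0), three planted peptide
strata with log2 levels (4, 6, 2) and sizes 34/29/39, two planted sample
groups of 9 cases each, and exponential survival with exponential
censoring.  Choices the design left open, fixed once:

* **Noise.**  Per-reading Gaussian intensity noise with sd
  `noise_sd · ln2 · max(b, 0.01) · √Sxx` (Sxx the centered sum of squares
  of the exposure grid).  Because the OLS slope error equals the reading
  error divided by √Sxx, this makes `noise_sd` the approximate sd of the
  recovered log2 activity — `sample_effect` and `noise_sd` then share a
  scale, and "effect = 2×noise" has its usual meaning.  Default
  `noise_sd = 0.25` log2 units, a realistic technical-replicate spread for
  log-scale array readouts.  The 0.01 floor keeps flat spots noisy.
* **Differential peptides.**  Half of the non-flat peptides (the leading
  block, deterministically) carry a +`sample_effect` log2 shift (default
  0.5) in sample group 2; the first synthetic pathway is built over the
  same block so the enrichment stage has a true signal.
* **Clinical.**  Best response is multinomial with default proportions
  PR/SD/PD/NE = 15/1/1/2 of 19; progression hazards are ln2/20.7 and
  ln2/39.4 per month (group medians ≈ 21 and 39 months, typical of
  EGFR-TKI-treated NSCLC), OS hazards 0.6× those, censoring rate
  0.015/month.
* **Linearity.**  Intensities are linear in exposure time with a common
  intercept (200 a.u.); an optional saturation ceiling (off by default)
  clips the signal for stress-testing the slope fit.

What the generator does *not* emulate: spot morphology and image
segmentation, optical saturation nonlinearity, inter-array batch effects,
spatial artifacts, and non-exponential (e.g. cure-fraction) survival.
Passing recovery tests therefore demonstrate the correctness of the
analysis chain under the stated model, not robustness to those real-data
complications.

## Numerical and testing notes

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed reproduces byte-identical outputs, including the pipeline
  manifest (timestamps excluded).
* R² of a constant series is defined as 1 (the line fits exactly);
  degenerate Welch inputs (both groups constant) return p = 1 on equal
  means and p = 0 otherwise.
* Acceptance-style checks use problem sizes chosen for tight Monte Carlo
  error at interactive runtimes: 10,000 null simulations for Welch
  calibration, 2,000 for log-rank, 100 seeded studies for cluster
  recovery, 200 random ≤ 8-node graphs against the exhaustive centrality
  oracle, and exhaustive hypergeometric-oracle agreement for universes up
  to 25 plus a 2,000-configuration random sample up to 60.
* Zero-noise recovery of planted slopes is exact to < 10⁻¹⁵; QC recovery
  of the planted flat set is exact in the zero-noise limit (see QC above).

## Known limitations

* The consensus rule is strict intersection; a kinase missing from one
  source's coverage is never called, so source completeness bounds recall.
* The Mantel–Haenszel HR is biased toward the null with heavy event
  overlap; Cox regression is deliberately out of scope.
* Hierarchical-clustering cuts on exactly tied merge heights depend on the
  tie-break (smaller id first); real-valued data never ties in practice.
* The enrichment universe default (all genes in the collection) is a
  convention, not a recommendation; array-design universes are usually the
  better choice and are supported.
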