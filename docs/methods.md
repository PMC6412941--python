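# Methods

## Model and procedure

`modnmf` decomposes three binary relation layers that share an mRNA axis —
circRNA–mRNA co-expression, miRNA–mRNA targeting, pathway–mRNA membership —
with a single non-negative basis over the mRNAs. Writing the layers as
mRNA × entity matrices X_I, the objective is the unregularized summed
Frobenius error F(W, H) = Σ_I ‖X_I − W H_I‖². The W update is the standard
multiplicative rule applied to the column-concatenated problem
[X₁ X₂ X₃] ≈ W [H₁ H₂ H₃], so each full sweep (W, then every H_I) is
non-increasing in F and preserves non-negativity by construction.
Penalization weights are fixed at zero; there is no sparsity or graph
regularization.

Assumptions worth keeping in mind:

* The layers are binarized before factorization; all weighting of evidence
  (correlation strength, number of databases supporting a target) is
  deliberately discarded by the upstream thresholds.
* The shared basis forces modules to be consistent across layers: a
  component only scores high for a circRNA, a miRNA and a pathway
  simultaneously when they concentrate on the same mRNAs.
* The Frobenius residual of an unregularized fit decreases with K, so the
  "minimum-error" K selection effectively returns the top of the scanned
  range on noisy data. The per-K curve is always reported for elbow
  inspection, and a fixed `--k` bypasses the scan; on block-structured
  data the elbow at the true K is sharp (see the acceptance checks).

## Numerical choices

* Convergence: relative objective change < 1e−6 or 500 sweeps, whichever
  first. Multiplicative denominators are floored at 1e−12 (a floor, not an
  additive smoother, so updates are unbiased away from the boundary).
* Initialization is i.i.d. uniform(0, 1] — strictly positive, so no entry
  is locked at zero by the multiplicative form. Restart r of a fit seeded
  with s uses generator seed s + r; the winning restart's seed is recorded.
* The diagonal rescaling ambiguity (W D, D⁻¹ H_I) is fixed after fitting by
  normalizing W columns to unit sum with the scale moved into H_I, leaving
  every product W H_I unchanged; factorizations are therefore comparable
  across restarts.
* Z-scores use the sample standard deviation (ddof = 1); zero-variance
  columns/rows yield all-zero z rather than NaN, which keeps degenerate
  components out of the top ranks.
* Rank ties in top-k% selection are broken lexicographically by ID, and
  top-percent ties by the smaller percent, so member assignment is a pure
  function of its inputs.
* Pearson p-values use the two-sided t transform with n − 2 degrees of
  freedom; an exact permutation option exists for very small sample counts.
  Zero-variance features are skipped (correlation undefined), not scored 0.
* The rank test behind the miRNA screen is the unpaired Mann–Whitney
  rank-sum by default; the paired signed-rank variant is available via
  config when the design is actually paired. Fold changes add a
  pseudocount (default 0.25) to both group means; 0 restores the naive
  ratio.
* Enrichment uses the upper-tail hypergeometric test with BH adjustment
  across the sets tested in one call; the universe is the pipeline's
  common mRNA axis, not the whole annotation, because module genes are
  drawn from that space. Sets are intersected with the universe and kept
  when 3–2000 genes remain.

## Parameters

| parameter | default | meaning |
|---|---|---|
| fc_high / fc_low | 2 / 0.5 | fold-change bounds (case mean / control mean) |
| mirna_p_cut | 0.005 | rank-test cut, miRNA screen only |
| min_expressed_fraction | 0.5 | strict "> half of samples" expression filter |
| pcc_cut / pcc_p_cut | 0.4 / 0.05 | positive co-expression retention |
| min_degree | 4 | "more than three partners" per mRNA column |
| k_min..k_max / n_restarts | 5..20 / 100 | K scan and restarts |
| top_percent range | 1..10 | candidate member fractions per module |
| functional_min_terms | 10 | strict "> 10 enriched GO BP terms" screen |
| min_nto | 0.5 | inclusive NTO retention threshold |
| min_partners | 4 | strict "> 4 direct partners" candidate rule |

All thresholds that encode a strict "more than" are implemented strictly
(a feature expressed in exactly half the samples is dropped; 10 enriched
terms is not functional; 4 partners is not a candidate); the NTO threshold
is inclusive (a pair at exactly 0.5 is kept).

"Direct partners" of a circRNA pool across the functional modules it
belongs to and deduplicate by partner ID: known disease genes require a
within-module co-expression edge, known miRNAs and pathways require
NTO ≥ 0.5 with co-membership. Pathway partners are not restricted to a
known-pathway list unless one is supplied. A per-module counting mode is
available via config.

## Synthetic data: what it emulates and what it does not

The generator plants K_true blocks that span all four axes: an mRNA block
of 10% of the axis (30 of M = 300 by default) and matching entity blocks,
with within-block edge probability p_in = 0.8 against background
p_out = 0.02. One circRNA is planted as the disease candidate: it covers
its whole block, eight block mRNAs are declared known disease genes, and
every other circRNA's edges to those genes are removed — so candidate
status has a unique generative answer. Known miRNAs default to background
(blockless) miRNAs, exercising the miRNA-partner code path without
creating partners.

The GO-like annotation contains, per block, one broad near-block set and
twelve granular 3–4-gene subsets plus random noise sets. Granular sets
only become significant once a module's top-k% covers essentially all of
their genes, so the enriched-term count rises with coverage and the
top-percent choice lands on the percent that captures the block. This
mirrors the granularity of real GO BP (many small specific terms under a
broad one); with only broad sets the term count would saturate early and
the smaller-percent tie rule would truncate modules.

Expression matrices in the simulated bundle realize the same blocks as
latent-factor co-expression (15 case / 18 control samples, log-normal
noise σ = 0.3, latent weight 0.8, fold change 4 on planted differential
features, half up and half down), so the screen stages can be run on
them. The candidate's forced known-gene wiring, however, is exactly
expressible only at the relation-layer level — a correlation screen cannot
carve edges out of a shared latent factor — so the bundle's ready config
enters the pipeline at the relation matrices, and the serialized bundle
carries an explicit mRNA-universe file (edge lists cannot represent
zero-degree mRNAs that are still part of the axis).

What passing these tests does not show about real data: Bernoulli block
layers have no hub structure, overlapping modules, or database bias;
log-normal latent-factor expression has no count noise, batch effects or
dropout; and real annotation terms overlap hierarchically rather than
nesting cleanly inside modules. Recovery rates on the synthetic defaults
are therefore upper bounds on what to expect in practice.

## Problem sizes used in the checks

The test suite and the acceptance script run the default 3-block instance
(M = 300; 33 circRNAs, 27 miRNAs, 18 pathways; 20 restarts at the true K),
a 5-block K-scan instance (M = 300; 60/50/40 entities; K ∈ 2..8, 8
restarts — entity axes sized so block signal dominates the Bernoulli
noise), random joint problems with layers up to 20 × 15 for descent and
oracle checks, and 20-seed null simulations for the enrichment FDR. These
sizes keep every property measurable in seconds while leaving the planted
structure clearly identifiable.

## Known limitations

* K selection by raw residual is statistically naive (see above); the
  package reports the curve rather than second-guessing it.
* Binarization discards edge weights; a weighted or probabilistic variant
  would need a different objective.
* The enrichment module treats annotation sets as flat; no GO-graph
  propagation or redundancy reduction is attempted.
* ID harmonization (probe collapsing, symbol aliases) is out of scope;
  inputs are matched case-sensitively as given.
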