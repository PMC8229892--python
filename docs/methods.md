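# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions a maintainer needs to know.

## Synthetic data model

The generator (`lymphovelo.synthdata`) draws gene × cell spliced and unspliced
counts from a negative-binomial model, `Var = m + φ·m²` with a fixed
dispersion φ = 0.1 for both layers — the standard over-dispersion model for
deep plate-based counts without UMIs. Per cell, a relative expression profile
is built from a log-normal baseline (σ = 1) and modified multiplicatively:

* **Markers** — each subtype multiplies its marker genes (canonical LEC
  markers plus a 30-gene program at fold-change 4). Marker genes are clamped
  to a *low* baseline (0.04–0.08 × the median) outside their compartment,
  reflecting the near-absence of genes like *Ackr4* or *Mrc1* outside their
  anatomical niche; without this, "required-low" annotation rules have no
  contrast to work with.
* **DE effects** — per subtype, genes multiplied by 2^(log2FC) in the
  up-regulated condition (defaults: 10 up, 10 down per subtype at |log2FC| = 2).
* **Mitochondrial block** — ten dedicated genes whose summed count fraction
  per cell is Beta-distributed (mean 5%, concentration 60), with an optional
  block of planted high-mitochondria cells (default 5 cells at 50%), so the
  MAD and cap filters have real outliers to find.
* **Contaminants** — CD45(*Ptprc*)-expressing cells (~1% of their library from
  *Ptprc*); all other cells have exactly zero *Ptprc*, making the Cd45 filter's
  planted truth unambiguous.

The unspliced layer is generated at steady state: `E[U_gc] = γ_g · E[S_gc]`,
sharing the cell's depth factor with the spliced layer (both layers derive
from one library). γ_g is drawn log-uniformly on **[0.05, 0.5]** by default —
the range of unspliced/spliced read ratios typical of intron-containing
transcripts; the γ-recovery study deliberately widens this to [0.2, 2] to
probe recovery across an order of magnitude. Genes named in `ds_spec` have
their unspliced mean multiplied (default ×3) in the inflamed condition only,
and are assigned γ = 0.3 — a gene whose transcription is ramping up carries a
substantial unspliced pool, and a vanishing γ would make the planted shift
physically negligible.

Defaults are small (3 subtypes × 2 conditions × 60 cells, 1000 genes, mean
depth 30,000) so the full pipeline runs in seconds; these are the problem
sizes used throughout the test suite and the acceptance script. A single
integer seed drives one `numpy` Generator; regeneration is bit-identical.

**What the generator does not emulate:** gene–gene correlation beyond the
planted block structure, doublets, ambient RNA, batch effects beyond a scalar
depth shift, zero-inflation beyond the NB, or transcriptional bursting.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to every artefact of real data.

## Quality control

Cells are dropped when any of the following holds: library size or detected
feature count more than k = 3 MADs (scaled by 1.4826) from the median (both
sides); mitochondria-only fraction more than 3 MADs *above* the median;
library size outside a hard count window; combined mitochondrial + ribosomal
fraction above 10%; or any detected *Ptprc*. All verdicts are computed
independently and conjoined, so filter order cannot change the kept set. When
every value is identical the MAD is zero and no cell is flagged (documented
convention). The hard window is exposed as data-derived quantile bounds
(default 0.5%/99.5% of observed depth) rather than absolute read counts,
since the absolute window appropriate for one chemistry is meaningless for
another depth scale.

Normalization is total-count log-normalization,
`x = ln(1 + count/libsize × 10 000)`, applied to the spliced layer. A
count–depth quantile-regression normalization was deliberately not layered on
top: it adds heavy machinery orthogonal to everything downstream, which
consumes log-normalized values only. HVGs are ranked by dispersion
(variance/mean) standardized within 20 equal-occupancy mean-expression bins,
ties broken lexicographically. Cell-cycle scores use expression-matched
controls (default 25 bins, 50 controls per set gene, seeded); phase is G2M if
that score is largest and positive, S if the S score is, else G1. Cell-cycle
(or any) covariates are removed per gene by OLS with intercept; residuals are
standardized and clipped at ±10 (bounded outlier influence); residual SDs
below 1e−10 of the data scale are treated as exactly zero so numerically
perfect fits do not amplify float noise.

## Clustering and annotation

PCA is computed by SVD of the centered HVG submatrix; each component's sign is
fixed by making its largest-magnitude loading positive, so the embedding is
reproducible. The SNN graph connects cells whose (k+1)-neighborhoods
(k = 20, including self) share members, weighted by Jaccard overlap and pruned
below 1/15; communities are found with seeded Leiden optimization of the
RB-configuration quality at resolution 0.5 and relabeled by decreasing size.
k = 20 is a conventional default, declared in the config and not asserted
against anything. Batch structure, when declared, is handled by per-batch gene
centering before PCA — a deliberately light substitute for anchor-based
integration, adequate for the scalar depth shifts the generator produces.

Subtype calls are per cluster: each rule (e.g. ceiling = *Ackr4* high with
*Lyve1* low) scores `mean(high) − mean(low)` on the cluster-average normalized
expression; the argmax rule wins, "unassigned" if no score is positive. With
strong planted condition effects the partition may split each subtype by
condition; annotation then merges the split clusters under one subtype label,
which is what the downstream per-subtype analyses consume.

## Differential expression

Within a subtype, genes detected in ≥ `min_pct` (0.2) of either condition's
cells are tested with a two-sided Wilcoxon rank-sum on normalized values:
mid-ranks for ties; below 8 total observations the null distribution of U is
enumerated exactly over all group assignments, otherwise a normal
approximation with tie-corrected variance and 0.5 continuity correction is
used. log2FC is computed on de-logged means with pseudocount 1,
`log2((mean(expm1 x₁)+1)/(mean(expm1 x₂)+1))`, and the |log2FC| > 0.2
threshold is applied to both directions. Adjustment is Bonferroni over the
tested genes within the subtype (the convention of the tooling this mirrors);
Benjamini–Hochberg is available by flag. The cross-dataset comparison mode is
the same computation at `min_pct = 0.25`, log2FC > 0.25. Gene-set
over-representation uses the one-sided hypergeometric tail against a
user-supplied background, replacing any external ontology service.

## RNA velocity and DS genes

Genes are pre-filtered on raw counts: maximum cluster-mean ≥ 5 (spliced) and
≥ 1 (unspliced), optionally intersected with a protein-coding list. Counts are
pooled per cell with its 5 nearest neighbors in the PCA embedding of the
QC-passed data (the pooling space is a package choice; the convention this
follows does not pin it down) and each layer is size-normalized to its median
pooled depth. γ is fitted through the origin, `γ = max(0, ΣUS/ΣS²)`, on the
cells in the bottom-q and top-q spliced quantiles (q = 0.5 selects every
cell); Eq-exact velocities are `v = βU − γS` with β = 1. No intercept is
offered: the model has none and β is fixed.

For DS selection, the per-condition mean velocities of a gene within a subtype
are divided by the gene's mean pooled spliced abundance in that subtype before
the perpendicular-distance rule `d = |y − x|/√2 > 0.1` is applied. This
relative scaling is the package's resolution of a genuine ambiguity: on the
raw pooled-count scale, the null fluctuation of a mean velocity grows with the
gene's abundance, so no single absolute threshold can separate planted shifts
from noise across genes — whereas the relative velocity of a null gene
concentrates near zero (its SD scales as γ·√(4φ/n)) while a ×3 unspliced
excess sits at √2·γ regardless of abundance. The absolute scale remains
available (`spliced=None`). The signed side of the identity line is retained
to report the direction of the predicted change, and the per-cell residuals
`U − γS` with per-condition means provide the single-gene diagnostic
(positive inflamed mean = expected up-regulation). DS genes are intersected
with significant DE genes per subtype.

## Ligand–receptor screening

For each (pair, sender, receiver), the interaction mean is the average of the
ligand's mean expression in the sender and the receptor's mean in the
receiver; complexes score per cell as the minimum over members. The null is
built by reshuffling cluster labels (default n_perm = 1000, the reference
tool's convention); `p = (1 + #{null ≥ obs})/(1 + n_perm)` — the +1 smoothing
guarantees validity and avoids p = 0. Pairs whose ligand or receptor is
detected in fewer than 10% of the relevant cluster's cells get p = 1.
Clusters with fewer than 2 cells are excluded with a warning. Ortholog
conversion is a plain table lookup: one-to-one rows map directly, one-to-many
rows resolve to the uppercased symbol when present and are dropped (and
counted) otherwise.

## Pipeline and reproducibility

Stages communicate only through TSV/MTX artifacts in the output directory, so
any stage can be rerun in isolation; floating-point inputs (normalized
expression, embeddings) are recomputed deterministically from the filtered
counts rather than round-tripped through text. The global seed fans out to
per-stage seeds by stable hashing of the stage name; all tables are written
with a fixed float format, making reruns byte-identical. The manifest records
per-stage wall time and sha256 of every artifact and is written even when a
stage fails. Cross-run comparison reports, per subtype and direction, the
fraction of one run's significant DE genes found in the other's.

## Known limitations

Dynamical (likelihood-based) velocity models, velocity-field projections,
UMAP fidelity, doublet/ambient handling and pseudobulk DE are out of scope.
The clustering resolution is not adapted to discover minor LEC subsets beyond
the three modeled compartments. The permutation test's records share
permutations across cluster pairs, so their p-values are weakly dependent;
calibration statements are about the marginal rate.
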