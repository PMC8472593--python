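# Methods

## Model and assumptions

`scdosage` quantifies the gene dosage effect at single-cell resolution by
joining two patient-matched measurements from independent platforms: bulk
DNA-derived copy-number segments and a single-cell TPM expression matrix.
The core assumptions are

* **TPM comparability.** Columns of the expression matrix sum to a
  constant (10⁶), so a gene's proportion of a cell's transcriptome is
  comparable across cells of different depth. All statistics are computed
  on TPM; no further normalization or batch correction is applied.
* **Pooled relative expression.** For gene *g*, z = (x − μ_g)/σ_g with μ_g
  and σ_g taken over *all* cells of the dataset (all patients pooled).
  This asks "is this cell high for this gene relative to the cohort",
  which is the right contrast when copy-number states differ *between*
  patients. A per-patient pooling mode exists but is not the default.
* **Dropout masking, not imputation.** A zero TPM is treated as
  uninformative: the entry is masked and excluded from event calling. By
  default zeros still enter μ and σ (the moments are taken "across all
  cells"); `include_zeros_in_moments=False` excludes them from the
  moments too. Both modes are first-class because the right choice depends
  on how much of the zero mass is biological; the default follows the
  pooled-moment reading and is recorded in the output metadata.
* **Patient-level CNV.** Segments come from bulk DNA, so one copy-number
  state per (patient, gene) is broadcast to all of the patient's cells.
  No per-cell CNV inference is attempted — and deliberately none from the
  expression itself, which would make the concordance circular.
* **Strictness.** "Significant" means |z| strictly greater than the
  threshold; values exactly at the threshold are not called, so ties can
  never inflate event counts.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `z_threshold` | 1.96 | two-sided 5% point of N(0,1); P(\|Z\|>1.96) ≈ 0.04999 |
| `ddof` | 1 | sample standard deviation; configurable to 0 |
| `include_zeros_in_moments` | True | zeros enter μ, σ; only their z is discarded |
| `gain_min_cn` / `loss_max_cn` | 3.0 / 1.0 | GAIN at CN ≥ 3, LOSS at CN ≤ 1, diploid band in between; declared, not estimated |
| `min_overlap_bp` | 1 | any overlap assigns a segment (intersect default) |
| `min_cells` | 100 | recurrence cutoff in cells; scale to the cohort (≈ 5–7% of cells: 100 of ~1500, 6 of ~130) |
| `concordance_mode` | CNG_UP | gain+up; CNL_DOWN is implemented but off by default — in sparse, dropout-heavy data the down tail rarely clears −1.96 |
| MCODE | degree 2, node score cutoff 0.2, k-core 2, haircut on, fluff off | canonical parameterization |
| enrichment background | expression matrix genes | the measured universe; genome-wide backgrounds overstate significance |

Multi-segment genes take the segment with the larger overlap; ties prefer
the copy number farther from diploid, then the leftmost segment — a
deterministic, logged rule. Genes overlapping no segment are UNKNOWN,
distinct from NEUTRAL in output; neither produces events.

## Cell states and diversity

State scores are the mean unmasked z over a signature's genes (NaN when
every signature gene is masked in a cell); a within-cell average-rank
variant (`method="rank"`) is available when heavy z tails are a concern.
A sample-wise enrichment score (GSVA-style) is deliberately not
reimplemented: every downstream use (correlations between states, arrows
on an embedding) needs only a per-cell scalar, and the mean-z score is
transparent and exactly testable. The shipped panels are the published
breast-cancer marker lists for EMT/metastasis, stemness, pluripotency,
differentiation and proliferation; any extra panel (e.g. the genes of the
top concordance module, such as an SRP/ribosome cluster) can be supplied
as a GMT or dict and is scored identically.

Diversity treats a cell as an ecological plot: proportions p_i over the
cell's expressed genes give Shannon–Wiener H = −Σ p_i ln p_i (natural log,
max ln S) and Gini–Simpson D = 1 − Σ p_i² (max 1 − 1/S). The Simpson form
is implemented as 1 − Σ p_i² — the linear variant 1 − Σ p_i is identically
zero since proportions sum to one, so it cannot be the intended index.
Both are scale-invariant in the cell's total signal, hence insensitive to
the TPM constant.

envfit-style arrows regress a state score on the two centered embedding
axes by ordinary least squares; the arrow is the coefficient direction
scaled by √R². The embedding itself (t-SNE/UMAP) is consumed as an input —
computing it is not part of the contract.

## The simulator

`simulate_dataset` emulates the study design, not the sequencing process:

* genes laid out on a fixed grid (1 kb genes every 2 kb) across
  chromosomes; per patient, CNV segments placed disjointly on that grid,
  by default two CN = 4 gain segments of 16–18 kb per patient in regions
  distinct across patients, planting ~50 dosage genes in a
  3 × 200-cell cohort;
* log-normal expression: gene means ~ N(2.0, 1.0²) on the log scale,
  cell noise sd 0.4; genes in a segment have their log-mean shifted by
  β·ln(CN/2) (β = 1 ⇒ expression ∝ copy number; β = 0 is the null);
* dropout by a logistic in log expression, P(drop) =
  expit(1.7 − 1.5·ln x) — abundant transcripts almost never drop, weak
  ones mostly do — giving ~28–29% zeros overall, inside the ≤ 30% design
  band;
* TPM normalization after dropout, so columns sum to 10⁶ exactly;
* a sparse background interactome (G(n, 0.02)) with one ~90%-dense
  12-gene module planted among the gain genes, plus a truth table for
  exact scoring.

The noise scale was fixed by a power sketch before any end-to-end run:
with carrier fraction f = 1/3, pooled standardization bounds the mean
carrier z near √((1−f)/f) ≈ 1.41, so only the upper noise tail of carrier
cells exceeds 1.96 (~15% at fold 2). A 20-cell cutoff (10% of carriers)
is therefore recoverable and cutoffs near the carrier count itself are
not — the same geometry explains why real analyses keep `min_cells` well
below the cohort size.

What the simulator does **not** model: counts and UMI noise (a
negative-binomial count path exists via `tpm_from_counts` but is not the
default), cell types and clonal subpopulations, within-patient CNV
heterogeneity, correlated gene programs outside the planted module, and
batch effects. Passing recovery tests therefore show the pipeline's logic
is correct under its own assumptions, not that those assumptions hold in
any particular tissue.

Determinism: one `SeedSequence` per dataset; the segment plan, gene means,
network and each patient's cells draw from separately spawned streams, so
results are byte-identical for a given (config, seed).

## Numerical choices

* Per-gene moments use a two-pass compensated mean; rows whose standard
  deviation is below 10⁻¹² of the row's data scale are masked as constant
  (one-pass arithmetic can turn a constant gene into ±0.8 z-noise).
* Interval overlap is half-open on 0-based coordinates everywhere;
  1-based closed (SEG-style) inputs are converted once at read time, and
  conversion is idempotent.
* MCODE follows the canonical description: vertex weight = k × density of
  the highest k-core (k ≥ 2) of the closed neighborhood; greedy expansion
  admits neighbors with weight ≥ (1 − cutoff) × seed weight; complexes
  without a 2-core are discarded; haircut takes the module's 2-core.
  Output ordering (score, then size, then seed id) and all tie-breaks are
  deterministic. Being greedy, it is not a global density×size optimizer:
  triangle-free cycles are invisible to the weighting, and on arbitrary
  dense random graphs the top module can differ from the exhaustive
  optimum; on its design regime (a dense complex in a sparse background)
  it matches exhaustive search.
* Hypergeometric p-values use the survival function directly (no 1−CDF
  subtraction); BH is applied across all tested sets.
* Event tables and recurrence tables are fully sorted with documented
  tie-breaks, so repeated runs are byte-identical.

## Known limitations

* Gain/loss thresholds on absolute copy number ignore tumor ploidy and
  purity; pre-called states can be supplied instead
  (`mode="precalled_state"`).
* Recurrence has no permutation null — the cell-count cutoff is a hard
  filter, and its false-retention behavior is characterized empirically
  (β = 0 cohorts retain ~0% of genes at the default settings).
* The enrichment test assumes independent sampling of the query from the
  background, which recurrence-selected gene lists violate mildly.
* Mean-z state scores are not GSVA; absolute values are not comparable
  across datasets, only across cells within one run.
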