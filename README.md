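# scdosage

Concordant CNV–expression (gene dosage) analysis for matched bulk
copy-number calls and single-cell RNA-seq.

## The problem

Tumors carry recurrent copy-number variants (CNVs), and a gene sitting in an
amplified segment is expected to be transcribed more — the *gene dosage
effect*. Bulk RNA-seq averages this signal over mixed cell populations;
single-cell RNA-seq resolves it per cell but is riddled with dropouts
(zeros that reflect capture failure, not silence). `scdosage` is for
analysts with a patient-matched pair of data types — bulk DNA-derived CNV
segments and a single-cell TPM expression matrix from the same patients —
who want the genes whose copy-number gains coincide with significant
up-regulation across many individual cells, and a functional
characterization of those genes.

## The method

1. **Relative expression.** Each gene's TPM row is standardized across all
   cells: `z = (x − μ) / σ`. Entries with zero TPM are masked (dropout),
   and genes with σ = 0 carry no signal and are masked entirely.
2. **CNV mapping.** Each patient's CNV segments (0-based half-open
   intervals) are intersected with gene coordinates; a gene takes the
   per-patient copy-number state of its best-overlapping segment
   (GAIN at CN ≥ 3, LOSS at CN ≤ 1 by default).
3. **Concordant events.** A (gene, cell) pair is an event when the gene is
   non-neutral in the cell's patient and the z entry is unmasked; it is
   *informative* when |z| > 1.96 (the two-sided 5% normal point) and
   *CNG-UP concordant* when a gain meets z > 1.96. Genes are ranked by the
   number of distinct cells with a concordant event and kept above a hard
   cutoff (`min_cells`, e.g. 100 for a ~1500-cell cohort).
4. **Characterization.** The retained genes are clustered into dense
   modules on a user-supplied interaction network (a faithful MCODE
   reimplementation: k-core × density vertex weights, greedy seeded
   expansion, haircut), tested for gene-set over-representation
   (hypergeometric upper tail + Benjamini–Hochberg against GMT sets), and
   used as per-cell signatures alongside published cell-state marker
   panels (EMT/metastasis, stemness, pluripotency, differentiation,
   proliferation). Per-cell transcriptome heterogeneity is summarized by
   the Shannon–Wiener index H = −Σ pᵢ ln pᵢ and the Gini–Simpson index
   D = 1 − Σ pᵢ², and state scores can be projected envfit-style onto a
   2-D embedding.

A fully reproducible simulator generates matched synthetic cohorts with
planted dosage effects, expression-dependent dropout and a planted dense
network module, so every stage can be validated against known truth.

## Worked example

```python
import scdosage as sd

ds = sd.simulate_dataset(seed=1)            # 3 patients x 200 cells, 1000 genes
z = sd.compute_zscores(ds.expression)
print(sd.entry_census(z))
# EntryCensus(total=600000, masked=170294, retained=429706)

assignment = sd.classify_cnv_state(sd.overlap_genes(ds.annotation, ds.segments))
events = sd.call_events(z, assignment, ds.metadata)
print(sd.event_census(events))
# EventCensus(total=8904, informative=1421, non_informative=7483, n_cells=600, n_genes=54)

cng_up = sd.filter_concordant(events, "CNG_UP")
table = sd.recurrence_table(cng_up, min_cells=20)
print(table.head(3))
#  gene_id  n_cells  n_events patients_hit   mean_z
#    G0582       39        39         (P1) 2.845049
#    G0577       34        34         (P1) 2.635071
#    G0007       33        33         (P3) 2.731881

print(sd.evaluate_recovery(table, ds))
# RecoveryMetrics(precision=1.0, recall=0.9629..., f1=0.9811..., n_retained=52, n_truth=54)

modules = sd.mcode_find_modules(ds.network, query=set(table["gene_id"]))
print(len(modules[0].members), modules[0].score)   # 12  11.27 — the planted module
```

Reading: 28% of the 600,000 z entries are masked dropouts; 8,904
(gene, cell) pairs fall in non-neutral segments, 1,421 of them significant;
52 genes recur in ≥ 20 cells, all of them truly planted in CN = 4 gain
segments (precision 1.0), and MCODE pulls out the planted 12-gene complex
as the top-scoring module.

The same analysis runs from the shell:

```bash
scdosage simulate --seed 1 --out cohort/
scdosage run --config pipeline.yaml       # paths + parameters in YAML
```

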