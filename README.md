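# tammune

Immunophenotyping of tumors from the differentiation of tumor-associated
monocytes/macrophages (TAMM).

In head-and-neck squamous cell carcinoma (and solid tumors generally),
the level of immune infiltration — the "immune hot" vs "immune cold"
phenotype — predicts both prognosis and response to immune checkpoint
blockade (ICB). This package implements, as a tested and reusable
pipeline, an analysis strategy that traces that phenotype back to TAMM
differentiation:

1. **Differentiation signatures** (`preprocess`, `trajectory`): QC-filter
   single-cell counts (genes in < 3 cells; cells with > 4,500 or < 200
   detected genes or > 10% mitochondrial transcripts), contrast the early
   (monocyte) and late (mature macrophage) archetypes by per-gene
   Wilcoxon rank-sum tests, and call genes with |log2FC| > 1.3 at
   Benjamini–Hochberg FDR < 0.05 the early/late differentiation
   signatures. A diffusion map orders cells along the differentiation
   axis; pseudotime is diffusion distance from a root cell.
2. **Copy-number estimation** (`cnv`): relative copy number of cell *k*
   at gene position *i* is the 101-gene window mean
   CNV<sub>k</sub>(i) = Σ<sub>j=i−50</sub><sup>i+50</sup> E<sub>k</sub>(O<sub>j</sub>)/101
   of reference-centred log2 expression along the genomic gene order,
   with gains/losses called at ±0.2.
3. **Immune composition** (`deconv`): bulk tumors are modelled as linear
   mixtures over an LM22-style basis; per-sample fractions solve
   min<sub>f≥0</sub> ‖B·f − y‖₂, renormalized to the simplex.
4. **Immune subtypes** (`subtype`): Monti consensus clustering
   (subsampled Ward linkage on unsquared Euclidean distances) splits
   samples k=2 on the 22 immune fractions into infiltrated (A) vs cold
   (B), then k=3 on z-scored early-signature expression refines A into
   A1/A2/A3 by decreasing infiltration. Kaplan–Meier/log-rank compares
   survival.
5. **Hub genes** (`network`): nodes of the DEG interaction network are
   ranked by degree, eigenvector centrality, shortest-path betweenness
   C<sub>spb</sub>(v) = Σ<sub>s≠v≠t</sub> σ<sub>st</sub>(v)/σ<sub>st</sub>
   and eccentricity centrality 1/max<sub>w</sub> dist(v,w); the top 40 by
   degree, intersected over the top 20 by eigenvector and by betweenness,
   are the hub genes (the route by which CXCL9/10/11 and CCL5 emerge).
6. **Hot/cold grade** (`score`): ssGSEA (rank-weighted running sum,
   α = 0.25) of the four-chemokine set {CXCL9, CXCL10, CXCL11, CCL5},
   median-split into immune hot/cold; fold change is the hot-minus-cold
   difference of mean immune scores; TMB is mutations per megabase.
7. **ICB response** (`predict`): a [7, 20, 5, 1] neural network —
   sigmoid 1/(1+e<sup>−x</sup>) at every layer, dropout on both hidden
   layers, mean binary cross-entropy (1/N)Σ −(y·log p + (1−y)·log(1−p)) —
   predicts response (CR/PR = 1 vs SD/PD = 0) from the four chemokine
   grades plus the M1-macrophage, CD8 T and activated-memory CD4 T
   fractions, and is evaluated by ROC/AUC and confusion matrix.

Because the original cohorts are external accessions, the `synth` module
generates synthetic stand-ins with planted ground truth (differentiation
axis, copy-number segments, mixing fractions, hot/cold effect, survival
hazards, response model, hub module) so every stage is exercised as a
recovery problem.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts and write tables to `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_qc_and_signatures.py
python analysis/03_trajectory_and_cnv.py
python analysis/04_deconvolve_and_subtype.py
python analysis/05_hot_cold_and_hubs.py
python analysis/06_predict_response.py
```

Output from a run:

```
QC: removed 0 genes and 11 cells -> 600 x 489
early signature: 40 genes called, 40/40 planted markers recovered (100%)
pseudotime vs planted latent time: Spearman rho = 0.861 (489 cells)
planted gain: 100% of interior positions called gain; mean log2 ratio 0.94
deconvolution: mean per-type Pearson r vs truth = 0.998
two-step subtype sizes {'B': 100, 'A1': 34, 'A3': 33, 'A2': 33}, best-permutation agreement with planted truth 100%
survival A vs B: log-rank chi2 = 16.71, p = 4.36e-05
hot/cold split recovers planted phenotype on 100% of samples
fold change hot - cold: chemokine grade 0.853, summed immune score 0.420
hub screen: 16 hubs, 12/12 planted module members
train AUC = 1.000 ... test AUC = 1.000
```

Reading: the QC thresholds drop the 11 low-quality/mito-heavy cells; the
signature split recovers every planted marker; pseudotime tracks the
planted differentiation axis (rho 0.86) with early markers falling and
late markers rising along it; the 150-gene planted gain is called at
every interior window position near its true +1 log2 ratio; estimated
fractions match the planted mixtures (r ≈ 1 at this noise level); the
two-step classifier reproduces the planted A1/A2/A3/B structure, whose
infiltrated group survives longer; the chemokine grade separates hot
from cold exactly and the hub screen finds the entire planted module;
the response network separates planted responders perfectly at this
effect size (real cohorts are far noisier — see `docs/methods.md`).

Library use is one import away from the same results, e.g.:

```python
from tammune import synth, deconv
cohort = synth.gen_bulk_cohort(synth.BulkSimConfig(n_samples=100, seed=1))
fractions = deconv.deconvolve(cohort.expression, cohort.basis)
```

A `tammune` console script exposes each stage
(`tammune simulate|qc|deconvolve|subtype|score|network|cnv|trajectory|predict --help`).

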