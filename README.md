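# netconverge

Cross-disease network convergence analysis: do two complex diseases share
a molecular neighborhood, and can that shared neighborhood be turned into
a blood biomarker?

`netconverge` is a Python library (with a thin CLI) for the full chain:

1. **Network prioritization** — random walk with restart (RWR) over a
   weighted functional linkage network (FLN), seeded with each disease's
   confirmed genes. The fixed point of
   `p = (1 - α) W p + α p0` (default restart probability α = 0.5, `W`
   column-stochastic by weighted degree) scores every gene's proximity to
   the seed set; candidates are the non-seed first neighbors of the seeds.
2. **Convergence** — exact intersection of the two diseases' candidate
   neighborhoods (Venn decomposition), then a union-seeded ranking of the
   shared genes.
3. **Expression signature** — per-study pooled two-sample *t*-tests on
   log2 expression, Benjamini–Hochberg adjustment at FDR 0.05 within each
   comparison, and a direction-annotated intersection of significant genes
   across studies (`concordant_up` = up-regulated everywhere).
4. **Biomarker evaluation** — ΔΔCt relative quantification of a qPCR
   target against a reference gene (fold change `2^(-ΔΔCt)`, healthy
   controls as calibrator), group testing on the ΔCt scale, covariate
   screening/adjustment, and ROC analysis with Mann–Whitney AUC and
   Hanley–McNeil 95% CI.

A first-class synthetic-data module generates networks with planted
disease modules, seeded training sets, expression studies with planted
shared signatures, and qPCR cohorts with planted shifts — so every stage
is testable against known ground truth. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

`examples/05_full_pipeline.py` generates the default synthetic study-set
(seed 17) and runs all four stages:

```
convergence: {'a_only': 63, 'shared': 38, 'b_only': 50, 'a_total': 101, 'b_total': 88, 'rank_mode': 'union'}
signature intersection: ['G0030', 'G0393']
network-supported concordant-up biomarker: ['G0030'] (planted: G0030)
discovery: fold change 5.26 +/- 0.54, AUC 0.92 (95% CI 0.87-0.98)
replication: fold change 5.59 +/- 0.52, AUC 0.94 (95% CI 0.90-0.99)
```

Reading the output: disease A's seeds have 101 candidate neighbors,
disease B's 88, and 38 genes sit in both neighborhoods. Two genes are
differentially expressed in every study; only `G0030` moves up in all of
them *and* lies in the shared network neighborhood — it is exactly the
biomarker gene the generator planted. In both simulated qPCR cohorts
(planted five-fold up-regulation) the estimated case fold change is ~5
with diagnostic accuracy (AUC) ~0.9.

The other examples each exercise one capability and print a line on what
the numbers mean:

```bash
python examples/01_network_prioritization.py   # RWR candidate ranking
python examples/02_cross_disease_convergence.py
python examples/03_expression_signature.py
python examples/04_qpcr_biomarker.py
```

## Command line

```bash
netconverge simulate --preset paperlike --seed 17 --out-dir sim/
netconverge prioritize --network sim/fln.tsv --seeds sim/seeds_a.txt --alpha 0.5 --out ranked_a.tsv
netconverge converge --ranked-a ranked_a.tsv --ranked-b ranked_b.tsv \
    --network sim/fln.tsv --seeds-a sim/seeds_a.txt --seeds-b sim/seeds_b.txt --out shared.tsv
netconverge signature --expression sim/expr_glucose.tsv --annotation sim/groups_glucose.tsv \
    --expression sim/expr_pd_blood_1.tsv --annotation sim/groups_pd_blood_1.tsv --out-dir sig/
netconverge biomarker --qpcr sim/qpcr_discovery.tsv --out-dir bio/
netconverge run-all --config pipeline.yaml
```

All inputs and outputs are plain TSV/JSON: edge tables
(`gene_a  gene_b  weight`), one-gene-per-line seed lists, genes × samples
expression matrices with a (sample, group) annotation table, and Ct tables
(`sample  group  target_ct  reference_ct` plus optional covariates).

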