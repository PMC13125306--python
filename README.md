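# clonecnv

Expression-based CNV clonal-evolution analysis for multi-sample tumor
cohorts (single-cell and spatial transcriptomics): infer per-cell relative
CNV profiles from genome-ordered expression, score CNV burden, classify
malignant cells, call clone-level CNV events with an HMM, reconstruct clone
phylogenies under the irreversibility assumption, compare DCIS vs IDC
burden, and stratify survival by a maximally selected expression cutpoint.
Everything is exercisable on synthetic cohorts with planted ground truth.

## Modules

| module | what it does |
| --- | --- |
| `clonecnv.sim` | synthetic cohorts with planted clonal CNV architecture, spatial sections, marker cohorts, survival fixtures |
| `clonecnv.qc` | barcode QC filters, log normalization, vst HVG selection, PCA + SNN/Leiden clustering, marker annotation, module scores |
| `clonecnv.cnv` | reference centering (cutoff 0.1), genome smoothing, dynamic 1.5-SD denoising, [-1, 1] rescale, CNV scores, 3-state HMM region calls, clone consensus events |
| `clonecnv.malignant` | exact 1-D k-means (k = 3) over CNV scores; top-mean cluster labelled tumor |
| `clonecnv.clonetree` | clone-tree reconstruction from event sets, branch lengths `bk = 10·log2(ΔZ)`, node diameters `dl = √p`, Newick + SVG output |
| `clonecnv.compare` | Venn set decompositions, exact/asymptotic Wilcoxon, correlation, Kaplan-Meier + log-rank, best survival cutpoint (with permutation-adjusted p), univariate Cox |
| `clonecnv.io` | 10x MTX triple, gene-position/annotation/event TSVs, BED-like region calls, truth JSON |

## CLI

```sh
clonecnv simulate --out cohort/ --seed 1            # synthetic cohort + truth
clonecnv qc --in cohort/ --out qc/ --min-umis 200 --min-genes 200 \
    --max-genes 6000 --max-mito 0.2
clonecnv infer --in qc/ --out cnv/ --cutoff 0.1 --denoise-sd 1.5 --window 101
clonecnv classify --scores cnv/scores.tsv --out calls.tsv --k 3
clonecnv tree --events cnv/events.tsv --out tree/ --scale 10 --floor 2
clonecnv compare venn --sets s1.txt --sets s2.txt --out venn.json
clonecnv compare survival --survival surv.tsv --out surv.json
clonecnv pipeline --out run/ --seed 1               # everything, one seed
```

`clonecnv pipeline` is byte-for-byte deterministic for a fixed seed.

## Notes

- The synthetic noise model (negative binomial counts, dosage multiplier =
  copy/2 with a 0.05 floor for homozygous deletions) is a stand-in: the
  analyses this package implements were originally run on real accessions
  with no stated generative model.
- Batch integration is a deliberate simplification: per-batch mean-centering
  of principal components (`qc.center_batches`) instead of a full
  mixture-model integration.
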