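# drugscan

Predicting how strongly a drug inhibits a cancer cell line — its ln(IC50),
the natural log of the half-maximal inhibitory concentration in micromolar —
from two binary inputs:

* a **genomic fingerprint**: presence/absence of somatic mutations over a
  fixed (gene, genomic position) vocabulary restricted to a cancer-gene
  whitelist;
* a **molecular fingerprint**: 3,072 bits formed by concatenating three
  1,024-bit hashed substructure fingerprints of the drug's SMILES
  (path-based with bond orders, extended feature-based circular, and
  path-based ignoring bond orders).

The regressor is an **ensemble of five convolutional networks**. Four use a
dual-convergence layout: the genomic and molecular blocks are convolved in
separate 1-D branches, merged ("virtual docking"), and processed further;
the fifth convolves the whole concatenated input as one entity. The
reported prediction is the arithmetic member mean,

    f(x) = (1/5) * sum_m f_m(x),

and accuracy is assessed with R² = 1 − Σ(yᵢ−fᵢ)²/Σ(yᵢ−ȳ)², RMSE, Pearson r,
and AUROC for detecting *sensitive* pairs, defined by ln(IC50) < −2
(≈ 0.135 µM).

Around the model the package provides the full working pipeline: dataset
curation filters (cancer types with ≥ 10 cell lines; screening drugs with a
registered structure and ≤ 1000 g/mol; approved drugs of 200–650 g/mol,
single-fragment, organic), cancer-type-stratified splits and k-fold CV,
per-type/cell-line/drug evaluation reports, random-forest and SVM baselines,
an in-silico **drug-repurposing screen** (a cancer type is called sensitive
to a drug when ≥ 10 % of its cell lines respond; drugs hitting > 90 % of
types are flagged pan-cytotoxic and excluded), and a synthetic-data
generator that emulates the shape of CCLP/GDSC-style corpora with a planted,
analytically tractable mutation × drug response signal.

It is aimed at computational pharmacogenomics researchers who want a
CPU-scale, fully reproducible re-implementation of this class of model to
probe, extend, or benchmark against.

## Worked example

```python
import numpy as np
from drugscan import DrugResponseEnsemble, evaluate, stratified_split, SplitSpec
from drugscan.synthetic import make_benchmark

bench = make_benchmark(seed=1)                  # 200 cell lines x 30 drugs
train, test = stratified_split(bench.instances, SplitSpec(test_fraction=0.05, seed=1))

ens = DrugResponseEnsemble(genomic_width=bench.genomic_width,
                           batch_size=256, random_state=1)
ens.fit(bench.X[train.index], bench.y[train.index])

pred = ens.predict(bench.X[test.index])
report = evaluate(bench.y[test.index], pred)
print(f"R2={report.r2:.3f} RMSE={report.rmse:.3f} AUROC={report.auroc:.3f} "
      f"(ceiling {bench.ceiling:.3f})")
```

Output (a few minutes on one CPU):

```
R2=0.944 RMSE=0.724 AUROC=0.970 (ceiling 0.973)
```

R2 is the held-out coefficient of determination of the ensemble mean; the
*ceiling* is the best R² any predictor could reach given the simulation's
noise level, Var(signal)/(Var(signal)+σ²) — the gap to it is the learning
error. RMSE is in ln(IC50) units, and AUROC scores how well low predictions
rank the truly sensitive (ln IC50 < −2) pairs first.

The same pipeline is scriptable from the shell:

```bash
drugscan simulate --out-dir run/sim --seed 1
drugscan curate   --cell-lines run/sim/cell_lines.csv --drugs run/sim/drugs.csv \
                  --assays run/sim/assays.csv --out-dir run/cur
drugscan encode   --mutations run/sim/mutations.tsv --drugs run/cur/drugs_retained.csv \
                  --cell-lines run/cur/cell_lines_retained.csv --out-dir run/enc
drugscan train    --instances run/cur/instances.csv --genomic-fp run/enc/genomic_fp.csv.gz \
                  --drug-fp run/enc/drug_fp.csv.gz --out-dir run/trn --seed 1
drugscan evaluate --predictions run/trn/predictions_test.csv --out-dir run/ev
drugscan scan     --model run/trn/ensemble.npz --drugs run/sim/drugs.csv \
                  --genomic-fp run/enc/genomic_fp.csv.gz \
                  --cell-lines run/cur/cell_lines_retained.csv --out-dir run/scn
```

Every command writes a JSON manifest (input hashes, seeds, thresholds) next
to its artifacts.

## Layout

```
src/drugscan/
  fingerprints.py   genomic + molecular encoders (sklearn transformers)
  curation.py       dataset filters and instance assembly
  models.py         the five CNN configs, member/ensemble estimators
  _nn.py            minimal numpy reverse-mode engine (conv/pool/dropout/dense/Adam)
  evaluation.py     metrics, stratified split, k-fold CV, centric reports, baselines
  repurposing.py    sensitivity calls and library screening
  synthetic.py      planted-signal corpus generator
  cli.py            the `drugscan` command
  configs/models.yaml   the five architectures, scaled + full profiles
docs/methods.md     model, assumptions, parameter choices, limitations
```
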