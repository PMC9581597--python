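# mifquant

Quantitative analysis of multiplexed immunofluorescence (mIF) images:
nuclei-segmentation benchmarking, cyclic-round registration, per-cell
marker classification, and immune-phenotype profiling — built around the
nine-parameter conventional type 1 dendritic cell (cDC1) panel used to
compare tumor infiltrates (identity: CD11c, HLA-DR, BDCA-3; checkpoint:
CD40, PD-L1; function: IL-12, CD86, IDO).

It is aimed at imaging groups that segment nuclei with external tools
(Stardist, Cellpose, U-Net variants, or manual annotation), need a
rigorous, scriptable way to benchmark those masks and turn marker
channels into per-cell calls and population statistics, and want every
stage testable without patient data: a synthetic field generator produces
realistic multiplexed fields with complete per-cell ground truth.

## The core quantities

Segmentation quality is scored by matching predicted to ground-truth
instances at an IoU threshold *T*,

```
IoU = |I_P ∩ I_GT| / |I_P ∪ I_GT|,
```

counting matched predictions (TP), unmatched predictions (FP) and
unmatched ground-truth cells (FN), then sweeping *T* from 0.1 to 0.7:

```
Precision = TP/(TP+FP)          Recall = TP/(TP+FN)
Average Precision = TP/(TP+FN+FP)
F1 = 2·Precision·Recall/(Precision+Recall)
```

Marker positivity per nucleus comes either from a pixel-fraction
threshold over the nucleus and its perinuclear ring, or from a few-shot
logistic regression trained on 5–10 analyst-chosen positive and negative
exemplar nuclei.  Calls compose into gates (cDC1 = CD11c⁺HLA-DR⁺BDCA-3⁺,
CD40/PD-L1 subsets, IL-12/CD86/IDO combinations); abundances are
percentages of all nucleated cells, subset fractions are percentages of
their parent population, and expression levels are background-normalised
mean fluorescence intensities (MFI) on a log10 scale with an Otsu
high/low split.  Cyclic staining rounds are aligned with a 2D rigid
transform estimated from the nuclear channel by a coarse-to-fine rotation
search with phase-correlation translation solving.

See `docs/methods.md` for the full model description, parameter defaults,
and limitations.

## Worked example

Run the complete synthetic workflow — simulate a 1,600-cell two-round
field, register the rounds, segment nuclei with the classical baseline,
benchmark against the known masks, classify all eight markers few-shot,
and gate phenotypes:

```python
from mifquant.io import PipelineConfig
from mifquant.pipeline import run_pipeline

cfg = PipelineConfig(n_cells=1600, field_shape=(1024, 1024), seed=1)
res = run_pipeline(cfg, "example_out")

pops = res["abundances"].set_index("population")
print(round(pops.loc["cDC1", "pct_of_nucleated"], 2))
print(res["subset_fractions"].round(2).to_string(index=False))
print(res["seg_metrics"].query("threshold == 0.5").round(3).to_string(index=False))
```

prints (about 17 s on one CPU):

```
15.46
          subset  count  pct_of_cdc1
cDC1/CD40+PD-L1+     54        22.88
cDC1/CD40+PD-L1-     54        22.88
cDC1/CD40-PD-L1+     77        32.63
cDC1/CD40-PD-L1-     51        21.61
 threshold   tp  fp  fn  precision  recall  average_precision    f1
       0.5 1491  36 109      0.976   0.932              0.911 0.954
```

Reading: 15.46% of nucleated cells were called cDC1 (the generator's true
value in this field is 16.88%, drawn around a mixture fraction of 17%);
within cDC1s the CD40⁻PD-L1⁺ subset is the largest at 32.6% (mixture:
32.5%); and the baseline watershed segmentation recovered 1,491 of 1,600
nuclei at IoU > 0.5 (Average Precision 0.911).  The run log
(`example_out/log.yaml`) also records the estimated inter-round transform
— here rotation 1.500°, translation (4.03, −2.96) px against a true
displacement of 1.5° and (4, −3) px, NCC quality 0.98.

The same stages are available as CLI subcommands:

```sh
mifquant simulate --n-cells 1600 --seed 1 --out field/
mifquant segment field/field.tif --out pred.tif
mifquant benchmark-seg --gt field/labels.tif --pred pred.tif --out bench/
mifquant classify field/field.tif pred.tif --truth field/truth.csv --out cells/
mifquant profile cells/cells.csv --out profile/
mifquant report values.csv --design three_group --out stats/
```

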