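# lpsmono

A differential-expression pipeline for **paired two-color spotted cDNA
microarray** studies of human monocytes challenged with endotoxin
(lipopolysaccharide, LPS) in vivo. In this design, RNA drawn from the same
subject before (T = 0) and after (T = 1 h or T = 4 h) an infusion is
labelled with two fluorescent dyes and co-hybridized on one slide, so every
array directly measures a within-subject post/pre expression ratio. The
package is aimed at analysts who need a transparent, fully testable
re-implementation of this classic analysis: scanner-level spot QC,
mixed-effects differential-expression calling, gene-list overlap analysis,
and comparative-Ct (ΔΔCt) qPCR validation.

## The model

For gene *g*, array *a* and duplicate spot *r*, the normalized log-ratio
M = log₂(post/pre) is modelled as

```
M_gar = μ_g + u_a + ε_gar ,   u_a ~ N(0, τ²) ,   ε_gar ~ N(0, σ²)
```

— a per-gene linear mixed model with a random array effect. With duplicate
spots averaged per array (the default), inference on μ_g reduces to the
one-sample problem on per-array means with variance σ_B² = τ² + σ²/r.
Gene-wise variances are moderated by empirical Bayes with a scaled
inverse-χ² prior (prior df d₀ = 4), giving a moderated t with d + d₀
degrees of freedom; the posterior probability of differential expression is
the logistic transform of the Lönnstedt–Speed log-odds (B-statistic) with a
prior DE proportion p = 0.01; multiplicity is controlled by
Benjamini–Hochberg FDR. A gene is **called** differentially expressed when

* q-value < 0.005,
* posterior probability > 0.95,
* fold change > 2 (or < 0.5), and
* the ≥2-fold change appears in ≥ 70 % of valid arrays.

Upstream, spots must pass five criteria on **both** channels — unflagged,
|median − mean|/median < 0.1, saturation < 20 %, mean/SD > 2, and > 90 % /
> 80 % of pixels above background + 1 SD / + 2 SD — and a gene needs valid
measurements on ≥ 50 % of arrays with a consistent direction of regulation.
Samples enter only with FACS purity > 80 %.

Because the study's raw hybridizations are not redistributable, the package
ships a synthetic-data generator that emulates the paired design (10 LPS
arrays from 5 subjects plus saline controls, duplicate spots, dye bias,
intensity-dependent structure, injected QC violations) with a known truth
table, so the whole pipeline is testable end to end. The published DE gene
tables for both timepoints are packaged verbatim for the worked examples.

## Worked example

A complete synthetic run — simulate, gate samples, spot QC, ratio matrix,
normalization, mixed-model fit, moderation, calls, truth comparison, qPCR
validation:

```python
from lpsmono.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(output_dir="demo_run", seed=1))
print(report["qc"])          # {'mean_pass_fraction': 0.877}
print(report["de_LPS"])      # {'n_called': 94, 'n_up': 84, 'n_down': 10}
print(report["de_saline"])   # {'n_called': 0, 'n_up': 0, 'n_down': 0}
print(report["recovery"])    # {'n_true_de': 100, 'n_called': 94,
                             #  'sensitivity': 0.94, 'observed_fdr': 0.0}
print(report["qpcr_concordance"])  # '8 of 8'
```

Reading: ~88 % of synthetic spots pass the five QC criteria; of 100 spiked
genes the call gates recover 94 with no false positives; the saline arm
(no true signal) yields zero calls; and the ΔΔCt fold changes of the top
called genes agree in direction with the array calls for all 8 genes
tested. Outputs (per-gene results, DE lists, QC summary, resolved config,
`report.json`) land in `demo_run/`.

The same stages are available as a CLI:

```sh
lpsmono simulate --out sim --seed 1
lpsmono qc --gpr-dir sim --out qc.tsv
lpsmono overlap --out candidates.tsv   # published tables vs in-vitro list
lpsmono run-all --seed 1 --out demo_run
```

`lpsmono overlap` reproduces the candidate-gene analysis on the packaged
tables: the two timepoint lists (11 and 28 genes) share exactly one gene,
and intersecting their union with an in-vitro DE gene list yields the six
candidate genes.

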