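# pioneerkit

Layered multi-omics analysis of pioneer transcription-factor activity at
its genomic binding sites.

Pioneer transcription factors (p53 being the model case) can bind closed,
nucleosome-occupied chromatin and initiate its opening, but they succeed in
driving transcription at only a minority of their binding sites. This
package provides, for computational epigenomics researchers, a tested and
reusable implementation of the integrative analysis that dissects that
activity into independent functional layers:

* **Accessibility transitions** — classifying each binding site as
  constitutively open, opened upon activation, constitutively closed, or
  putatively closed, from accessibility (ATAC-type) peaks in control and
  treated conditions;
* **Chromatin-state stratification** — collapsing an 18-state segmentation
  to promoter / enhancer / transcription / quiescent;
* **Nucleosome profiling** — occupancy tracks from mono-nucleosome-sized
  fragments (180–240 bp), anchored profiles at response-element (RE)
  centers, and eviction / repositioning scores for the treatment contrast;
* **Transcription initiation** — stranded 5′-end (CTSS) coverage, summit
  calling, TSS-status classification (induced / uninduced / none at
  log₂FC 0.5), and per-region-normalized initiation-density profiles that
  resolve the characteristic modes at the RE and ~50 bp away;
* **Occupancy→transcription response** — a four-parameter logistic
  y = a + (b − a) / (1 + exp(−(log₁₀x − x₀)/k)) of local initiation change
  on binding-signal strength (CPM), whose midpoint x₀ estimates the
  occupancy threshold for productive binding;
* **Differential signal** — a simplified negative-binomial Wald test with
  median-of-ratios normalization and Benjamini–Hochberg FDR
  (log₂FC > 1 / < −1 and FDR < 0.1 by default);
* **Enhancer–gene linking** — distal (≥ 2.5 kb) interaction-pair filtering
  and candidate target-gene selection from induced, factor-bound enhancer
  TSSs (TSS log₂FC > 1, FDR < 0.1; gene log₂FC > 0.5, FDR < 0.05).

A ground-truthed synthetic-data generator reproduces the signal structure
these analyses assume (graded occupancy, RE classes, nucleosome-depleted
regions with positioned flanking nucleosomes, bimodal initiation offsets at
{0, +50} bp, negative-binomial replicate noise), so the full pipeline is
testable end to end without any external data. See `docs/methods.md` for
models, parameters and limitations.

## Worked example

Simulate 200 binding sites and run every stage:

```python
from pioneerkit import PipelineConfig, SimulationConfig, run_all

cfg = PipelineConfig(
    outdir="example_out", seed=7,
    simulate=SimulationConfig(n_sites=200, depth=50_000, seed=7),
)
result = run_all(cfg)
s = result["summary"]
print("transitions:", s["layers"]["counts"]["transition"])
print("sigmoid x0 (log10 CPM): %.2f  threshold %.0f CPM" %
      (s["sigmoid"]["x0"], s["sigmoid"]["occupancy_threshold_cpm"]))
print("eviction (opened): %.2f  (const. closed): %.2f" %
      (s["nucleosome"]["opened"]["eviction_score"],
       s["nucleosome"]["constitutively_closed"]["eviction_score"]))
print("treated initiation modes (bp from RE):", s["density"]["treated"]["modes_bp"])
```

prints

```
transitions: {'constitutively_closed': 102, 'constitutively_open': 56, 'opened': 37, 'putatively_closed': 5}
sigmoid x0 (log10 CPM): 1.52  threshold 33 CPM
eviction (opened): 3.64  (const. closed): -0.24
treated initiation modes (bp from RE): [50, 0]
```

Reading this output: 56/200 sites (28%) were accessible before activation
and 37 previously closed sites opened; the logistic fit places the
occupancy threshold for local transcription induction at ≈ 33 CPM; the
nucleosome eviction score is strongly positive only at the sites that
opened (occupancy lost at the RE), and treated-condition transcription
initiation concentrates at the RE itself (0 bp) and ~50 bp away — the
generator's configured initiation geometry, recovered by the profile
machinery. The full report bundle (`site_layers.tsv`, `summary.json`,
nucleosome and density profile tables, candidate genes, run manifest) is
written to `example_out/`; rerunning with the same config and seed
reproduces it byte for byte.

The same stages are available from the shell:

```sh
pioneerkit simulate --outdir data --seed 7          # ground-truthed dataset
pioneerkit run --config pipeline.yaml --seed 7      # full pipeline
pioneerkit layers|nucprofile|ctssdensity|link ...   # individual reports
```

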