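# tissuechip

Tissue-specific ChIP-seq binding-site classification and target-gene
characterization, with a synthetic-data generator that plants ground truth
for every pipeline stage.

## The problem

Chromatin factors such as the *C. elegans* DRM-complex components LIN-35
(Rb), EFL-1 (E2F) and DPL-1 (DP), and the HP1-like protein HPL-2, bind
different genomic sites in different tissues. Given peak calls for each
(factor, tissue) combination, the analysis questions are: which binding
sites are specific to the germline, the soma, or the intestine, and which
are broadly bound? which genes do those sites plausibly regulate? and do
the per-tissue target-gene sets differ in germline expression, chromosomal
distribution, functional annotation, and physical site properties?

`tissuechip` implements that analysis as a reusable, tested pipeline:

- **Classification.** A tissue category is a boolean recipe over named
  `factor@tissue` peak sets: an *anchor* set supplies candidate site
  intervals, *include* sets must all overlap a site (≥ `min_overlap` bp,
  default 1), *exclude* sets must not. Categories are evaluated in priority
  order and sites matching several recipes go to the earliest, so the
  output sets are disjoint. The four shipped defaults are
  germline-specific (germline EFL-1 ∧ germline DPL-1 ∧ ¬somatic DPL-1),
  soma-specific (somatic EFL-1 ∧ DPL-1 ∧ LIN-35 ∧ ¬germline EFL-1
  ∧ ¬intestinal HPL-2), intestine-specific (intestinal LIN-35 ∧ HPL-2
  ∧ ¬somatic/intestinal EFL-1) and broadly bound (germline EFL-1 ∧
  intestinal DPL-1 ∧ somatic LIN-35).
- **Target assignment.** A gene is a high-confidence candidate target of a
  site when its TSS lies < 500 bp from the nearest site base, low
  confidence within [500, 2000] bp; sites > 2,000 bp from every TSS are
  unassignable. A site may target several genes and vice versa.
- **Statistics.** Gene-set over-representation uses the upper-tail
  hypergeometric probability P[X ≥ k] for k of n query genes hitting a
  K-of-N reference, computed in log space (stable to p ~ 1e-300);
  chromosomal distribution compares observed to gene-count-proportional
  expected target counts with Pearson's χ² (df = #chromosomes − 1);
  replicate concordance tiles pooled peaks into non-overlapping 100-nt
  windows, counts each replicate's read 5' ends and reports their Pearson
  correlation, alongside directional peak-set overlap fractions; term
  enrichment keeps terms with fold > 2 and P < 0.05 (top 10, P-ascending).
- **Synthetic data.** A generator plants category labels, target genes,
  germline membership (10.5% of a ~19,800-gene, six-chromosome genome),
  X-chromosome biases, per-category widths, and gamma-Poisson replicate
  read tracks with closed-form inter-replicate correlation
  r = φμ/(1 + φμ), so every statistic above can be checked against known
  truth.

## Worked example

Generate a synthetic study and run the full pipeline:

```bash
tissuechip simulate --out study --seed 20260927
tissuechip run study/run_config.yaml
tissuechip classify study/run_config.yaml
```

The last command prints the per-category site counts, which at zero noise
equal the planted structure exactly:

```json
{
  "broadly_bound": 1419,
  "germline_specific": 415,
  "intestine_specific": 656,
  "soma_specific": 282
}
```

`study/results/report.json` then holds the characterization. With the
default planted biases the germline-specific targets come out strongly
germline-enriched and X-depleted while the intestine-specific set shows
the opposite pattern (from `analysis/04_enrichment.py`, same seed):

```
          category  target_genes  germline_fraction  germline_fold  x_ratio
 germline_specific           523             0.3652          3.416    0.126
     soma_specific           349             0.2464          2.305    0.395
intestine_specific           828             0.0302          0.282    2.514
     broadly_bound          1646             0.2303          2.154    0.459
```

and the intestine-specific sites are twice as wide as the others
(`analysis/05_site_properties.py` reports an intestine/other mean-width
ratio of 2.00). The numbered scripts under `analysis/` reproduce each
stage of this walkthrough and write their tables to `results/analysis/`.

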