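# sigmeta

Signed disease–gene literature networks coupled with a per-gene,
cross-dataset expression meta-analysis — built around the question of how
one disease (obesity) might modulate the progression of another
(myocardial infarction, MI) through the genes both touch.

## What it does

The pipeline has four analysis stages plus a synthetic-data generator
that makes the whole chain testable offline:

1. **relations** — load tab-delimited tables of signed literature
   assertions (`subject → object` with polarity `+`/`−` and a supporting
   reference count), QC-filter them (defined polarity, ≥ 3 references),
   aggregate conflicting rows by evidence-weighted majority, and perform
   the cross-disease set accounting. The protective motif extraction
   finds genes *g* with `obesity ⊣ g → MI` ("inhibited MI promoters") and
   `obesity → g ⊣ MI` ("activated MI inhibitors").
2. **meta** — the "mega-analysis": per gene and study, the effect size is
   the log2 fold-change LFC = mean(case) − mean(control) with unpooled
   (Welch) variance `s²₁/n₁ + s²₂/n₂`. Effects are pooled by inverse
   variance; heterogeneity is Cochran's `Q` against `df = k − 1` with
   `I² = 100·(Q − df)/Q` truncated at zero. When `Q ≤ df` the
   fixed-effect model is selected; otherwise DerSimonian–Laird
   random-effects weights `1/(varᵢ + τ²)` are used. Inference is a
   two-sided Wald z-test; the significance rule is `|LFC| > 1` and
   `p < 0.05` (strict), with BH q-values reported alongside. Forest,
   volcano and QQ diagnostics are included.
3. **enrich** — over-representation of a gene list against GMT
   collections: one-sided Fisher exact (hypergeometric tail) p per set,
   BH-FDR across sets, and the reporting criteria `q ≤ 0.005`,
   set size ≤ 1000, overlap ≥ 2 %.
4. **paths** — all minimum-hop directed paths between two entities in
   the signed network, each with its composed net sign (product of edge
   polarities), plus classification of intermediates as
   promoter/inhibitor/indirect with respect to the target disease.

## Worked example

```python
import numpy as np
from sigmeta import (qc_filter, protective_networks, mega_analysis,
                     significant_genes, results_table)
from sigmeta.synthdata import (core_network_relations, SimulationConfig,
                               gen_expression)

# literature network: the packaged 11-gene core fixture
inhibited, activated = protective_networks(
    qc_filter(core_network_relations()), "OBESITY", "MI")
print(sorted(inhibited.genes()), len(activated.genes()))

# expression meta-analysis on simulated seven-study data with one
# strongly down-regulated gene
lfc = np.zeros(50); lfc[0] = -2.0
cfg = SimulationConfig(n_genes=50, planted_lfc=lfc, tau2=0.25, seed=1)
datasets, truth = gen_expression(cfg)
results, _ = mega_analysis(datasets)
print(results_table(significant_genes(results)).to_string(index=False))
```

prints

```
['ADRB1', 'AVP', 'COL3A1', 'IRS1', 'MAPK14', 'MC3R', 'MIR155', 'NPPA', 'NPPB', 'ROCK1', 'SMAD3'] 0
 gene  k  pooled_lfc       se            p         q_bh         Q  df       isq     tau2  model
G0001  7   -2.075318 0.165482 4.452478e-36 4.452478e-36 13.241211   6 54.686925 0.096878 random
```

The first line is the protective motif: the 11 genes the literature marks
as MI promoters that obesity inhibits, and zero MI inhibitors activated
by obesity. The second is the pooled result for the planted gene — the
only one of the 50 genes passing the significance rule: its true LFC of
−2 is recovered (−2.08 ± 0.17), and the planted between-study
heterogeneity shows up as Q = 13.2 over df = 6 (I² = 55 %, τ̂² = 0.097),
correctly selecting the random-effects model.

The same workflow is available from the shell:

```bash
sigmeta all --seed 3 --n-genes 50 --out run/
sigmeta mega --expression run/sim/sim_GSE24591.tsv --expression run/sim/sim_GSE66360.tsv --out run/mega2
```

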