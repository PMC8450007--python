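# phylostab

Toolkit for comparing sets of phylogenetic trees produced under different
alignment/masking strategies. Trees are represented as vectors of
bipartition (split) support values; the resulting trees × splits matrix can
be reduced to "backbone" splits that only express relationships between
predefined taxon groups, decomposed by PCA (with per-variable
contributions), and scored for per-strategy dispersion — a tight cloud of
trees in PC space means a more stable strategy. The package also ships the
alignment-thinning generators such comparisons are typically run against
(gap/block masking, confidence-score threshold series, stepwise
fastest-rate-category removal), an RNA helix loop classifier with
small-parsimony transition counting, and a synthetic-data module so the
whole pipeline runs without any external data.

## Modules

| module                   | what it does                                                          |
| ------------------------ | --------------------------------------------------------------------- |
| `phylostab.io`           | Newick (supports as internal-node labels), FASTA, TSV site tables, tree manifests |
| `phylostab.bipartitions` | canonical split bitsets, RF distance, trees × splits support matrix   |
| `phylostab.backbone`     | group schemes, group-respecting splits, matrix reduction with report  |
| `phylostab.pca`          | PCA (eigen route, n−1 denominator), contributions, dispersion ranking, tree-stat summaries |
| `phylostab.masking`      | gap/block masking, score-threshold series, rate-category stripping    |
| `phylostab.helix`        | dot-bracket parsing, bulge/internal/hairpin loops, bulge signatures, parsimony transitions |
| `phylostab.synthetic`    | seeded tree-set and alignment fixtures with planted backbone rearrangements |
| `phylostab.cli`          | subcommand CLI orchestrating all stages                               |

## CLI

```bash
# generate a self-contained synthetic bundle (trees + manifest + groups + alignment)
phylostab simulate --seed 17 --out bundle/

# end-to-end: trees -> support matrix -> backbone reduction -> PCA -> dispersion
phylostab stability --manifest bundle/manifest.tsv --groups bundle/groups.tsv \
    --out results/ --min-support 50 --min-presence 0.5

# individual stages
phylostab trees-matrix --manifest bundle/manifest.tsv --out matrix.csv
phylostab reduce --matrix matrix.csv.json --groups bundle/groups.tsv \
    --out reduced.json --report report.tsv
phylostab pca --matrix reduced.json --out-prefix results/pca

# alignment thinning
phylostab mask-gaps   --alignment aln.fasta --gap-threshold 0.5 --min-block 3 --out masked/
phylostab mask-scores --alignment aln.fasta --sites sites.tsv \
    --thresholds 0.715,0.794,0.900,0.942,0.970,0.973,0.990 --out series/
phylostab strip-rates --alignment aln.fasta --sites sites.tsv --out strips/

# helix loop signatures from FASTA-like (id, sequence, dot-bracket) records
phylostab helix --records helices.txt --out signatures.json
```

`stability` writes `scores.csv`, `loadings.csv`, `contributions.csv`,
`stability.csv` (dispersion + rank per strategy; rank 1 = most stable),
`reduction_report.tsv` and `run.log`. All outputs are byte-reproducible
from the same inputs and seed. Exit codes: 0 success, 2 invalid
parameters, 3 malformed/inconsistent data.

## Conventions

- Supports are declared per collection as `percent` ([0, 100]) or
  `probability` ([0, 1]); mixing scales raises.
- A degree-2 root is suppressed on parse; conflicting supports on the
  merged edge are an error (opt into taking the maximum).
- Split columns are ordered by (size, bitmask); splits absent from a tree
  get the fill value (default 0, i.e. "no support"); a missing-marker mode
  exists but PCA requires complete columns.
- Gap masking keeps a column when its non-gap fraction is **≥** the
  threshold; score masking removes columns with score **<** the cutoff;
  "fastest" rate category = highest category index.

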