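# circuitminer

Stage-specific **miRNA–TF–mRNA circuit mining** from developmental
time-course expression data.

During a developmental process such as mouse lung maturation, transcription
factors (TFs) and microRNAs jointly regulate gene expression, and the active
regulatory combinations change between developmental stages. `circuitminer`
detects these combinations as *circuits*: a triple (miRNA, TF, mRNA),
supported by database-derived interaction pairs on all three edges
(miRNA→gene, TF→gene, miRNA→TF), whose three pairwise expression
relationships are all statistically significant within one developmental
stage. The TF is represented by the expression profile of its coding gene.

For each edge the association between the two expression vectors *i*, *j*
over a stage's time points is the Pearson correlation

$$R(i,j) = \frac{E[(i-\mu_i)(j-\mu_j)]}{\sqrt{E[(i-\mu_i)^2]\,E[(j-\mu_j)^2]}}$$

whose significance is assessed by a permutation test: one vector is held
fixed, the other permuted (exhaustively over all $n!$ orderings when
feasible, otherwise by seeded Monte-Carlo draws with the add-one
correction), and the edge is significant at $p \le \alpha$ (default
$\alpha = 0.05$). A candidate is a circuit in a stage iff all three edges
are significant there.

The package covers the full pipeline:

- **data_io** — TSV/GMT readers and writers, identifier normalization, the
  shared domain types (expression matrices, interaction sets, gene sets).
- **synthetic** — a generator of statistically controlled datasets with
  planted, stage-confined circuits and decoy interactions, used as ground
  truth throughout the tests.
- **candidates** — variance filtering of the gene universe and candidate
  assembly from the three pair sets.
- **stages** — time-axis segmentation: a shipped early/late preset and
  two-way hierarchical clustering of expression columns.
- **detection** — the permutation-tested correlation core and the
  all-three-edges circuit call, with per-edge caching and stable sub-seeds.
- **context** — stage overlaps (Venn regions for circuits/TFs/miRNAs/genes),
  gene-set restriction (tissue-specific, cancer), exclusive regulators, and
  cross-stage common-node networks.
- **enrichment** — exact hypergeometric (or conservative EASE)
  over-representation of circuit gene lists against GMT collections with
  Benjamini–Hochberg adjustment.
- **pipeline / cli** — a YAML-configured end-to-end driver
  (`circuitminer run`) with per-step subcommands and SIF/GraphML export.

## Worked example

The numbered scripts under `analysis/` walk through the whole procedure on
a simulated study: 7 time points × 2 replicates, an early (t1–t3) and late
(t4–t6) stage with the final time point excluded, and 50 circuits planted
per stage at a target edge correlation of |R| ≈ 0.95.

```bash
python analysis/01_simulate.py      # write the dataset under results/data/
python analysis/02_candidates.py    # variance filter + candidate assembly
python analysis/03_stages.py        # two-way clustering -> stage partition
python analysis/04_detect.py        # permutation-tested circuit detection
python analysis/05_context.py       # overlaps, gene-set contexts, networks
python analysis/06_enrichment.py    # per-stage gene-set enrichment
```

Step 02–04 print, for the default seed:

```
variance filter: 410 gene rows -> 308 retained, 102 dropped
100 circuit candidates (100 miRNAs, 100 TFs, 100 genes)
suggested partition: {'stage1': [0, 1, 2], 'stage2': [3, 4, 5]} excluded: [6]
matches the early/late preset: True
stage early: 49 circuits detected
stage late: 49 circuits detected
stage whole: 100 circuits detected
  recall in early: 49/50 = 0.98
  recall in late: 49/50 = 0.98
```

meaning: the bottom variance quartile of gene rows was removed, the three
pair sets joined into 100 candidate triples, column clustering re-derived
the early/late split, and detection recovered 49 of the 50 circuits planted
in each stage — each planted circuit is also visible over the whole 6-point
span, while the two stray whole-only calls are multiple-testing noise at
$\alpha^3$.

The same pipeline runs on real data from the command line, given expression
TSVs (rows = entities, columns `<time>_<replicate>`), 2–3 column interaction
pair TSVs, a TF→coding-gene map and optional context gene lists:

```bash
circuitminer run --config run.yaml --seed 1
```

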