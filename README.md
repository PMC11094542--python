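# crust-assembly

Quantitative inference chain for soil microbiome studies of biological soil
crusts (and similar sample sets): eco-enzymatic stoichiometry, abundant/rare
taxon structure, null-model community-assembly partitioning, and co-occurrence
networks with a random-matrix-theory (RMT) correlation cutoff — plus a
synthetic-data generator that produces all five inputs with known ground
truth, so every stage can be validated without sequencing data.

Intended users: microbial ecologists who have an ASV table, a taxonomy, a
rooted phylogeny, soil physicochemistry and enzyme assays for the same
samples, and want the standard assembly/stoichiometry/network analyses as
reproducible, seeded, tested code.

## What it computes

**Enzyme stoichiometry.** From activities of C- (AG, BG, XS, CB), N- (NAG,
LAP) and P-acquiring (AP) enzymes:
ratios ln(BG)/ln(LAP+NAG), ln(BG)/ln(AP), ln(LAP+NAG)/ln(AP); the vector
summary of the point (X, Y) with X = (BG+CB)/(BG+CB+AP),
Y = (BG+CB)/(BG+CB+NAG+LAP), where length = √(X²+Y²) scales with relative C
limitation and the polar angle (degrees from the x-axis) reads N limitation
below 45° and P limitation above; and the quadrant classifier on
((LAP+NAG)/AP, BG/(LAP+NAG)).

**Community structure.** Abundant (mean relative abundance > 1%) vs rare
(< 0.1%) partitioning, copiotroph:oligotroph ratios from an editable
phylum→strategy map, Shannon diversity, Bray–Curtis β-diversity with PCoA and
one-way PERMANOVA (seeded permutations, add-one p).

**Assembly processes.** For every sample pair: abundance-weighted βMNTD;
βNTI as its z-score against a taxon-shuffling null on the patristic distance
matrix; Raup–Crick with Bray–Curtis (RC_bray) against a
richness/occupancy-preserving reassembly null; the five-way partition
(βNTI > 2 heterogeneous selection, < −2 homogeneous selection, then
RC_bray > 0.95 dispersal limitation, < −0.95 homogenizing dispersal, else
undominated); Mantel tests of βNTI against soil-variable distances.

**Networks.** Pearson correlations of ln(count+1) abundances, cutoff chosen
where the eigenvalue nearest-neighbour spacing distribution turns Poisson
(the RMT transition), topology metrics, deterministic greedy modularity
modules with abundant/rare composition, per-sample network complexity
(z-scored subgraph properties) and its regression on enzyme ratios.

**Synthetic data.** Yule phylogenies with shallow terminal radiations,
Brownian-motion environmental optima (clade-conserved niches), lognormal
metacommunities sampled under five named assembly regimes, and soil/enzyme
tables with configurable N/P/balanced limitation — all seeded, with a
truth.json that regenerates the bundle bit-for-bit.

## Worked example

Simulate a 12-sample heterogeneous-selection community (200 taxa, 1,000 reads
per sample, P-limited soils) and run every stage:

```python
from crust_assembly.pipeline import RunConfig, run_pipeline

config = RunConfig(simulate=True, regime="heterogeneous_selection",
                   n_samples=12, depth=1000, n_taxa=200, limitation="P",
                   n_null=199, n_perm=499, prevalence=1/6,
                   subsets=("whole",), seed=11, out_dir="demo_run")
summary = run_pipeline(config)
```

Output (from `demo_run/summary.json`, abridged):

```
structure:  26 abundant / 80 intermediate / 94 rare taxa;
            PERMANOVA by site R2 = 0.24, p = 0.002
enzymes:    mean vector angle 53.2 deg -> all 12 samples called P_limited
assembly:   heterogeneous_selection fraction 0.73 over 66 pairs
            (undominated 0.20, homogeneous_selection 0.06)
network:    RMT threshold 0.30; 80 nodes, 736 edges, avg degree 18.4,
            clustering 0.80, modularity 0.39 in 3 modules
```

Reading it: the generator placed samples along an environmental gradient with
clade-conserved optima, so most pairs are *more* phylogenetically divergent
than the null expects (βNTI > 2 → heterogeneous selection dominates); the
P-limitation scenario pushes AP activity up, so the stoichiometry vector
angle sits above 45°; and environmental filtering induces strong
co-occurrence blocks that the RMT cutoff keeps while stripping noise.

The same stages run from the shell on files:

```bash
crust-assembly simulate --regime dispersal_limitation --n-samples 12 \
    --depth 1000 --n-taxa 200 --seed 3 --out data/
crust-assembly structure --table data/asv_table.tsv --taxonomy data/taxonomy.tsv \
    --metadata data/metadata.tsv --out out/
crust-assembly assembly --table data/asv_table.tsv --tree data/tree.nwk \
    --n-null 999 --seed 3 --out out/
crust-assembly network --table data/asv_table.tsv --seed 3 --out out/
crust-assembly all --config run.yaml --seed 3 --out out/
```

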