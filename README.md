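# ctmotif

Functional-motif discovery in bipartite component–target (C–T) networks.
The pipeline takes a compound property table, a component–target edge list,
a gene-set collection (GMT) and a disease-gene score table, and produces:

1. **Drug-likeness screen** — Rule-of-Five descriptor bounds plus an oral
   bioavailability window (0.3–0.55, inclusive) and a GI-absorption class;
   a compound passes only with zero violations.
2. **Module detection** — two-level map-equation codelength minimisation
   over the C–T network (random walk with uniform teleportation), with a
   permutation significance filter against degree-preserving bipartite
   rewirings of the edge set.
3. **Motif selection** — significant modules become items of a 0/1 knapsack
   (value = disease-annotated targets or summed relevance; weight = module
   size; capacity = a fraction of total weight) solved by a genetic
   algorithm (roulette selection, two-point crossover, per-bit mutation,
   elitism); an exact DP/Pareto solver ships as the test oracle.
4. **Validation** — hypergeometric over-representation with
   Benjamini–Hochberg adjustment, pathway coverage of motif genes versus
   the full network, reference-pathway proportion, and relevance/evidence
   summaries against high-reliable gene sets.
5. **Component ranking** — information gain × min-max-normalised target
   count (the Q score); components with Q > 0.01 form the key group.

A synthetic-data module generates every input with planted ground truth, so
the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic input bundle with ground truth + a ready config
ctmotif simulate --preset small --seed 1 --outdir demo/

# run the whole pipeline from the bundle's config
ctmotif pipeline --config demo/config.yaml

# or run stages individually
ctmotif screen  --compounds demo/compounds.tsv --out passed.tsv
ctmotif network --network demo/network.tsv --out stats.json --sif net.sif
ctmotif motifs  --network demo/network.tsv --n-perm 199 --seed 1 --out modules.json
ctmotif frms    --sdfms modules.json --disease demo/disease.tsv --out frms.json
ctmotif enrich  --genes genes.txt --gmt demo/genesets.gmt --out enrichment.tsv
ctmotif keycomp --network demo/network.tsv --frms frms.json --out scores.tsv
```

Every stage writes JSON/TSV artifacts with an embedded provenance block
(resolved parameters + seed); re-running with the same seed reproduces the
outputs byte for byte.

## Layout

```
src/ctmotif/
  core.py       domain types + TSV/SIF/GMT/JSON readers and writers
  adme.py       drug-likeness screen
  mapeq.py      visit rates, codelength, partition search, significance
  knapsack.py   knapsack instance building, exact oracle, genetic algorithm
  enrichment.py hypergeometric enrichment, BH, validation metrics
  keycomp.py    information-gain Q-score component ranking
  synthetic.py  seeded generators for all inputs with ground truth
  cli.py        click CLI + pipeline orchestration
```
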