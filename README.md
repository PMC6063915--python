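# procnet

Transcriptomic inference pipeline for two-condition contrasts: sample
clustering diagnostics, from-scratch gene set enrichment analysis, and
inference of a process network that links enriched gene sets through
protein-interaction support among perturbed genes.

## What it does

- **`procnet.synthetic`** — seeded generators for expression matrices with
  planted differentially expressed gene sets, gene set collections with
  controllable overlap, and interaction networks with planted inter-set
  connectivity over an Erdős–Rényi background. Every downstream stage is
  testable without external data.
- **`procnet.expression`** — GCT 1.2 / TSV expression matrices with sample
  annotations; probe-to-gene collapsing (per-sample max by default);
  mean-replicate imputation for 2-sample groups; average within/between group
  distances (Euclidean, Manhattan, 1 − Pearson correlation); agglomerative
  hierarchical clustering (single/complete/average linkage) with
  deterministic tie-breaking, Newick export, and clade-purity checks.
- **`procnet.gsea`** — signal-to-noise-ratio gene ranking with the
  small-sample sd floor (`sd' = max(sd, 0.2·|mean|)`), the weighted
  running-sum enrichment score with leading-edge extraction, a gene-set
  permutation null (vectorized, shared per set size), Benjamini–Hochberg
  q-values, a 10–500 effective-size filter, and the perturbed-gene union over
  significant leading edges.
- **`procnet.network`** — interaction edge lists with integer confidence
  scores; filters that drop edges below a score cutoff (default 500,
  boundary inclusive) and restrict to measured genes.
- **`procnet.bpn`** — candidate links between enriched sets supported by
  interactions between perturbed genes; a Metropolis sampler over link
  subsets targeting `exp(β·(coverage − λ·|S|))`; posterior link
  probabilities, probability thresholding (default ≥ 0.45, inclusive),
  connected components, and per-link support dissection (how many supporting
  interactions connect leading-edge genes on both sides).
- **`procnet.cli`** — `procnet simulate|cluster|gsea|bpn|run|report` with a
  single YAML config surfacing every threshold, and a manifest (seed +
  SHA-256 hashes) making runs reproducible byte-for-byte.

## CLI quick start

```sh
# generate a synthetic fixture bundle (GCT/CLS/GMT/network/truth + manifest)
procnet simulate --config examples/config.yaml --outdir out/fixtures --seed 1

# full pipeline: inputs (or simulation) -> cluster -> gsea -> link inference
procnet run --config examples/config.yaml --outdir out/run --seed 1

# inspect one link's supporting interactions
procnet report --rundir out/run --set-a S0000 --set-b S0001
```

See `examples/config.yaml` for the full set of knobs (defaults: set-size
filter 10–500, 5000 permutations, q ≤ 0.01, interaction score ≥ 500,
link probability ≥ 0.45; the sampler's burn-in/steps default to the
publication-scale 10⁷/10⁸ and should be reduced for desk-scale runs as in
the example).

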