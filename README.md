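# pepfer

Free-energy regression for peptide-display affinity selection.

`pepfer` infers additive binding free-energy models (−ΔΔG/RT matrices) for
peptide-recognition domains from input/bound NGS count tables produced by
multi-round affinity selection on random peptide libraries, and uses the
fitted models to predict relative affinities, scan phosphosites, and score
variant effects.

## How it works

1. **Read processing** (`pepfer.library`): paired reads are merged, the
   variable region is located between constant DNA anchors (Hamming
   matching, ≤5 mismatches per anchor), PHRED-filtered (≥20 at every
   position of the cropped region), checked against the degenerate codon
   design (NNS by default), translated, and tallied into per-round count
   tables.
2. **Model** (`pepfer.model`): predicted enrichment of a peptide is
   `κ = α_NS·Σ_offsets exp(NS window score + γ_x) + α_S·Σ_offsets exp(specific window score)`,
   where the specific mode may overlap up to five residues of the constant
   protein flanks. Observed counts are scored with a scaled binomial
   log-likelihood in which the bound/input odds are `exp(depth)·κ` per
   table, plus L2 / exponential-barrier / Dirichlet regularization.
3. **Inference** (`pepfer.fitting`): all free parameters are optimized
   jointly with L-BFGS using analytic gradients (a fused numba kernel with
   a pure-numpy fallback). One coefficient set is shared across rounds;
   activities and depths are independent per count table. The central
   column can be constrained to tyrosine (0 for Y, −10 otherwise).
   `normalize` gauge-fixes the model so the optimal sequence has relative
   affinity exactly 1.
4. **Baseline** (`pepfer.enrichment`): position-wise amino-acid
   log-enrichment matrices, hypergeometric down-sampling, count-distribution
   histograms, and matrix comparison (r²).
5. **Scoring** (`pepfer.scoring`): relative affinities `exp(−ΔΔG/RT)` of
   centrally aligned windows, phosphosite scanning with co-expression
   allow-lists, variant-effect affinity ratios, model truncation, ln(K_D)
   regression validation, exact sign tests, energy logos, and model
   clustering.
6. **Simulator** (`pepfer.simulate`): NNS-encoded random libraries with
   skewed abundances, affinity-proportional selection with non-specific
   carry-over, per-round sequencing, and FASTQ generation with planted
   corrupt reads — everything needed to test parameter recovery end to end
   with a known ground truth.

## Command line

```sh
# reads -> count table
pepfer process --in-fastq in.fastq --bound-fastq bound.fastq \
    --design x5yx5 --round 1 --out r1.tsv --report r1_report.txt

# count tables -> model (joint multi-round fit, normalized JSON output)
pepfer fit --tables r1.tsv r2.tsv r3.tsv --design x11 \
    --config fit.yaml --out model.json --log fit.log

# log-enrichment baseline
pepfer enrich --table r1.tsv --design x5yx5 --out enrich.tsv --pseudocount 0.5

# synthetic experiment with ground truth
pepfer simulate --config sim.yaml --out-dir sims/ --fastq

# scoring
pepfer score --model model.json --sites sites.tsv --fasta proteins.fasta \
    --allow coexpressed.tsv --out scores.tsv
pepfer variants --model model.json --pairs pairs.tsv --out ratios.tsv
pepfer logo --model model.json --out logo.png --tsv logo.tsv
pepfer cluster --models a.json b.json c.json --out dendro.txt
```

Designs: `x5yx5` (eleven residues, fixed central Tyr), `x11` (fully random),
or a YAML file with `name`, `length`, `fixed_positions`, anchors, flanks,
and `codon_pattern`.

## Model JSON

Fitted models serialize to JSON with the design, both binding modes
(row-major width×20 coefficient tables), constrained cells, per-round
activity/depth parameters, and metadata; floats round-trip exactly.
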