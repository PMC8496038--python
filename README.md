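# regseq

Models of regulatory-sequence recognition, with and without
spacing-and-orientation constraints (SAOC) among transcription-factor
binding sites. The package asks whether simple binding models reproduce
global properties of regulatory sequence — length, uniqueness, frequency,
evolutionary turnover, and master-regulator dominance — entirely on
synthetic data with known ground truth.

## What's inside

| module | role |
| --- | --- |
| `regseq.motif_model` | PFM data structures, information content, palindromy, MEME/JASPAR/TSV I/O |
| `regseq.multimer_builder` | chain dimeric motifs into 3-6-TF multimeric motifs (PCC alignment + per-column averaging) |
| `regseq.pwm_scanner` | exact p-value → score thresholds (DP over the discretized score distribution) and double-strand scanning |
| `regseq.occupancy_math` | closed-form combinatorics: motif diversity, genome-wide hit expectations, Poisson specificity with/without master regulators |
| `regseq.classifier_pipeline` | hit-count-feature logistic regression, chromosome-held-out evaluation, feature selection, genome tiling, threshold calibration |
| `regseq.evolution_sim` | neutral-mutation turnover: mutate, re-score/re-scan, measure dropout |
| `regseq.synthetic_data` | seeded generators for motif catalogs, cooperating dimer catalogs, and labeled sequence sets |

## CLI

```bash
regseq table2                              # occupancy-calculus summary table (TSV)
regseq poisson-heatmap --n-master 0 --n-master 2
regseq mr-heatmap --arity 4 --arity 5      # hit expectations vs TF and MR counts
regseq make-data --n-tfs 100 --outdir data/    # motif catalog + labeled FASTA/BED
regseq scan data/monomers.meme data/sequences.fa --p-value 1e-4   # BED6 hits
regseq train --n-tfs 100 --selection rfe_k --outdir model/
regseq evolve --rate 0.06 --rate 0.49 --corpus-mb 10 --outdir turnover/
```

## Notes

- Scanning thresholds are exact on a 1000-bin discretized score lattice;
  hit calling uses the same lattice, and a numba kernel (with a pure-numpy
  fallback) accelerates long-sequence scans without changing results.
- Sequence coordinates are 0-based half-open on the forward strand; hits
  are emitted as BED6.
- All generators and simulations are deterministic under their seeds.
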