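# petscreen

A tested, reusable implementation of a machine-learning-guided enzyme
screening loop for condition-specific PET hydrolase discovery: profile-HMM
homology scoring and condition tuning, supervised activity prediction under
pooled cross-validation, multi-objective candidate selection, plate-assay and
DSF data processing, and per-residue statistics of sequence/surface
determinants of low-pH activity — exercised end to end on a synthetic enzyme
world with planted, recoverable determinants.

## Layout

| module | what it does |
| --- | --- |
| `petscreen.seqio` | FASTA/Stockholm I/O, pairwise identity (global affine alignment, shorter-sequence denominator), greedy redundancy filtering |
| `petscreen.msa` | Needleman–Wunsch (Gotoh affine gaps), UPGMA-guided progressive alignment, gappy-column stripping, neighbor-joining trees |
| `petscreen.hmm` | profile HMM build (match/insert/delete, Laplace pseudocounts), forward bit scores (global and uni-local), Viterbi column maps, score normalization to a reference, condition tuning |
| `petscreen.predictors` | k-mer + HMM-score features, 5-fold plans, pooled cross-validated prediction, AUROC with tie handling, precision@0.5, Spearman |
| `petscreen.selection` | round-2 multi-objective rule (argmax-or-percentile + identity filter) and round-3 threshold rule |
| `petscreen.assay` | product quantification from A260, the +0.05-over-blank activity call, per-enzyme summaries, condition contingency tables with co-tested exclusion, hit rates, DSF Tm extraction (highest transition) |
| `petscreen.groups` | acid vs neutral group split at pH 4.5, differential conservation of residue classes, exact/asymptotic Mann–Whitney per position, factor profiles and factor-activity correlation, reference-coordinate mapping, accessory-domain clustering |
| `petscreen.simulate` | the synthetic world: star phylogeny with an acid-associated subfamily, planted conserved columns and property shifts, accessory domains, yield-tiered assay plates, melt curves, property tables, full ground truth |
| `petscreen.pipeline` / `petscreen.cli` | YAML-configured orchestration and the `petscreen` command |

## CLI

```bash
petscreen simulate --out world/ --seed 1 --n-enzymes 212
petscreen assay world/assay.csv --melt world/melt_curves.csv --out-dir assay_out/
petscreen align world/sequences.fasta --out aln.fasta
petscreen hmm-build aln.fasta --out hmm.json
petscreen hmm-score hmm.json world/sequences.fasta --out scores.tsv --reference DP001
petscreen train world/sequences.fasta assay_out/per_condition.csv \
    --condition cryPow,4.5,40 --out metrics.json
petscreen run-all --out run/ --seed 1     # one-command synthetic end-to-end
```

Exit codes: 0 success, 1 usage error, 2 stage failure.

## Notes on conventions

- Pairwise identity uses the shorter sequence length as denominator and 'X'
  never counts as a match; both are configurable.
- The profile HMM scores in bits against a uniform background by default;
  insert states emit at background (score-neutral), 'X' is score-neutral.
- Mann–Whitney p-values are exact (full assignment enumeration, midranks for
  ties) for combined n ≤ 12, tie-corrected normal approximation otherwise;
  no multiple-testing correction by default (a Benjamini–Hochberg option
  exists).
- Metrics are computed over pooled out-of-fold predictions, never averaged
  per fold.
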