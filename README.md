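# smallrna-libbias

Toolkit for studying how small-RNA **library-construction protocols bias**
miRNA sequencing results. It bundles a read annotator, length/composition
statistics, a lightweight RNA secondary-structure engine, an end-structure
classifier, qRT-PCR (2^-ΔΔCT) and read-count abundance statistics, a
protocol-bias simulator, and a CLI that runs the whole analysis and emits a
structured JSON bias report.

## The science in brief

Small-RNA libraries are built by ligating adapters to both ends of ~22 nt
RNAs, and every protocol family does this differently:

- **Hybridization-based protocols** (e.g. SOLiD-style cloning with
  degenerate-end adapter mixes, and stem-loop qRT-PCR primers) tolerate
  structured ends but smear read lengths: they truncate 3' ends, admit 5'
  variation, and produce flatter length distributions (lower excess
  kurtosis).
- **Direct single-stranded ligation** (early Illumina cloning, "V1") gives
  tight length distributions but fails when the RNA's ends are sequestered
  in intramolecular base pairs, so molecules whose 3' end participates in
  **end secondary structure (ESS)** are depleted or lost entirely.
- **Improved ligases** ("V1.5"-style) sit in between.

These mechanisms distort which miRNAs you count and how well sequencing
agrees with qRT-PCR. This package makes each mechanism explicit and
measurable:

- `folding` — a scored Nussinov-style dynamic program (GC=3, AU=2, GU=1,
  +1 per stacked pair, minimum loop 3) with an exact brute-force
  enumeration oracle for testing.
- `ess` — classifies whether a fold leaves the 5'/3' terminal bases paired
  (categories `non_ess`, `ess5_only`, `ess3_only`, `both`).
- `annotation` — ungapped alignment of reads to a reference set with
  bounded mismatches, end trimming, and non-templated 3' additions;
  category calls (miRNA / rRNA / mRNA / repeat / no match) and per-family
  count tables.
- `composition` — length distributions with excess kurtosis, N-padded
  position frequency matrices with per-column information content.
- `abundance` — relative abundances, Pearson correlation matrices across
  methods, 2^-ΔΔCT qRT-PCR quantification, and log2 fold differences
  between samples (sequencing and qPCR, with matching sign conventions).
- `synthetic_data` — a generative model of the protocols: per-protocol
  length jitter, 3' truncation, 5' variation, non-templated additions, and
  ESS-category-dependent ligation success, sampled by rejection to an
  exact depth.
- `cli_report` / `cli` — orchestration and the `smallrna-libbias` command.

## Quick start

Generate a complete synthetic study (2 samples x 4 protocols, with
triplicate CT tables for a 9-miRNA qPCR panel) and analyze it:

```bash
smallrna-libbias demo --out study --seed 0
smallrna-libbias run --config study/config.json
# -> study/report/bias_report.json plus per-section TSVs
```

Individual steps are also exposed: `annotate`, `fold`, `ess`, and
`compare` (see `smallrna-libbias --help`).

## Worked example

Folding and end-structure classification:

```python
>>> from smallrna_libbias import fold, classify_ess
>>> r = fold("GGGAAAACCC")
>>> r.structure, r.score
('(((....)))', 11.0)
>>> r2 = fold("GGGGGGGG" + "AAAA" + "CCCCCCCC" + "AA")
>>> r2.structure
'((((((((....))))))))..'
>>> classify_ess(r2).category.value   # the 3' AA overhang shields the 3' end
'ess5_only'
>>> classify_ess(fold(r2.sequence[:-2])).category.value  # remove it -> 3' ESS
'both'
```

Running the demo study above (`seed 0`, cloning depth 220, deep-sequencing
depth 50,000) produces `study/report/bias_report.json`, from which the
numbers below are taken verbatim. The two samples share 9 miRNA families;
`sample_a` is simulated with miR-1 at exactly twice the relative abundance
it has in `sample_b` (true log2 fold = 1.0).

Length-distribution excess kurtosis (sample_a): the hybridization-style
model smears lengths while direct ligation stays tight:

| protocol model | excess kurtosis | n reads |
|---|---|---|
| solid_cloning | 0.099 | 220 |
| illumina_v15_cloning | 1.104 | 220 |
| illumina_v1_cloning | 5.593 | 220 |

Fraction of miR-1 reads whose fold has 3'-end pairing (`ess3_only` +
`both`), sample_a: the V1 model's hard intolerance of 3' end structure
removes such reads entirely, while the hybridization model retains them:

| protocol model | 3'-ESS fraction of miR-1 reads | n |
|---|---|---|
| solid_cloning | 0.510 | 51 |
| illumina_v15_cloning | 0.263 | 99 |
| illumina_ga | 0.036 | 28,478 |
| illumina_v1_cloning | 0.000 | 143 |

Correlation between qRT-PCR relative abundances and per-protocol read
frequencies over the 9-family panel (sample_a row of
`report/correlations_sample_a.tsv`): 0.982 (solid), 0.796 (V1.5), 0.747
(GA), 0.746 (V1).

Recovered log2 fold difference for miR-1 between the samples (true value
1.0): 0.94 (V1.5 cloning), 0.77 (V1 cloning), 0.76 (SOLiD cloning), 0.73
(deep GA), 0.90 (qPCR); miR-206 (true −0.45): −0.72 (GA), −0.60 (qPCR),
and **undetectable** in the V1 cloning library — the family's 220-read
column contains a zero, which the pipeline reports as `null` rather than
inventing a pseudocount. Ratios of read *frequencies* are also
compositionally distorted whenever ligation bias reweights the rest of
the panel, which is visible in the GA estimate despite its 50,000-read
depth.

Category fractions behave as programmed: the solid-model libraries carry
~20% non-miRNA reads (rRNA + mRNA + unmappable), the others 6–10%.

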