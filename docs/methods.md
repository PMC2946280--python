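# Methods note

This note records the models, parameter choices, and numerical decisions
behind `smallrna-libbias`, and the known limits of each.

## Secondary-structure engine (`folding`)

The engine is a **scored Nussinov-style dynamic program**, not a full
thermodynamic (nearest-neighbor free-energy) folder. A structure is a
non-crossing set of base pairs over {GC, AU, GU} with a minimum hairpin
loop of 3 unpaired bases. Its score is the sum of pair scores

- GC = 3, AU = 2, GU = 1 (proportional to typical hydrogen bonding /
  relative stability),
- plus a stacking bonus of 1 for every pair stacked directly on another,

and `fold()` maximizes this score exactly over all legal structures.
Three interval tables are filled: `V[i,j]` (best score with i·j paired),
`W[i,j]` (unconstrained best), and `Wnp[i,j]` (best with i and j not
paired with *each other*), the last of which lets the recurrence award
the stacking bonus exactly when two pairs are adjacent. The fill is a
numba-compiled kernel (O(n³), ~0.1 ms for a 22-mer after JIT warm-up);
`fold_cached` memoizes whole results because the simulator folds the
same candidate sequences repeatedly.

Presentation vs. score: helices shorter than `min_helix` (default 2,
i.e. isolated pairs) are dissolved from the *reported* structure and
pair set, because single isolated pairs are not believable helices at
this level of theory — but the reported `score` remains the
unconstrained DP optimum. This split keeps an exact testing oracle:
`enumerate_structures()` brute-forces every legal structure (guarded to
length ≤ 16) without the helix filter, and the maximum enumerated score
equals `fold().score` exactly, bit for bit. The traceback resolves ties
deterministically (5'-most base, 5'-most partner first) and re-derives
branch equalities using the same floating-point operation order as the
kernel, so structure reconstruction never disagrees with the tables.

Symmetry note: scores are invariant under *sequence reversal* (the pair
rule set is symmetric in its arguments), and the test suite verifies
this. Reverse-*complement* invariance does **not** hold and is not
claimed: the complement of the illegal pair C·A is the legal wobble
G·U, so complementing a sequence can create or destroy pairings.

## End secondary structure (`ess`)

A read has 5'-ESS (resp. 3'-ESS) if any base within `end_window`
(default 2) positions of that end is paired in its fold. Categories:
`non_ess`, `ess5_only`, `ess3_only`, `both`. The window default reflects
that single-stranded ligases and adapter hybridization need the terminal
couple of bases accessible; it is a parameter, not a claim, and
`classify_structure` works on any dot-bracket string so the rule can be
applied to structures from other folders.

## Annotation (`annotation`)

Reads are aligned to each reference **without gaps**, allowing up to
`max_mismatch` substitutions (default 2), `max_trim` reference bases
missing at either end (default 3), and `max_add3` non-templated 3'
additions (default 3) — the known edit vocabulary of small-RNA library
preparation (truncation, 5' variation, NTA). Among feasible placements
the best is chosen lexicographically by (mismatches, total edits,
category priority miRNA > rRNA > mRNA > repeat, reference id), which
makes annotation deterministic and order-independent. Ungapped alignment
is a deliberate simplification: indels are rare in mature miRNA reads
and a banded aligner would add complexity without changing the bias
statistics of interest. Per-sequence results are cached since deep
libraries contain few unique sequences.

## Composition (`composition`)

Length distributions are summarized by **population excess kurtosis**
(weighted m4/m2² − 3); a sharper, single-mode length profile scores
higher, a protocol that smears lengths scores lower. Position frequency
matrices are built after right-padding 3'-truncated reads with `N`; `N`
is excluded from the entropy so a column's information content (2 − H
bits, optional small-sample correction 3/(2·ln2·n)) reflects only
observed bases, and the `N` counts themselves record truncation depth.

## Simulator (`synthetic_data`)

Each protocol is a `ProtocolBiasModel` with interpretable knobs:
Gaussian length jitter (`length_sd`), a 3'-truncation distribution over
0–3 bases, 5'-variation probability, non-templated 3'-addition
probability, a per-ESS-category **ligation success probability**, and a
depth. Reads are generated by rejection sampling: draw a source molecule
from the abundance profile (miRNA families plus rRNA/mRNA/unmappable
contamination), apply the mutation chain, fold it, classify its ESS
category, and accept with that category's ligation probability —
repeating until the library reaches its exact depth (guarded by an
attempt bound). When a model's ligation vector is uniform the fold step
is skipped entirely, which makes neutral (bias-free) simulations cheap.

The default models encode the qualitative protocol contrast: the
hybridization-style model truncates heavily and ligates structured ends
almost as well as unstructured ones; the direct-ligation V1 model is
tight in length but assigns 3'-ESS molecules ligation probability
exactly 0; the V1.5 model sits between; the deep-sequencing model pairs
V1.5-like prep with 50,000-read depth. Parameters are plausibility
choices, not fits to any dataset.

Realism and limits: the simulator intentionally closes the loop through
the package's *own* folding and ESS code, so simulation-based tests
check internal consistency of the bias mechanism, not the truth of the
Nussinov model; sequencing error, PCR duplication, and adapter read-
through are out of scope. One emergent caveat: because acceptance is
conditioned per molecule, observed *read-level* ESS fractions mix
ligation bias with post-truncation refolding — a heavily truncating
protocol can show a lower 3'-ESS read fraction than its permissive
ligation vector suggests. Fold-difference estimates from read
frequencies are compositional: a protocol that reweights other families
distorts a family's frequency ratio even when its own counts are
unbiased.

## Abundance statistics (`abundance`)

qRT-PCR quantification uses 2^-ΔΔCT with triplicate CTs combined by
arithmetic mean before differencing; the reference miRNA's relative
abundance is exactly 1 by construction. Between-sample log2 fold is
−ΔΔCT (positive = higher in the first sample), matching the sequencing
convention log2(freq_A/freq_B). The sequencing fold difference supports
a pseudocount (default 0.5, with family-count-adjusted denominators);
at pseudocount 0 it is the pure frequency-ratio equation and raises
`UndetectableFoldDifference` on zero counts instead of fabricating a
value. Pearson correlations are computed on untransformed relative
abundances by default (a `--log` flag offers log10(x+pc) for sensitivity
analysis); `pearson` is validated against a direct covariance/σ oracle
to 1e-12.

## Pipeline and determinism

All randomness flows from one integer seed through
`numpy.random.SeedSequence`-derived child seeds (kept < 2^31), so the
demo generator, the simulator, and the report are reproducible
byte-for-byte. The report never silently drops a section: anything that
cannot be computed is emitted as `{"skipped": <reason>}`, and stage
failures are re-raised naming the stage and library.

## Known limitations

- The folding model has no loop penalties, no temperature, no dangles;
  scores are not free energies and should only be compared within this
  model.
- Ungapped annotation cannot place reads with internal indels.
- Kurtosis on 220-read libraries is noisy (sampling SD ≈ √(24/n) ≈
  0.33); stochastic ordering tests therefore use 2,000-read libraries.
- The external quantitative check in the test suite needs per-sample
  abundance tables that cannot be redistributed; it fails with an
  explanatory message when they are absent.
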