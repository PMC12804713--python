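# Methods

This note documents the statistical model implemented by `cfimpute`, the
synthetic data used to exercise it, and the numerical and design choices a
maintainer should know about. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model

### Observation model

A *fragment* is one sequenced molecule (both mates of a pair merged),
reduced at extraction to the panel SNPs it covers, the observed allele
(0 = ref, 1 = alt) and the base quality. Bases matching neither allele,
bases below `min_baseq`, indels, and duplicate/secondary/supplementary
alignments are discarded; where mates overlap a site with conflicting
bases the higher-quality base wins and a tie drops the site. The emission
for a fragment against a haplotype is the product over covered sites of
`1 − e` on match and `e` on mismatch, with
`e = max(10^(−q/10), 10^(−4))` and qualities capped at Q40. The
biallelic collapse (mismatch mass `e`, not `e/3`) reflects that the two
non-ref/alt bases were already discarded at extraction. Inside the HMM the
haplotype allele is replaced by `θ_{t,k} ∈ {10^(−4), 1 − 10^(−4)}`
(the *theta floor*), so a single panel genotyping error cannot zero out a
likelihood.

### Haploid copying HMM over grids

Alleles are processed in *grids* of 32 consecutive SNPs packed into 32-bit
words; the hidden state at grid `g` is which of `K` conditioning reference
haplotypes the class haplotype copies there. Transitions exist only between
grids, with switch probability
`σ_g = 1 − exp(−n_gen · d_g / 100)` for inter-grid genetic distance `d_g`
in cM (measured between the median-bp SNPs of adjacent grids) and the
uniform-switch kernel: stay `1 − σ + σ/K`, switch to each other state
`σ/K`. `n_gen = 100` is the conventional effective-generations scaling of
this model family. A fragment contributes its per-site emission factors to
the grid each site belongs to, so fragments spanning grids factorize
without duplication. Forward–backward runs in O(GK) per class with
per-grid scaling. Pad bits of the last grid never receive observations and
never enter dosages.

### Read-label Gibbs sampler

Fragment labels are resampled one at a time from the exact conditional:
the prior times the ratio of the class likelihood with the fragment
included versus excluded (only the receiving class's forward pass changes,
so a sweep costs O(V · n_labels · G · K)). In NIPT mode the prior
(0.5, 0.5 − FF/2, FF/2) does not cancel and is part of every conditional;
fragments covering no usable site draw straight from the prior. After each
sweep a *block pass* visits every grid boundary (including the one before
the first grid) and draws, from the exact conditional over that proposal
set, one of the label permutations applied to all fragments starting at or
after the boundary — identity included, so correct states are invariant.
This identifies and repairs phase switch errors, and at boundary zero
offers a global label permutation.

### Two-stage procedure and msPBWT refresh

Stage 1 restricts observations to common SNPs (default folded MAF ≥ 0.01;
rare SNPs carry almost no information about read origin early on) and
iterates `n_outer` rounds of {sweeps + block passes + conditioning-set
refresh} in `n_chains` independent seeded chains, keeping the chain with
the highest joint log probability. One grid frame is used for both stages:
stage 1 simply drops rare-site observations, which keeps the per-SNP
posterior, the msPBWT index and the refresh queries aligned across stages.

The refresh rounds each class's per-SNP alternate-allele posterior to a
hard haplotype, packs it into grid words, and queries the msPBWT: per grid
the 255 most frequent words get ranked symbols (ties broken by ascending
word value) and the remainder share symbol 0 with an exact rare-word
store; index `A[g]` holds the reverse-sorted-prefix order and `U` the
prefix counts that advance an insertion position in O(1) per grid. An
up/down scan around the insertion trace `f` collects the `L` closest rows
with exact match lengths (symbol-0 collisions are resolved against stored
words; the scan terminates early because symbol match length is monotone
away from `f`). Candidates shorter than `min_match_grids` are dropped and
the rest ranked by match length summed over grids, each grid's
contribution divided by the number of candidates covering it (a uniqueness
weighting — the scorer is pluggable since only the objective, length plus
uniqueness, is canonical); per-class selections merge round-robin into K
rows, padded with seeded-random rows on shortfall.

Stage 2 restores all sites and fragments, initializes each fragment's
label to the argmax of its emission against the current class haplotype
estimates (ties drawn from the prior), burns in, and averages the per-SNP
posteriors of the last `n_sample` sweeps into haplotype dosages. Maternal
genotype dosage = classes 1+2; fetal = classes 1+3; diploid = 1+2.

### Label-mode heuristics (NIPT)

Two well-separated failure modes exist because class identity is partly
conventional:

* **Permutation modes.** A labelling in which entire classes are swapped is
  locally stable: single-fragment and block moves rarely cross, because
  relabelling also moves prior-biased uninformative fragments. Stage-2
  burn-in therefore runs once from every global label permutation of the
  stage-1 labelling and keeps the highest joint log probability (diploid
  mode is label-symmetric and runs only the identity).
* **Maternal orientation.** The transmitted and untransmitted maternal
  classes have identical haplotype content models and differ only in read
  share (0.5 vs 0.5 − FF/2). After sampling, fragments decisively
  preferring one maternal haplotype estimate (log-likelihood margin > 2
  nats) are counted, and the classes are swapped if the untransmitted slot
  won more informative reads. This is a maximum-a-posteriori correction
  robust to the prior-driven drift of uninformative fragments.

Phased best-guess genotypes are taken from the final state after three
greedy (iterated-conditional-modes) passes — averaging dosages across
sweeps is correct for dosage but smears phase whenever the chain visits a
permuted mode. Dosages remain sweep averages.

## Tunable parameters

| name | default | meaning |
|---|---|---|
| `K` | 40 | conditioning haplotypes (shared by all label classes) |
| `maf_threshold` | 0.01 | folded-MAF cut defining stage-1 common SNPs |
| `min_match_grids` | 2 | msPBWT match-length filter |
| `scan_L` | 8 | neighbours kept per grid in the up/down scan |
| `n_outer` / `sweeps` | 3 / 30 | stage-1 refresh rounds / sweeps per round |
| `burn_in` / `n_sample` | 10 / 20 | stage-2 burn-in / averaged sweeps |
| `n_chains` | 3 | independent stage-1 chains (best joint log-prob kept) |
| `n_gen` | 100 | recombination scaling (effective generations) |
| `min_mapq` / `min_baseq` | 10 / 10 | alignment and base filters |
| `ff` | — | fetal fraction, required in NIPT mode (typical 0.04–0.5) |

FF is a fixed input (as provided by an NIPT report), not estimated; the
likelihood tolerates mis-specification gracefully because it enters only
through the label prior. Light sampling settings (one chain, few sweeps)
can leave the diploid sampler in the symmetric label-mixed state, which
still yields correct genotype dosages but uninformative phase; the
defaults avoid it.

## Synthetic data

The generator emulates the study design of NIPT imputation benchmarks at
desk scale. The reference panel is a mosaic-of-founders model: founder
haplotypes drawn with a Beta(0.2, 0.2) allele-frequency spectrum (both
rare and common sites; not a population-genetic estimate), remaining
haplotypes copying founders with per-interval switch probability
`recomb_per_snp` plus per-site flip noise `mut_rate`, and a realized
folded-MAF floor enforced post hoc. Defaults (`n_founders=40`,
`recomb_per_snp=1e-3`, `mut_rate=2e-4`, `maf_min=0.002`) were set so that
two independently drawn haplotypes are essentially never identical over a
desk-scale region — with too few founders and too low a switch rate a
"fresh mosaic" is a single founder copy, and the father's transmitted
haplotype collides with a maternal haplotype, a degeneracy real parental
genomes do not show. Sites sit every 100 bp with a flat 1 cM/Mb map.

A family draws mother and father haplotypes as fresh panel mosaics
(related to, but not identical to, panel rows; `exact_rows=True` uses rows
verbatim for oracle tests), and the child carries copies of the mother's
first and father's first haplotype — no intra-region recombination in
transmission, matching the three-fixed-haplotypes model assumption; region
chunking is the intended mitigation in practice. cfDNA fragments cover
contiguous SNP runs (Poisson length, mean `read_len` SNPs), with source
labels drawn from the FF prior, bases flipped independently with
probability `err`, and qualities set to `−10·log10(err)` capped at Q40;
fragment count is set so expected site depth equals `coverage`.

What the generator does **not** emulate: coalescent linkage structure,
GC/mappability bias, sequencing-machine error profiles, ancient-DNA
damage, maternal recombination in transmission, aneuploidy, and real cfDNA
fragment-size biology. Tests passing on this generator therefore show the
*inference machinery* is correct and the accuracy effects point the right
way — not that real-data accuracies are reproduced.

## Verification conditions

The behavioural test suite freezes these study conditions:

* Diploid recovery: panel of 400 haplotypes x 2000 SNPs, target haplotypes
  present in the panel, 4x coverage at 0.1% base error (common-SNP dosage
  r² checked against 0.99), plus an exact-recovery setting — error-free
  long-read-like fragments (mean 100 SNPs) at 20x — in which the problem
  is fully determined and r², NRC, F1 and PSE must reach their ideals.
  Long fragments are required for the PSE ideal: adjacent heterozygous
  sites separated by long identical-by-descent runs are not linked by any
  short fragment, and phase across such a gap is unidentifiable.
* NIPT direction of effect: 10 seeded replicates on a 160 x 512 panel;
  fetal accuracy sweeps run at FF {0.1, 0.2, 0.3} x 1x and coverage
  {0.25x, 1x, 4x} at FF 0.2, both pinned mid-range because fetal accuracy
  saturates at high FF x high coverage and collapses to a panel-frequency
  baseline when almost no fetal reads exist, either of which obscures the
  trend under test; the nipt-vs-diploid maternal comparison runs at
  FF 0.3 x 4x, where the diploid model is most mis-specified.

Problem sizes throughout (panels of 10²–10³ haplotypes, 10²–10³ SNPs) are
the package's chosen desk scale for self-contained verification.

## Numerical choices

* Theta floor `10^(−4)`; base-quality cap Q40; sequencing error floor
  `10^(−4)`.
* Forward/backward passes rescale per grid; emissions are max-shifted
  before exponentiation; all sampling uses `numpy.random.Generator` seeded
  from one `SeedSequence` per run, so results are bytewise reproducible.
* Symbol ranking ties break by ascending word value; neighbour-scan ties
  by scan order (up first, closest first); conditioning-set score ties by
  ascending row index; genotype rounding sends exact .5 dosage ties to the
  heterozygote.
* Degenerate inputs: an empty read set returns prior dosages (the mean of
  the theta columns); a single-grid region makes the block pass a no-op;
  a genetic map not covering the panel span extrapolates flat with a
  warning; zero common SNPs at the chosen threshold is a hard error.
* Output dosages print with 3 decimals; phased genotypes always use `|`.

## Known limitations

* Maternal recombination within the imputed region is not modelled (three
  fixed underlying haplotypes); impute in windows to mitigate.
* FF is not estimated from the data.
* The maternal-orientation correction relies on the FF/2 read-share
  asymmetry and loses power as FF → 0, where the fetal genome is anyway
  uninformative.
* Rare-variant fetal accuracy is limited by the conditioning-set size and
  panel depth; only biallelic SNPs are modelled.
* The sampler's permutation-mode selection is a heuristic; pathological
  regions (very long runs without heterozygous sites) can still leave
  locally ambiguous phase, which the PSE flip-exclusion convention scores
  fairly but cannot remove.
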