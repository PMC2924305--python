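# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`. BED input is
read as-is. GTF/GFF3 and browser-printed coordinates are 1-based inclusive
and converted at the I/O boundary (`GenomicInterval.from_one_based`): a
printed pair (s, e) maps to `[s−1, e)` with length e − s + 1. Array-CGH
breakpoints are a different animal: they name the *edges* of an affected
segment (segmentation-bin boundaries), not inclusive probe positions, so
`GenomicInterval.from_breakpoints(left, right)` treats the segment as
`(left, right]` with length right − left. Peaks without an explicit summit
use the interval midpoint (floor) — the only summit-free proxy available.
Ambiguous bases (N) are permitted everywhere and contribute 0 to log-odds
scores, so peaks at assembly gaps are kept rather than discarded.

## Dimeric PWM model and scanning

A binding site is modelled as two half-site probability matrices
(`half_a`, `half_b`, each width w with per-position base probabilities)
separated by a spacer whose length ranges over a configurable inclusive
interval; the default is {0} (a contiguous site), since p53-family response
elements are predominantly spacer-less, and a degenerate single-block motif
is `w_b = 0`. A placement's score is Σ log2(p_col(base)/bg(base)) over both
half-sites; spacer positions and N bases contribute 0. Zero-probability
cells (possible at pseudocount 0) are floored at −10 bits per position so
scores stay finite and comparable; the floor is deeper than any realistic
column. Scanning maximises over positions × strands × spacers; the reverse
strand is scored by scanning the reverse-complemented log-odds matrix, which
makes the best score of a sequence exactly equal that of its reverse
complement. PWM construction uses per-column
(count + pseudocount)/(n + 4·pseudocount) with default pseudocount 0.25.

Threshold calibration sweeps the union of observed best scores from a
positive and a background set; at threshold t, TP = #pos ≥ t, FP = #bg ≥ t,
FN = #pos < t, and the t maximising F = 2PR/(P+R) wins, ties resolving to
the smallest (recall-favouring) candidate. The FDR at a threshold is
estimated as (background call rate)/(positive call rate), clipped to [0, 1],
and is best computed on a background sample held out from calibration: the
threshold optimisation otherwise sits just above the calibration sample's
points and biases its background rate low (we measured ~0.02–0.04 optimism
at n = 500). ROC AUC uses the Mann–Whitney formulation (ties count ½), so
it is invariant under monotone transforms of the scores.

## Motif significance pipeline

Peaks are split (floor(fraction·n) training sequences, the rest evaluation;
200-bp windows centred on summits). Two backgrounds are built: random
genomic regions matching the peak set's length distribution and
per-chromosome proportions (largest-remainder allocation, exclusion of the
peaks themselves, bounded rejection sampling), and first-order Markov
sequences fit to the peak sequences with add-one smoothing. Each candidate
motif gets its own max-f-measure threshold calibrated on (training set,
Markov background), then a hypergeometric upper-tail test per background
(population = evaluation + background sequences, successes = sequences with
≥1 hit). The reported p is the **larger** of the two backgrounds' p-values —
the conservative reading of requiring enrichment against both — and is
BH-adjusted across candidates (a flag switches the α = 0.001 filter to raw
p-values; adjusted is the default). Significance additionally requires
>1.5-fold enrichment against both backgrounds; the best significant motif
is the one with maximal AUC (ties: narrower width, then lexicographic
consensus).

The built-in discoverer is deliberately simple and is not a reimplementation
of any published motif finder: for each width, the most over-represented
exact words relative to a first-order Markov expectation (canonicalised over
strands, observed ≥2) seed PWMs, each refined by hard realignment — every
training sequence contributes its best-scoring site, the PWM is rebuilt,
and iteration stops when the information content moves < 1e−3 bits (cap 50
iterations). External MEME-format PWMs enter the same evaluation unchanged.

The binomial over-representation test (for comparing a motif library
between two sequence sets) estimates each motif's hit rate in set B and
tests set A's hit count against it (upper tail), Bonferroni-corrected by
the number of motifs with at least one hit in either set.

## Peak annotation

Classification is by summit position, since the summit is the binding-point
estimate the sequence windows are centred on. Per gene, the TSS-flanking
region is 5 kb upstream of the TSS plus the first exon and first intron
(transcription order, strand-aware); intragenic is the rest of the gene
body; near is 5–25 kb upstream or ≤25 kb downstream of the gene end. With
several overlapping genes the priority is TSS-flanking > intragenic > near;
everything else is intergenic, so every summit gets exactly one category.
The enrichment null relocates each peak uniformly on its own chromosome
(length and summit offset preserved) and re-classifies, preserving
chromosome composition; p = (1 + #null ≥ observed)/(1 + n_perm). PTG
mapping is deliberately many-to-many: a gene is a potential target iff any
peak interval lies within 25 kb of the gene interval (overlap counts). The
CTCF-bounded search keeps (gene, peak) pairs within 300 kb whose
nearest-edge gap contains no CTCF site strictly inside it; a site touching
or overlapping either feature does not block (an insulator must separate,
not touch), and overlapping pairs are always kept.

## Conservation

The per-region conservation score (PCCS) is the mean per-base score over
*all* bases of the region, with missing track bases counting 0 (uncovered =
unconserved); the covered fraction is reported alongside so the
present-bases-only alternative is auditable. Cumulative curves report the
fraction of regions at or above each cutoff (the empirical survival
function). The two-set comparison is Mann–Whitney (distribution-free, the
standard choice for conservation scores): exact enumeration when the
smaller set has ≤8 values and no ties, otherwise the normal approximation
with tie correction. Summit windows use floor-based centring for odd sizes
and clip at chromosome bounds with a warning. Quartile summaries stratify
by rank (stable sort, ties broken by input order) into four near-equal
groups.

## Phenotype similarity

Disease profiles are rows of a non-negative disease×term matrix (binary
presence by default; arbitrary weights accepted). Pairwise similarity is
the cosine of the two weight vectors — 0 for disjoint support, 1 for
identical overlap — and a disease set is scored by the mean over all
unordered pairs, computed via ‖Σ unit vectors‖² so large sets stay cheap.
The null is n uniform without-replacement draws of the same size;
p = (1 + #null ≥ observed)/(1 + n), never exactly 0. Note the null draws
come from the whole matrix, so when a large planted cluster exists the null
mean sits somewhat above the background-pair similarity. Term enrichment is
the hypergeometric upper tail of each term's within-set disease count;
top-k% membership of a query term set is again hypergeometric. One caution:
the mean pairwise cosine of a set can *decrease* when a member orthogonal
to a tight majority is duplicated, so no monotonicity under duplication is
claimed (only permutation invariance and the max-pair bound).

## Synthetic data

One master seed fans out to per-generator child seeds by SHA-256 hashing of
generator names, so adding a generator never perturbs the others; all
generators are byte-reproducible under (parameters, seed).

- **Genome**: i.i.d. bases at a target GC (default 0.41, the human value).
- **Default motif**: two identical RRRCWWGYYY half-sites (strong C/G at
  positions 4/7 of each half, 0.85; purine/pyrimidine/weak positions at
  0.45/0.45), spacer {0} — the canonical p53-family response element shape.
- **Peaks**: 200-bp intervals, log-normal heights; with probability
  `planting_rate` (default 0.94, the motif-bearing fraction observed in the
  study conditions this package emulates) a motif instance *sampled* from
  the PWM (not consensus) replaces the genome at the summit, strand
  uniform. Sampling gives calibrated thresholds a realistic score spread —
  which also means a minority of planted sites legitimately score below a
  max-f-measure cutoff (~13% with the default motif); tests assert high
  sensitivity with a wide margin over background, not perfection. An
  optional category mix rejection-samples positions against a gene set.
- **Conservation track**: per-base Beta draws with specified means
  (baseline 0.1, elevated 0.6) and standard deviation (0 = exact means),
  elevated over designated segments.
- **Disease matrix**: 2,033 diseases × 500 terms, background density 0.2,
  with a 904-disease cluster sharing a 12-term block. These defaults come
  from closed-form arithmetic: two random binary profiles of density d have
  expected cosine ≈ d, so d = 0.2 sets the background similarity, and a
  shared block of B terms lifts cluster pairs to ≈ (d²T + B)/(dT + B) ≈
  0.28 at T = 500, B = 12 — the contrast the similarity statistic is meant
  to detect.

What the generators do **not** emulate: real genomes' repeat structure,
GC isochores and gene clustering; correlated conservation (real tracks are
autocorrelated, ours is i.i.d. within a segment); hierarchical disease/term
ontology structure. Passing recovery tests therefore demonstrates that the
statistics recover planted structure under their stated assumptions, not
performance on real data.

## Problem sizes and numerical choices

The recovery suites run at 500 training + 2,000 evaluation peaks with
2,000-sequence backgrounds over 10 seeds (motif recovery), n = 500
positives for FDR calibration, 200 regions per set over 20 seeds
(conservation), and 400×200 matrices over 20 seeds (phenotype) — sizes at
which each effect is comfortably detectable while the whole suite runs in
minutes on one CPU. The acceptance script uses the study-scale 11,369-peak
catalogue and the 2,033/904 disease matrix directly, since both are cheap.
Scanning is vectorised over pre-encoded sequence matrices (one gather-sum
per motif column), which is what keeps candidate evaluation (~150 PWMs ×
~8,000 sequences) tractable.

## Known limitations

- The discoverer's hard realignment can lock onto a shifted register of the
  true motif; recovery is therefore scored as the best per-column
  correlation over shifts and orientations.
- The FDR estimator treats every scanned sequence as potentially null, so
  against a mostly-positive set it estimates the null call-rate ratio, not
  the truth-labelled false share of calls (which is ~(1−q)× smaller at
  planting rate q).
- BH adjustment is not idempotent (re-adjusting adjusted values inflates
  them toward the maximum); adjusted values are computed once per candidate
  batch.
- bigWig tracks are not read natively; convert to bedGraph/wiggle first.
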