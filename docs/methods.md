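# Methods

## Amplicon model

Reads are modelled on the sequencing strand only, starting at the 8-bp sample
index (a configurable leading pad, default 0, records the possibility of extra
adapter bases on real instruments). The layout is fixed: index (8 nt), forward
anchor (17 nt, `GACACTCGAGGATCGAG`), BC (18 nt), spacer (71 or 83 nt), ROI
(8 nt), then the constant reverse region (`CCCTAGAAAGATAATCATATTGT` followed by
adapter sequence) filling the 151-nt read. For the default 71-nt spacer the BC
occupies read positions [25, 43) and the ROI [114, 122) (half-open, 0-based);
with the 83-nt spacer the ROI is [126, 134). The spacer's internal sequence is
design-specific and user-supplied; the shipped defaults are fixed pseudorandom
71/83-mers drawn once from seed 0. Eight default sample indexes are provided;
their minimum pairwise Hamming distance is large enough that the ≤1-mismatch
demultiplexer cannot confuse them.

## PCR simulation

Amplification is simulated at the **species-abundance level**, where a species
is a (clone, ROI-sequence) pair. Within one compartment, each cycle doubles
every species; a fraction `switch_prob` (p) of the newly synthesized copies is
"incompletely extended" and has its ROI redrawn from the compartment's
abundance-weighted ROI marginal. This is a deterministic expected-value
recursion, not a per-molecule simulation: the mechanism of chimera formation
(re-annealing at the shared spacer) is known but its kinetics are not, so a
single per-cycle scalar p stands in for the elongation-time setting, and the
per-molecule picture is retained only as a test oracle. Switching moves copies
between species without creating or destroying any, so total abundance after c
cycles is exactly `initial × 2^c`. Chimeras recombine at the spacer only (BC
from one template, ROI from another); multi-breakpoint chimeras, indels,
polymerase error spectra and sub-2× cycle efficiency are not modelled.

Because switching preserves both the BC and the ROI marginals, the recursion
has an exact closed form

    A_t = (2 − p)^t A_0 + tot0 (2^t − (2 − p)^t) ρ κᵀ,

with ρ, κ the normalised initial BC/ROI marginals of the compartment. The
closed form is what makes the simulator fast: singleton micelles double
trivially, two-molecule micelles are handled vectorised, larger micelles (rare
at realistic occupancy) individually, and bulk (conventional) compartments keep
the rank-1 mixed component symbolic, so a 30 000-clone conventional reaction
never materialises the 30 000² species matrix. Tests assert the per-cycle
recursion and the closed form agree to 1e-10.

A useful consequence for bulk reactions: the expected chimeric fraction after
c total cycles is `(1 − (1 − p/2)^c)(1 − w)`, where w is the probability that
a switch lands on the parent's own ROI sequence (≈ 1/n_clones + 1/4^8 for a
uniform random library). `switch_prob_for_target` inverts this to inject a
chosen chimeric read fraction.

The protocol wrapper runs round 1 (15 cycles by default) on the partitioned
templates, thins the pooled product binomially at the carryover fraction
(1/100 by default, molecule identities resampled abundance-weighted — a
pipetted subsample), and runs round 2 (18 cycles by default) on a fresh
partition (emulsion) or in bulk (conventional). Zero carried molecules raises
an error rather than returning an empty pool. Micelle merging is assumed
absent.

Emulsion partitioning assigns each molecule independently and uniformly to one
of M micelles (multinomial; Poisson with λ = T/M in the M ≫ 1 limit). Note
that round-2 occupancy is determined by the protocol, not by the round-1
dilution alone: λ₂ = λ₁ · 2^c₁ · f for carryover fraction f, so with 15 first-
round cycles and f = 0.01, λ₂ ≈ 328 λ₁. The default parameters
(2×10⁶ templates, 10¹⁰ micelles, λ₁ = 2×10⁻⁴) keep both rounds inside the
10³–10⁴-fold template-dilution rule; at λ₁ = 2×10⁻⁴ the model yields a ~55×
suppression of chimeras relative to conventional PCR, dropping to single-digit
factors as λ₁ approaches 2×10⁻³ because round 2 then dominates chimera
formation.

Read emission samples molecules abundance-weighted, assembles the full 151-nt
amplicon, applies i.i.d. per-base substitutions at `sub_rate` (a single lumped
PCR+NGS rate, default 1e-3; quality strings are constant `I`), and writes
standard 4-line FASTQ (optionally gzipped) plus a truth TSV (read id, source
BC/ROI, chimeric flag, mutated flag) and a JSON parameter sidecar. Output is
byte-identical under a fixed seed.

## Read analysis

Extraction slices at fixed offsets and accepts a read only if the index
matches a known sample uniquely within 1 mismatch, the anchor within 2 and the
spacer within 5 (roughly 1% per-base tolerance, scaled to element length; all
configurable — real pipelines rarely publish these thresholds, so they are
explicit here). Ambiguous index matches are unassigned rather than
best-hit: sample cross-talk is worse than read loss. Failures are statuses
(`bad_index`, `bad_anchor` — also used for spacer failures — `bad_alphabet`,
`too_short`), and the status counters partition the input exactly.

Barcode collapse is greedy and directional: candidates in descending count
(ties lexicographic); a candidate joins the nearest already-seeded barcode
within 2 substitutions that has a strictly greater count (ties: more reads,
then lexicographic), otherwise it seeds its own cluster. The ≥2-read filter
applies to cluster totals, members included (whether the support rule should
count the intact sequence alone is ambiguous in practice; cluster totals are
the default, the alternative is a parameter). A variant within reach of two
seeds joins the better one by default; `ambiguous="drop"` discards such
variants instead. An exhaustive O(n²) all-pairs oracle with the same ordering
rules is kept in the test suite and must agree exactly.

Per genuine barcode, ROI counts are pooled over cluster members; the genuine
ROI is the one with a strict majority (> 0.5 — exactly half fails). Reads are
then partitioned by Hamming distance to the genuine ROI: 0 genuine, 1 error,
≥2 chimeric. The sample percentage is 100 × chimeric / total over barcodes
with a defined genuine ROI; barcodes without one are excluded from numerator
and denominator (configurable to `all-parsed`). Condition averages are
unweighted arithmetic means — this reproduces the shipped reference tables'
printed Average columns exactly, which a read-count-weighted mean does not.
Fold changes are plain ratios reported to 2 significant figures. Histograms of
per-BC chimera proportion use 50 equal-width bins on [0, 1] by default,
averaging per-BC proportions across replicates over the shared barcode set.

## Occupancy model

`occupancy_pmf` is the Poisson pmf at λ = T/M (exact multinomial occupancy is
kept in the Monte-Carlo test oracle only). `distinct_pair_fraction` assumes k
equally abundant variants (1 − k^(1−j) for j co-encapsulated templates);
weighted abundances are out of scope. `chimera_potential` sums
P(j) · j · (1 − k^(1−j)) / λ over j = 2..60, the per-template probability of
having a distinct-variant micelle partner; the j-truncation error is < 1e-12
for λ ≤ 10.

## What the simulator does and does not establish

The generator emulates: tens of thousands of unique clones (default demos use
30 000; analysis runs 1 000), chimera rates of order 0.2–1.6%, BC substitution
variants within 2 nt and ROI variants within 1 nt at sub_rate 1e-3, replicate
samples distinguished by 8-bp indexes, and the emulsion/conventional contrast.
It does not emulate: quality-score structure (constant qualities), indels,
position- or context-dependent error rates, template-abundance skew (uniform
weights by default), primer artifacts, or micelle size heterogeneity. Passing
recovery tests therefore show the *analysis logic* is correct under the stated
error model, not that real libraries are free of these additional effects.

## Problem sizes and numerical choices

Simulation studies use 20 000 template molecules with micelle counts chosen to
preserve λ (occupancy statistics depend only on λ₁ and λ₂ = λ₁·2^c₁·f, both
scale-free), 1 000-clone libraries and 5×10⁵ reads — sizes at which binomial
sampling error (3 SE ≈ 0.05 percentage points at 1.5%) is well below the
effects of interest. Recovery is asserted within 3 binomial SE; Monte-Carlo
oracles within 3 SE of their own sampling distribution; exact identities
(conservation, closed form vs recursion) at relative tolerance 1e-10 to 1e-12.
Tabulated report values use half-up decimal rounding at the table's printed
precision. All randomness flows through `numpy.random.default_rng` seeds;
fixed seeds make every test and script deterministic.

## Known limitations

* The expected-value recursion reproduces mean behaviour; it understates
  stochastic clone-to-clone variance in chimera proportions at very low copy
  numbers (the per-molecule branching process is only used as an oracle at
  toy scale).
* `switch_prob` is a free parameter: no rate law links it to elongation time,
  so elongation-time comparisons are represented as user-chosen pairs of
  switch probabilities.
* The ≥2-read and frequency->0.5 rules assume per-clone coverage well above
  the thresholds; at coverage ~2-5 reads per clone, dropout and undefined
  genuine ROIs dominate (visible as the mid-range peak in per-BC histograms).
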