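# Methods

## Model

`pctraff` treats a promoter set the way collocation statistics treats a
corpus: sequences are sentences, binding-site types are words, and a TF
pair "collaborates" when its two site types co-occur at short range more
often than their individual frequencies explain. The analysis assumes that
(i) binding-site predictions are exchangeable evidence — no use is made of
scanner scores beyond the hit positions; (ii) functional coupling expresses
itself as a positional association at a characteristic midpoint distance
(d_min–d_max); and (iii) false-positive predictions contribute a product-
shaped background (each type's propensity to pair with anything) that the
average product correction can estimate and remove.

### Phase 1 — TFBS–sequence matrix and column filters

f_ij is the count of type-j sites in sequence i. Two single-pass filters
operate on the columns, each with its threshold computed on its own input
matrix (thresholds are not recomputed after removals, and the filters are
not iterated to a fixed point):

* **Over-representation:** remove column k when its sum exceeds 3σ, where σ
  is the *population* standard deviation of the column-sum vector. The rule
  compares the sum itself (not its deviation from the mean) with 3σ, so it
  presupposes the strongly dispersed column sums of a realistic motif
  panel; for a perfectly homogeneous matrix σ = 0, which we treat as
  "filter disabled" rather than removing every column.
* **Sparsity:** remove columns with strictly more zero entries than the
  per-column average ("more than" is read as strict, which keeps perfectly
  homogeneous matrices intact).

### Phase 2 — importance

PMI(s_i; t_j) = log₂ [ (f_ij/T) / ((r_i/T)(c_j/T)) ] with T the grand
total, r_i, c_j row/column sums. Cells with f_ij = 0 have no finite PMI and
are excluded rather than carried as −∞ sentinels. A cell is *important*
when its PMI is strictly positive; all hits of non-important (sequence,
type) combinations are dropped. No multiplicity correction is applied at
this stage. The matrix is built from the raw hit list, before the Phase-3
overlap filter.

### Phase 3 — same-type overlap resolution

Within each (sequence, type) group, hits are clustered by transitive
interval overlap (half-open intervals; touching is disjoint). One survivor
per cluster: smallest |midpoint − TSS|, ties broken by smaller start, then
"+" strand. Midpoints are start + ⌊length/2⌋. Transitive closure makes the
outcome independent of elimination order; distance to the TSS is absolute
in sequence coordinates.

### Phase 4 — pairing

Candidate pairs are same-sequence hit pairs with midpoint distance in
[d_min, d_max]; different types may overlap by at most `max_overlap` bases,
same types not at all (Phase 3 already guarantees this). Homotypic-cluster
de-duplication: per sequence and per unordered pair type, candidates are
scanned in 5′→3′ order (left midpoint, then right midpoint) and counted
greedily while neither participating hit has been counted for *that* pair
type; a hit may still be counted once for every other pair type. Pairs are
unordered and canonicalized lexicographically; homotypic pairs (a,a) are
permitted. Strand plays no role in pairing.

### Phase 5 — weighted cumulative PMI

All probabilities derive from pooled pair-instance counts F(a,b), T = ΣF:
p(a,b) = F(a,b)/T, and slot marginals p(a) = C(a)/2T with
C(a) = Σ_{b≠a} F(a,b) + 2 F(a,a), so Σ_a p(a) = 1 and
PMI(a;b) = log₂ p(a,b)/(p(a)p(b)) is the standard unordered bigram form.
Sequence weights w_s = N_s / Σ N_s (N_s = pair instances in s). Each pair's
score is PMI_pc(a,b) = (Σ_{s ∋ (a,b)} w_s) · p(a,b) · PMI(a;b), i.e. the
*global* joint probability and PMI damped by the weight mass of the
sequences actually containing the pair.

### Phase 6 — APC and significance

Per-type mean: PMI_pc(a; ·) = (1/(n−1)) Σ_{x=1..n} PMI_pc(a,x), the sum
running over **all** n participating types including x = a — the homotypic
term enters when the pair (a,a) was observed and contributes 0 otherwise —
while the denominator stays n−1. The overall mean averages PMI_pc over
every scored pair: all n(n−1)/2 heterotypic type slots (unobserved slots
count as 0) plus observed homotypic pairs. Then
APC(a,b) = PMI_pc(a;·)·PMI_pc(b;·)/overall_mean (defined as 0 in the
degenerate overall_mean = 0 case) and corrected = PMI_pc − APC. A uniform
heterotypic score structure is removed exactly: all corrected values are
identically 0, so structureless input can produce no significance.

z-scores standardize the corrected values over the scored universe
(heterotypic slots plus observed homotypic pairs) using the sample standard
deviation; zero spread means nothing is significant. Significance:
z ≥ z_threshold (default 3). At least two observed pair types are required.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| d_min | 5 | bp | ≈ half an average binding-site length; excludes trivial adjacency |
| d_max | 20 | bp | short-range cis-regulatory coupling; 50/100 supported for wider scans |
| max_overlap | 4 | bp | small inter-type overlap tolerated between distinct motifs |
| z_threshold | 3 | sd | conventional 3-sigma call on corrected scores |
| min_score | 0.85 | — | stand-in scanner's min-max–normalized log-odds cutoff |

All are configurable per run (YAML config or CLI flags).

## Stand-in PWM scanner

The scanner exists so the pipeline is runnable without any external
scanner: per-position log₂-odds against background base frequencies
estimated from the scanned set, pseudocount 0.01 × column total per cell,
window score min-max normalized so the best attainable window scores 1.0
and the worst 0.0. Both strands are scanned (reverse-complemented matrix on
the forward sequence; coordinates always forward-strand); windows containing
N never produce hits, and hits are never clipped at sequence boundaries —
out-of-range windows simply do not exist. Any monotone scorer is adequate
here because downstream phases consume only hit positions; precomputed hit
tables from any scanner can be supplied instead.

## Synthetic spike-in generator

The generator emulates the classic positive control: real promoters with a
known interacting pair planted at coupled positions.

* **Background:** i.i.d. bases with P(G)+P(C) = 0.41 (human-like GC),
  200 sequences × 1000 bp, TSS at the 3′ end.
* **Planted pair:** synthetic IRF-like (`TTTCACTTTC`) and E-box-like
  (`CACGTGAC`) consensi — both deliberately non-palindromic — inserted as a
  tandem block (motif_a, g background bases, motif_b) with g ~ U{5..20},
  k ~ U{2..12} insertions per sequence at uniform non-overlapping
  positions, overwriting background so sequence length is preserved. The
  truth table records every insertion. Note the *spacer* g is what the
  generator controls; the pipeline's midpoint distance equals
  g + ⌈L_a/2⌉ + ⌊L_b/2⌋ = g + 9 here, so with d_max = 20 only insertions
  with g ≤ 11 are countable as pairs — the detection signal rests on that
  subset, which is the harder and more realistic setting.
* **Decoys:** 12 motifs of 6–10 bp inserted independently per sequence
  (Poisson counts, uniform positions, no coupling). Their per-type rates
  are spread log-like from 0.2 to 9 insertions/sequence with panel mean
  equal to `decoy_rate` (default 3). The dispersion is deliberate: real
  motif libraries produce hit counts spanning orders of magnitude, and the
  Phase-1 3σ filter is built for exactly that regime — a flat decoy panel
  would make the column sums nearly homogeneous and the literal 3σ rule
  would remove everything. On default data the filter removes the most
  promiscuous decoy and the sparsity filter the rarest ones, leaving the
  planted pair plus a mid-frequency decoy panel, as intended.

What the generator does **not** emulate: chromatin context, repeats,
dinucleotide composition, real promoter GC heterogeneity, and scanner
false-positive structure. Passing spike-in tests therefore demonstrates
that the statistic recovers positional coupling against independent noise
of realistic rate structure — not performance on real genomes.

## Numerical choices

Coordinates are 0-based half-open everywhere internally. Counting and
pairing are pure integer operations; scores are double precision with
probabilities formed as count ratios (cross-checked against an exact
rational-arithmetic oracle to 1e−9 in the tests). Column/zero-count
thresholds use strict inequalities as documented. All randomness flows
through a single `numpy.random.Generator` seeded from the run seed, and
reruns are bit-identical. Test and benchmark problem sizes (200 × 1000 bp,
20 seeds per stochastic claim) keep the full suite within a few minutes on
one CPU while leaving the planted-pair detection margin large.

## Known limitations

* The literal 3σ column rule removes *every* column of a near-homogeneous
  matrix; the σ = 0 guard covers only the exact-degenerate case. Input with
  tightly clustered column sums should disable `filters.overrepresented`.
* On decoy-only data (no planted coupling) the null is not perfectly clean:
  Phase-2 importance selection keeps a type's hits precisely in the
  sequences where it is over-abundant, which induces mild homotypic
  co-occurrence for the most frequent types. In the test suite's 20-seed
  negative control, ~1.6% of scored pairs (roughly one homotypic decoy pair
  in half the runs, z ≈ 3.2–4.0) cross the z ≥ 3 line. Homotypic calls just
  above threshold deserve skepticism on real data too.
* The z-score is a *relative* statistic over the scored universe: once a
  pair dominates, its z saturates near (k−1)/√k for k scored pairs, and
  raising the true signal further can even lower its z, because chance
  pairs involving the planted types ("spillover") widen the corrected-score
  spread. The corrected score PMI_pc^APC itself grows monotonically with
  signal; rankings are stable. Compare corrected scores, not z magnitudes,
  across datasets of different signal strength.
* The greedy 5′→3′ disjoint matching of homotypic clusters is one defensible
  reading of the cluster-de-duplication rule; chained matchings would count
  differently. The choice is isolated in `pairing.enumerate_pairs`.
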