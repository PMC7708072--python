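# Methods

## The problem

Characterising a Cas9 nuclease requires knowing its protospacer adjacent
motif (PAM): the short sequence 3′ of the target that the protein must
recognise before cleaving. `pamscreen` implements the computational side of
that characterisation for depletion screens over a fully randomized 7-nt PAM
region, plus the two companion analyses such studies rely on: windowed indel
quantification of editing in cells from targeted amplicon sequencing, and
reconstruction of the processed crRNA/tracrRNA species from small-RNA
fragment coordinates.

## Depletion screen model

A 7N library holds all 4⁷ = 16,384 PAM variants around a fixed protospacer.
Exposure to the nuclease (in vitro cleavage, or plasmid interference inside
bacteria) removes cleavable members; sequencing the survivors next to an
unexposed control reveals which PAMs are functional. Per variant *i* the
statistics are:

* depletion coefficient
  `Dcoef_i = log2( (N_sel / N_ctl) · (n_ctl,i / n_sel,i) )`,
  where `n` are variant read counts and `N` sample totals; positive values
  mean depletion. A pseudocount of 0.5 on both variant counts (never on the
  chi-square) keeps the statistic finite when a variant drops to zero; the
  original formulation does not address zeros, so this is a package choice.
* a Pearson chi-square on the 2×2 table
  `[[n_sel, N_sel − n_sel], [n_ctl, N_ctl − n_ctl]]` (df = 1, no continuity
  correction), one-sided by halving: `p = p₂/2` when the selected proportion
  is below the control proportion, else `1 − p₂/2`. A variant is *depleted*
  when `p < α` with the raw threshold `α = 10⁻¹²` (no multiple-testing
  correction by default; a Bonferroni switch exists). Tables with a zero
  expected cell are treated as uninformative (`χ² = 0, p = 1`).

The depleted set feeds three models:

* **Position profile** — a 4×7 frequency matrix, each depleted PAM counted
  once (as when a sequence list is handed to a logo tool); information
  content per column is `2 − H` bits with `0·log 0 = 0` and no small-sample
  entropy correction (appropriate at the thousands of sequences these
  screens yield).
* **IUPAC consensus** — a column with information below 0.3 bits reads `N`;
  otherwise the code covers every base with frequency ≥ 50% of the column
  maximum. Both thresholds are package defaults chosen so that clean,
  deeply sequenced screens read off their motif exactly; a study reading a
  logo by eye has no algorithmic equivalent, so some convention is needed.
* **PAM wheel** — counts are first marginalised onto an ordered position
  subset (default positions 5–7), the depletion coefficient is computed on
  the marginal counts (not averaged over 7-mers), and sub-k-mers with
  positive coefficients become a nested ring chart: ring 1 is the position
  closest to the protospacer; a leaf's angular share is its coefficient over
  the positive sum, internal nodes aggregate children. Serialised as
  Krona-style tab-delimited text and JSON.

## Read processing

Screen reads are amplicons with fixed flanks, so the degenerate region is
recovered by anchored matching rather than general alignment: the two
flanking anchors must match with at most one substitution each (no indels —
an anchor indel shifts the block, so such reads are rejected). Placements
are ranked best-first (exact anchor pairs beat mismatched ones) and an
ambiguous read (two placements in the best tier) is rejected. Quality
control keeps reads whose arithmetic mean Phred score is ≥ 20, boundary
inclusive. Both a per-read extractor and a vectorised matrix path exist;
they implement the same contract.

## Synthetic screens

The simulator is the test bed for every stage and defines the study
conditions:

* library: uniform over 16,384 variants by default (skewed weights
  supported); sequencing depth 2×10⁶ reads per sample.
* selection: a hidden IUPAC rule; matching members are removed with
  `cleave_prob` (0.95 in the recovery checks), non-matching with
  `background_prob` (0). `in_vitro` mode sequences the surviving pool
  multinomially. `interference` mode inserts a colony bottleneck —
  50,000 draws with replacement before sequencing, for both the
  locus-carrying and control cells — reflecting a transformation screen
  harvested from >50,000 colonies; the bottleneck size beyond that figure
  is an assumption, not a measured fact.
* errors: independent per-base substitutions (default 0.1%, about Q30),
  uniform over the three alternatives; quality strings are constant Q30 and
  do not mark error positions. No PCR duplicates, chimeras, adapters, or
  quality-by-cycle structure.
* ground truth (rule, per-variant true counts) is returned separately and
  written as a JSON sidecar, never leaked through read names.

**Known property of the interference mode.** With a 50,000-colony
bottleneck, the effective sampling unit is the colony, not the read; at
2×10⁶ reads the per-variant counts are strongly overdispersed relative to
the multinomial and the raw chi-square call becomes anti-conservative — in
simulation a rule-free majority of “depleted” calls appears and the
consensus degrades. This is a property of the raw-threshold chi-square
procedure itself, not of the simulator, and is consistent with real
interference screens calling far fewer depleted PAMs than match the motif.
Consensus-recovery checks therefore run in the `in_vitro` mode, whose
multinomial sampling matches the test's assumptions; the interference
mode's overdispersion is itself asserted in the test suite. A
dispersion-aware (e.g. beta-binomial) call would be the remedy but is out
of scope.

Passing recovery tests on these simulations shows the pipeline inverts its
own generative model at realistic depth and error rates; it does not show
robustness to real-data artifacts the simulator omits (PCR jackpots,
position-dependent error, library synthesis bias).

## Amplicon indel quantification

Read pairs are merged on their maximal 3′ overlap (≥ 10 nt, ≤ 10%
mismatches, disagreements resolved toward the higher-quality base). Merged
reads with substitutions in the primer footprints are discarded — primer
sequence is fixed by the assay, so mismatches there indicate a bad read; the
threshold is 0.30% errors per primer base (mean + 1 SD of the commonly
cited Illumina substitution error rate of 0.24 ± 0.06%), which in practice
discards any read with ≥ 1 substitution in ~20–25-nt footprints. Whether the
original procedure applied that rate per read or per batch is unstated; per
read is implemented.

Each surviving read is globally aligned to the reference with free end gaps
(match +2, mismatch −1, gap open −6, gap extend −0.5 — values chosen to
consolidate indels rather than scatter mismatches); every indel is then
left-normalised (shifted to its leftmost sequence-equivalent placement) so
that calls are invariant to aligner tie-breaking inside homopolymers. The
cut site sits 3 nt 5′ of the guide's 3′ end (the Cas9 blunt cut),
strand-aware; the quantification window is the 20 reference positions
centred on that boundary. A read is *modified* iff an insertion or deletion
overlaps the window; substitutions never count (they are indistinguishable
from sequencing error at these depths). Reads under 60% alignment identity
are excluded as unalignable. Sample editing is
`indel% = 100·modified/analyzed`, and net editing subtracts the
untransfected control's percentage (floored at zero in summaries, raw value
retained).

Replicate significance uses a one-tailed Mann–Whitney U test (alternative:
treated > control), reported as `min(U_treated, U_control)` so complete
separation in the expected direction gives U = 0. For total n ≤ 12 the
p-value is exact by enumerating all C(n₁+n₂, n₁) assignments of the pooled
midranks (ties therefore handled exactly); larger samples use the
tie-corrected normal approximation. The smallest attainable one-tailed p
for 3 vs 3 is 1/20 = 0.05.

The amplicon simulator plants exactly one indel per modified fragment with
its left edge at the cut site, sizes drawn from a default spectrum
dominated by ±1–3 events; real repair outcomes (multi-indel alleles,
microhomology deletions away from the cut) are richer.

## Small-RNA boundaries

Fragments are clustered greedily by strand and both end coordinates
(tolerance ±2 nt): the most-supported exact coordinate seeds a cluster,
the boundary estimate is the support-weighted median of each end
(recentred until stable), and satellite clusters whose boundaries fall
within tolerance of a stronger unit are merged. The median is used rather
than the mode because a flat end-noise distribution has no identifiable
mode. Units need ≥ 5 supporting fragments; leftovers are reported
unassigned. Reconstructed units are filtered to 40–130 nt (inclusive) and
intersected with the CRISPR-array annotation, strand-aware, to split
crRNA length into spacer-derived and repeat-derived segments. When end
noise spans the full tolerance window the greedy pass can still split one
species into a dominant unit plus minor satellites; boundary estimates of
the dominant unit stay within the jitter, but support counts then
undercount the species — a documented limitation.

## Problem sizes

Simulation-backed checks use depth 2×10⁶ reads per screen sample (the
depth regime of the real screens), 10 seeds per recovery rule, 20
selection-free seeds at 2×10⁵ reads for the type-I check, 10,000 read
pairs per amplicon sample, and 2,000 small-RNA fragments — sizes at which
every sampling-error bound asserted in the tests is meaningful.

## Numerical and degenerate-input choices

* Chi-square p-values come from `scipy.stats.chi2.sf`; the statistic is
  computed vectorised over all variants.
* `Dcoef` is ±∞ without a pseudocount when a count is zero; with the
  default pseudocount it is always finite.
* Empty count tables, empty depleted sets, and all-nonpositive wheels all
  return empty results (with a warning for the wheel) rather than erroring.
* Depletion records sort by descending `Dcoef`, ties broken
  lexicographically by PAM; unit reconstruction breaks ties toward the
  leftmost coordinate — all outputs are deterministic for a given seed.
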