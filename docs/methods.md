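# Methods

## Entropy score

The per-residue tolerance score is the Shannon entropy, in nats, of the
softmax over the residue's 20-element substitution LLR vector.  The
wild-type letter is included with LLR fixed at 0 (a ratio of the wild type
to itself); this is the only convention under which the all-zero vector
gives exactly ln 20 and the published class thresholds (conserved ≤ 0.5,
flexible ≥ 2.0, maximum ≈ 3) are consistent — they only make sense on the
natural-log scale.  The score is computed through a log-softmax for
numerical stability and clipped to [0, ln 20] against rounding.  Thresholds
are applied inclusively as written: a score of exactly 0.5 is conserved,
exactly 2.0 flexible, and pLDDT exactly 70 disordered.

One property worth recording because it is easy to get wrong: entropy is
*not* monotone under lowering an arbitrary non-maximal LLR entry.  For a
state with softmax weight p, dH/dp = ln((1−p)/p) − H(rest), which is
negative when p is sizeable and the remaining distribution is broad, so
making such a substitution more deleterious can *raise* the entropy.  The
monotonicity that does hold — and that the tests assert — is for the
minimum-weight entry, where ln((1−p)/p) ≥ ln 19 ≥ H(rest).

Nonstandard letters (X, U, B, …) are rejected at parse time; the alphabet
is strictly the 20 canonical residues in the fixed column order A…Y.
Initiator methionine is scored like any residue; methionine is excluded
only from the per-amino-acid correlation, where its frequent initiator
position biases substitution predictions.

## Conservation

Percent identity of a homolog is matches over the *full* aligned length,
including gap columns, so fragment homologs score low and are removed by
the 20% floor (inclusive: exactly 0.20 is kept).  The conservation score of
reference position i is n_match/n_nongap over homologs only — the reference
is not counted in either total, since the quantity measures occurrence of
the reference residue *in homologs*; including it would only add a constant
+1/+1.  Columns where every homolog has a gap yield a missing value, not 0:
zero would assert observed divergence where there is no evidence, and
downstream statistics skip missing values.  Columns where the reference has
a gap carry no reference residue and are dropped, with positions renumbered
over reference residues.  A3M lowercase insertion letters are stripped
per-row (they do not exist in reference coordinates) and `.` is read as a
gap; identity comparison is case-insensitive after normalisation.

## Motif discovery

The scan semantics follow the motif definition "average score 0.5 or
lower": an anchor needs score ≤ 0.5, extension continues while the running
mean is ≤ 0.5 (a mean of exactly 0.5 is not a breach), and an open segment
that reaches the terminus is emitted.  Because a value ≤ 0.5 added to a
mean ≤ 0.5 cannot push the mean over 0.5, every breaching residue itself
scores > 0.5, so restarting the anchor search at the breach point is safe.

The two directional candidate sets are intersected at residue level (the
union of each direction's positions, then set intersection), since
candidates need not pair one-to-one across directions; contiguous runs are
re-extracted as intervals.  A run of the intersection carries no mean
guarantee (a subsegment of a ≤-threshold segment can exceed the threshold),
so runs with mean > 0.5 are discarded — the conservative reading that keeps
the published motif definition true of every output.

Merging replaces two motifs whose gap is within 8 residues by the spanning
interval when its mean is strictly below 0.5.  Merging runs to a fixpoint
*best-first*: at each step the eligible adjacent pair with the lowest span
mean merges (ties leftmost), and a merged interval may merge again.  A
single left-to-right pass was rejected because it is direction-asymmetric
when three candidates interact (the pass never reconsiders an earlier
neighbour after a later merge), which would break the mirror-symmetry
invariant — reversing the sequence must mirror the motif set.  Best-first
selection is reversal-invariant whenever span means are tie-free; exactly
tied palindromic configurations are ambiguous under any deterministic rule
and are resolved leftmost.  Motif scanning is region-restricted to each
disordered region by default (whole-protein scanning is available), and
motifs shorter than 4 residues are dropped, a robustness choice exposed as
a parameter.

A related caveat: re-scoring a protein as 0 inside reported motifs and 3
outside reproduces the motifs exactly only when adjacent motifs are more
than the merge gap apart; closer motifs legitimately merge on the rescored
pattern because a thin gap of 3-valued residues cannot hold the span mean
above 0.5 next to long zero runs.

## IDR annotation

All intervals are 1-based and inclusive (UniProt convention, deliberately
not BED half-open).  Coverage of a phase-separation segment is overlap
length over segment length; an IDR overlapping several segments takes its
maximum coverage, and coverage exactly 0.5 is participating ("over 50%" is
strict for driving).  The redundancy filter uses a global alignment with
unit match score, zero mismatch and linear gap penalty −1, identity defined
as matches over alignment length; the filter is a greedy pass in input
order and removes a protein only when identity with an already-retained one
*exceeds* 0.50.  The 10% disorder floor is inclusive.

## Group statistics

Mann–Whitney comparisons are two-sided.  For combined n ≤ 12 the p-value
comes from full enumeration of label assignments with midrank ties,
p = min(1, 2·min(P(U≤u), P(U≥u))); enumeration is exact where it is cheap
(C(12,6) = 924 arrangements) and the crossover is testable at the boundary.
Larger samples use scipy's tie-corrected normal approximation.
Significance tiers use strict inequalities: p = 0.05 is †, p = 0.10 is n.s.

Per-amino-acid profiles average the 20-element LLR vectors of all residues
of each letter; letters absent from a population give empty profiles, and
such letters are skipped (not imputed) in correlations.  Clustering embeds
the 20 mean-LLR vectors in 2-D and cuts an average-linkage tree at five
clusters, labelled by ascending cluster-mean entropy score (group 1 = most
conserved).  The embedding is pluggable: deterministic PCA by default —
the nonlinear neighbour-graph embedding (UMAP, seeded) is optional because
it is seed-sensitive, and the five-cluster contract is what matters, not
the embedding coordinates.

## Synthetic data generator

The generator emulates the statistical structure the analysis targets:

* alternating folded/disordered runs with pLDDT drawn uniformly from
  [80, 98] and [35, 68];
* sequences whose disordered runs are enriched (weight 3×) in the
  disorder-typical letters G, S, P, Q, K, R, E and folded runs mildly
  (1.5×) in hydrophobics — a fixed modelling table, not an empirical
  composition;
* planted motifs inside disordered runs whose non-wild-type LLRs are
  Normal(−8, 0.5) against a Normal(0, 0.3) background (wild-type entries
  0), giving motif sites entropy ≈ 0.03 nats and background ≈ ln 20;
* homologs sampled i.i.d. per site from the softmax of the site's LLR
  vector (Gumbel-max sampling), 200 per protein, with gaps injected at 2%
  per column.  This makes the score–conservation coupling a mathematical
  consequence inside the test-bed: a conserved site's expected homolog
  agreement is 1/(1+19e⁻⁸) ≈ 0.9937;
* phase-separation segments placed by group: driver-like proteins get a
  segment inside a slightly extended motif-bearing disordered run (so the
  run covers > 50% of it), client-like proteins a segment mostly outside a
  run (≈ 20% overlap), background proteins none.

Motif planting is **density-controlled**: the motif count targets a fixed
fraction of the protein's disordered capacity (default 0.16 at multiplier
1), scaled per group by multipliers 0.25 / 1.5 / 2.7 for the background /
client / driver gradient.  The rationale is a power analysis of the
group-comparison design: two groups differing only in motif density have a
rank-test effect θ = ½ + Δf/2, and the null standard deviation of θ̂ at
500 residues per group is ≈ 0.018, so adjacent conserved-fraction gaps of
≈ 0.2 (fractions ≈ 0.04 / 0.24 / 0.43) are required for the gradient to be
detected essentially always.  The driver density is capped near 0.45 by the
spacing of 7 background residues kept between planted motifs — itself the
smallest spacing the merge step can never bridge, since a merge would need
3s < 0.5(m+s), impossible at s = 7 for combined motif lengths ≤ 30.
Count-distribution planting (3–4 motifs at multiplier 1) remains available
by setting the density to None.  A protein whose drawn geometry cannot host
the target count raises a generation error; the dataset generator redraws
such a protein from a fresh deterministic substream (at most 20 attempts),
which carries no selection pressure on disordered capacity because the
target scales with capacity.  Indels are uniform per homolog and column; no
phylogeny is simulated — a tree would add realism but no test power for
the implemented statistics.

### What passing on synthetic data does and does not show

The generator's idealisations are deliberate and visible in the results.
Background sites (including folded runs) are maximally tolerant, so
homologs of motif-poor proteins fall below 20% identity and their
conservation tracks come out empty with a logged warning — real folded
domains are conserved and anchor alignments.  The two-level score
distribution also caps the *unstratified* per-site rank correlation between
score and conservation near −0.55 regardless of sample size (within each
level the ranks are noise), while the disorder-stratified Spearman reaches
≈ −0.73 and the Pearson correlations are ≈ −0.999; correlation analyses in
this package are therefore stratified by structural order, and all three
values are reported.  Passing tests demonstrate that the algorithms recover
planted structure under the stated conditions, not that real proteomes
behave this way.

## Problem sizes

The test suite and the reproduction script run the study at sizes chosen to
keep the whole analysis comfortably interactive: motif recovery over 20
seeds (one driver-like protein each), coupling statistics on 3 proteins
with 200 homologs, the group trend over 10 seeds with 16 proteins per group
subsampled to 500 disordered residues per group (systematic, evenly spaced
subsampling, so the sample composition matches the group's planted
density), motif membership over 10 seeds of 2 proteins, and determinism on
a 6-protein dataset with 30 homologs.  All randomness derives from a single
user seed via fixed integer salts.

## Known limitations

* LLR matrices are consumed as tables; running a language model, AlphaFold
  or a homology search is out of scope.
* The MSA simulator has no phylogenetic correlation between homologs, so
  conservation-score standard errors on real alignments will be larger than
  the i.i.d. ones observed here.
* The pairwise-identity scheme of the redundancy filter (unit match, linear
  −1 gaps) is one reasonable choice among several; synthetic results do not
  depend on it, real-data funnels may.
* Exactly tied span means in motif merging are resolved leftmost; such
  configurations cannot be handled symmetrically by any deterministic rule.
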