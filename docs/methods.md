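# Methods

## Model and assumptions

All coordinates are gene-order ranks: the n-th gene on a chromosome has
rank n, and the "length" of a chromosome is its gene count. This is the
only unit system in which the collinearity index MI = Σ Δy / len is a
dimensionless coverage fraction, so the len files consumed here must give
gene counts, not base pairs. Internally y increases toward the *top* of a
box (the upper-left corner carries the larger y); figures flip the y axis
so reference chromosomes read top to bottom, as Ks dotplots are
conventionally drawn.

The pipeline assumes that a retained genome copy appears as a set of
near-diagonal dot runs whose boxes, after merging, tile the reference
chromosome roughly once per copy. It does not model inversions explicitly
(an inverted segment is still one box), does not date events (no molecular
clock), and does not attempt cross-chromosome joint optimisation: each
reference chromosome is analysed independently and the genome-wide call is
the mode.

## Stage parameters

| parameter | default | units | role |
|---|---|---|---|
| eps | 50 | rank | DBSCAN neighbourhood radius (Euclidean on (x, y)) |
| MinPts | 3 | dots | DBSCAN core threshold (point itself included) |
| Ks range | 0–2 | — | display window; dots outside are dropped before clustering |
| min_num | 5 | dots | boxes with fewer gene pairs are discarded before merging |
| gap | per unit | rank | mean positive vertical gap between adjacent boxes of the unit |
| Slen | len(chr1)/6 | rank | horizontal merge bound, from the *target* chromosome length |
| y_overlap_tol | 0 | rank | allowed y-overlap between round members |
| min_boxes_per_chr | 2 | boxes | reference chromosomes with fewer regions are not analysed |

Distance metric: the clustering radius is interpreted in rank units with
the Euclidean metric (the alternative, Chebyshev, differs only near the
corners of the eps ball and was not adopted). Ks filtering precedes
clustering because the labeled plot only ever shows the 0–2 window.
Noise dots (no DBSCAN label) take no further part. `min_num` is not fixed
by convention; 5 was chosen as the default because it must be at least
MinPts to mean anything and should stay small enough to keep fragmented
remnants of older events visible; it is exposed as `--min-num`.

## Merge semantics

`y_gap`/`x_gap` are signed interval distances between box projections
(positive = separation, 0 = touching, negative = overlap). The merge
conditions are listed in the README; two points were genuinely open and
resolved as follows. Boxes overlapping on *both* axes (nested or crossing)
always merge — each single-overlap clause is satisfied with a zero gap.
`gap` is computed once per unit from the pre-merge (min_num-filtered)
boxes, not re-derived inside the merge loop, so the fixpoint is reached
under a fixed parameter set. Merging repeats "fuse the first mergeable
pair, scanning pairs in a fixed order" until no pair merges; the union box
is the tight bounding box with num = sum of parts. The fixed scan order
makes the result reproducible even if, on a pathological configuration,
different merge orders could reach different fixpoints (random-permutation
tests have not produced such a case).

## Round combination and the tie rules

Within one reference chromosome the round seed is the unused box with the
largest Δy (ties: larger num, then smaller r_y — i.e. the lower box). The
"no longer than the seed" constraint is non-strict (Δy ≤ seed's Δy);
strict inequality would forbid equal-length siblings, which real merged
regions produce. Members must be pairwise interior-disjoint on the y axis
(shared endpoints allowed; `--y-overlap-tol` relaxes this). Subject to
those constraints the member set maximises sumy, found by depth-first
search over the y-sorted candidates with a suffix-sum bound that prunes
only strictly worse branches, so the search equals full enumeration
including the tie-breaks (equal sumy → fewer members → lexicographically
smallest (chr1, id) list). A greedy top-down sweep is *not* equivalent:
on the grape-13 worked example the optimal round 1 keeps the Δy = 112 box
of target chromosome 8 and rejects the overlapping Δy = 110 box of
chromosome 10, a choice only the subset optimum makes reliably.

Rounds are emitted until every box is used. Trailing junk rounds are
harmless because the inflection rule appends MI = 0 after the last round
and picks the round with the largest consecutive MI drop (ties to the
earlier round); a chromosome whose last real round is k therefore still
yields k unless later rounds carry comparable coverage. MI > 100 % (boxes
over-covering the reference axis) raises a warning, not an error, since
slightly overlapping merged boxes can legitimately over-count. The
genome-wide multiplier is the modal per-chromosome inflection, ties to the
smaller value, with dissenting chromosomes listed in the report.

## Worked-example reference lengths

The two bundled region tables come with reference gene counts of 1281
(grape chromosome 13) and 5437 (Arabidopsis chromosome 3). These are the
unique integers consistent with the coverage percentages reported for
those comparisons: 947/1281 = 73.93 %, 909/1281 = 70.96 %, and
4793/5437 = 88.16 %, 3799/5437 = 69.87 %, 3533/5437 = 64.98 %. They are
inferred quantities, documented as such, not published table entries.

## What the synthetic generator emulates

`simulate(SimConfig(...))` plants, for every reference chromosome, k
collinear copies on k *distinct* target chromosomes (random offsets and
diagonal orientation; real WGD copies land on different chromosomes, as
in the willow example where chromosomes 8/16 and 9/10 each tile grape 13).
Each copy loses genes independently with probability 1 − retention
(lost genes also vacate their target rank, so density drops but the
diagonal stays contiguous), is cut at n_breaks uniform breakpoints with a
10–40-rank jitter between fragments, and draws per-dot Ks from
N(ks_mean, ks_sd) folded at 0. Optional extra layers add older, sparser
events at their own Ks; background noise dots are Poisson-sprinkled
uniformly over every comparison unit at noise_rate dots per rank².
Target chromosomes are assembled by concatenating their assigned copies
with random spacers, so lengths follow from content and placement is
always feasible (a configuration with more copies than target
chromosomes is rejected).

Defaults — 3 reference chromosomes × 800 genes, 8 target chromosomes,
retention 0.7, 2 breaks per copy, Ks ~ N(0.3, 0.08), noise 2 × 10⁻⁵ —
describe a mid-sized plant comparison with a recent event. Features of
real data *not* emulated: inversions inside a copy, tandem arrays,
segmental (non-whole-genome) duplications, Ks saturation, and
rank-correlated gene loss (fractionation bias). Passing the recovery
tests therefore shows the algorithm reads planted whole-genome signal
correctly under loss, fragmentation and background noise — not that it is
robust to every artefact of real annotations.

Noise robustness was measured empirically: recovery of the planted
multiplier is essentially perfect up to ~5 × 10⁻⁵ noise dots per rank²,
begins to degrade near 1 × 10⁻⁴ (where a noise dot expects ~0.8
neighbours within eps = 50 and DBSCAN chains start to percolate into
large spurious clusters), and collapses by 2 × 10⁻⁴. The recovery suite
runs 50 simulated datasets per multiplier k ∈ {2, 3} at the defaults
(seeds 1–50), a problem size that keeps the whole test run in seconds
while giving ~150 per-chromosome calls per multiplier.

## Numerical and degenerate-input choices

Thousands separators ("1,089") are accepted in any numeric input column
and never written. Empty dot tables produce header-only outputs with a
warning rather than an error. Zero-area boxes (coincident dots) are legal
and carry Δy = Δx = 0. A single box on a chromosome yields one round
whose inflection is trivially 1, which is why chromosomes with fewer than
2 regions are skipped by default. DBSCAN label identity follows input
order (clusters numbered by first core point; border-point ties go to the
first cluster discovered), making every stage deterministic for a fixed
input file; `simulate` is deterministic under a fixed seed.

## Known limitations

Eps is fixed, not adaptive: too large fuses unrelated fragments, too
small shatters real ones (an adaptive-eps variant is deliberately out of
scope). The MI inflection needs at least one clearly weaker round after
the true level, so a genome with heavily eroded, near-equal coverage at
k and k+1 can be miscalled on individual chromosomes — the modal call
plus the dissenting-chromosome list is the guard. Reference chromosomes
are analysed independently; no attempt is made to reconcile copy
assignments across chromosomes.
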