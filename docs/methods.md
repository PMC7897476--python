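# Methods

## Coordinate conventions

Sequence positions are 1-based closed intervals on the duplex top strand,
counted from the end furthest from the origami frame's polarity marker.
Axially, nucleotide *k* occupies the interval ((k−1)·r, k·r] with
r = 0.34 nm/nt (B-form rise), so nm → nt mapping of a measured position
uses the ceiling; the `geometry` module also exposes nearest and floor
rounding, since a 1–2 nm uncertainty maps to 3–6 nt under nearest/ceil.
RecA extension is modelled purely axially: an extension factor *e* ∈
[1, 1.5] scales length per nucleotide, so a 30-nt filament spans
10.2–15.3 nm (the upper bound equalling 45 B-form nt). Helical twist is
not modelled.

## Micro-homology scanning

`find_microhomology` reports every maximal exact shared substring
(default ≥ 3 nt, one RecA monomer footprint) between the 30-nt probe and a
target strand, computed with a suffix-extension table and verified in the
tests against a brute-force substring-pair enumeration. Matching is
orientation-preserving (probe vs the identical top strand); no
reverse-complement, mismatches or gaps. Overlapping maximal matches are
merged to target *loci*: within a cluster of mutually overlapping target
intervals the longest match is kept (ties: smallest target start, then
smallest probe start), because domains are loci on the duplex, not probe
pairings. Matches overlapping the designed homology region are masked out
with `exclude`.

`disrupt_domain` shuffles a domain's bases (composition-preserving) until
re-scanning shows no ≥ 3-nt match overlapping the locus; if no permutation
works within the attempt budget it substitutes bases chosen to avoid every
probe 3-mer and flags that in the result. `switch_domain` writes a
replacement probe substring at the locus, padding the 3′ edge with
non-matching bases to conserve length. Two bounded repairs handle corner
cases where the fixed flanks would extend or mask the new match: the 3′
repair may extend up to 2 nt past the old interval, and the two bases 5′
of the locus may be rewritten as a last resort. Both edits always conserve
strand length.

## Imaging

The frame is modelled as a rectangle (outline centreline 59.5 × 60 nm)
whose three internal strands run between anchor points inset 8 nm from the
outline, giving a 43.5 nm window — the B-form contour of a 128-bp duplex.
Rows sit at the border inset, mid-height and the opposite inset; row
identity (Control, NPF, Reaction) is assigned by increasing distance from
the marker's edge, which makes labelling equivariant under mirroring.

`render_frame` draws strands as Gaussian-profile height ridges (2 nm tall,
1.2 nm wide), the outline slightly taller (2.5 nm), the polarity marker as
a 4-nm blob, plus i.i.d. Gaussian pixel noise — a controllable stand-in
for a flattened tapping-mode topograph. `vectorize` inverts this:
Gaussian smoothing (1 px), height threshold (1 nm), frame location by the
border-ridge crests of the marginal height profiles, marker detection as
the tallest outline corner (ambiguity below a 15% margin is an error),
then per-column ridge peaks (`scipy.signal.find_peaks`, ±2 px weighted
centroid refinement) tracked into three polylines by nearest-neighbour
assignment. Traces are lightly smoothed (5-column boxcar) before arclength
measurements because unsmoothed per-column jitter inflates polyline
arclength quadratically; they are then clipped and extended onto the
anchor lines so arclengths are measured anchor-to-anchor. This
threshold/crest/peak-tracking design is a from-scratch re-creation of
ridge tracing for AFM topographs; it is validated by round-trip recovery
of planted ground truth, which is the property the analysis depends on.

`intersection_position` resamples both polylines at 0.25 nm, takes the
pair of points at minimal separation and reports the arclength along the
target from the end furthest from the marker. Separations above 8 nm (two
pixels at the typical 4 nm pixel size; well below the 22 nm row spacing)
are "no contact". Because the separation profile is nearly flat around a
contact, the centre of the near-minimal region (within 0.25 nm of the
minimum) is used rather than a single argmin. Synthetic contact fixtures
approach the target to 4.5 nm between ridge centrelines — close enough to
be a clear contact, far enough that the two ridges remain separable peaks.
Round-trip recovery over 50 seeded renders at 0.3 nm pixel noise is
within 2 nm everywhere (typically ≤ 0.5 nm mean error).

## Events and per-frame statistics

Dwell times derive from consecutive-frame persistence; dwell < 10 s is
transient, exactly 10 s stable (the threshold is configurable — the
boundary convention is a choice, stated here once). Probe-induced
dislocations are flagged as isolated spikes: a point deviating from both
temporal neighbours by more than 8 nm while the neighbours agree within
8 nm; endpoints are never flagged. Joint statistics report mean, sample
sd, the fraction strictly below the lower filament bound (partially
aligned filaments) and the fraction inside the closed band. Outcome
proportions are reported with both a pooled binomial SE and, when
replicate labels exist, the SD of per-replicate proportions — published
uncertainties of this kind rarely state their estimator, so both are
given; likewise proportions can be computed with or without unclassified
frames in the denominator (default: included, consistent with category
percentages summing to 100).

## Enrichment test

The statistic is the fraction of transient events whose nt position lies
within a tolerance (default 6 nt, the upper measurement uncertainty) of
any micro-homology domain; events inside the designed homology region are
excluded, since the claim concerns sampling outside it. Two null models
are provided, both conditioned on the same support as the data (positions
in the excluded region are unreachable for observed and null events
alike — without this conditioning the test is anti-conservative):

- **circular** (default): one shared uniform circular shift of all event
  positions per permutation, on the circle of allowed positions. Preserves
  event clustering and conditions on the domain layout.
- **uniform**: independent uniform resampling of each event position.
  Appropriate when events are independent draws, e.g. against the
  synthetic generator.

p = (1 + #{null ≥ observed}) / (1 + n_perm) — never zero, valid, but
conservative for this heavily tied discrete statistic; a tie-corrected
mid-p (`p_value_mid`, half weight on ties) is reported alongside and is
the quantity to inspect for distributional calibration.

Two regimes deserve note. With only 128 strand positions the circular
null has at most 128 distinct shifts, so its attainable p-values are
bounded below by roughly the number of shifts reproducing the observed
statistic over 128. And at the default 6-nt tolerance, nine domains
expand to cover nearly all 98 non-homology positions, saturating the
indicator: the statistic then carries no contrast regardless of the null.
Analyses that need power with many domains should use a tolerance
matched to the measured peak width (≈ 3 nt here) and, for independently
drawn events, the uniform null. `power_curve` quantifies this: at
effect 0 it recovers the nominal type-I rate, at effect 1 with 50 events
the power exceeds 0.95 (uniform null).

## Synthetic generator

Defaults are the study conditions: 30-nt probe; 128-nt strands; homology
region at nt 40–69 (centre ≈ nt 55, ≈ 18.7 nm); nine planted domains of
3–5 nt outside it (the control strand carries three); 514 frames with
outcome rates 52.5 / 7.4 / 4.6 / 35.5% (homologous / heterologous / none /
unclassified); joint lengths Normal(11.1, 3.5) nm truncated at zero;
exponential dwells with means 4 s (transient) and 60 s (stable),
straddling the 10 s threshold; measurement noise 1.5 nm (the middle of
the 1–2 nm budget). Event positions mix three components (weights
0.5 / 0.3 / 0.2): a homology-centre peak, the domain peaks, and uniform
background. True peak positions carry only a small physical jitter
(0.5 nm — a contact is pinned to its few-nt locus); the 1.5 nm measurement
noise is added once, so observed peaks have the stated 1–2 nm width.
Event count defaults to 200 (a single experiment); absolute event rates
are not constrained by any published count, and pooled, multi-experiment
analyses should scale this up — the full-pipeline test uses 1000 events,
where the planted enrichment (micro weight 0.3) is detected at p ≤ 0.05
in ≈ 85% of random layouts (tolerance 3 nt, uniform null).

Sequences are built constructively: background strands avoid every probe
3-mer (randomised depth-first fill with backtracking), the homology region
is written verbatim, and each planted domain is written with 2-nt flanks
repaired so no probe 3-mer spans a junction — this guarantees the planted
match is maximal and creates no spurious loci. Every emitted sequence set
is verified by re-scanning (the scan must report exactly the planted
domains) and the generator retries placement otherwise.

What the generator does *not* emulate: NPF diffusion or sliding dynamics
(positions are i.i.d. draws, not trajectories), frame-to-frame structural
correlation of the origami, tip-convolution and drift in images, or
domain-specific dwell kinetics. Passing tests therefore demonstrate that
the analysis recovers the statistical structure it assumes, not that the
assumptions hold for any particular real instrument series.

## Numerical choices and limitations

- Scanner: O(|probe|·|target|) extension table; fine for ≤ kilobase
  strands, not meant for genomes.
- Sequence edits fail loudly (`SwitchError`) when no base assignment can
  satisfy the post-conditions within bounded attempts.
- Vectorization assumes one frame per image, near-horizontal internal
  strands and noise sd ≲ 0.3 nm after the stated smoothing; it
  re-vectorizes each image independently (no temporal linking).
- Permutation tests are bit-reproducible from their seed; all generator
  seeds derive from a single top-level seed (crc32 of the stage name,
  folded below 2³¹).
- The acceptance script scales the imaging round trip to 20 renders and
  the enrichment to one pooled experiment of 1000 events; these sizes are
  the package's reporting defaults and can be raised freely.
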