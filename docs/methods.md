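# Methods

`paremir` implements the computational core of a plant small-RNA study in
three connected analyses: miRNA annotation from deep-sequenced small-RNA
tags, degradome (PARE) evidence for miRNA-guided target cleavage, and
phased-siRNA locus detection with trigger-miRNA identification.  This note
records the models, the thresholds and their defaults, the numerical
choices, what the synthetic data does and does not emulate, and the known
limitations.

## Data model and conventions

All sequences live in a DNA alphabet `{A, C, G, T, N}` internally (`U` is
converted on input, displayed again only at output boundaries), so a single
comparison alphabet is used throughout; `G:T` encodes the G:U wobble.
Internal coordinates are 0-based half-open; every emitted file (GFF3,
D-plot tables, hit dumps) is 1-based inclusive.  `N` never pairs in folding
and never matches in mapping.

Tag tables are distinct sequences with one raw integer count per library.
Normalized abundances are transcripts per 2 million (TP2M, small-RNA) or
per 10 million (TP10M, PARE): `raw * scale / basis`, where the basis is the
library's genome-matched raw total.  Multi-mapping tags are never
apportioned: each hit carries the tag's full abundance, and hit counts
enter the analysis only through the `<= 20 genome hits` filter.

## miRNA discovery

**Stringent route.**  Distinct tags of 20-24 nt with at least 10 TP2M in
one library and 1-20 perfect genome hits are candidate matures.  For each
hit two asymmetric precursor windows are folded — `(hit-150, hit_end+30)`
and `(hit-30, hit_end+150)` — covering 5'-arm and 3'-arm placements; the
window in which more mature bases pair is kept.  A candidate passes when
the locus strand bias is >= 0.9 (sense share of all locus tag abundance),
the abundance bias is >= 0.7 (share of the top two tags), the mature is the
most abundant overlapping sense variant, and its duplex with the located
star has at most 4 mismatches+bulges with no bulge longer than 1 nt.
Failures carry the first violated criterion, evaluated in that order
(biases before structure), so rejection reasons partition the failures:
relaxing exactly one threshold admits exactly the candidates rejected for
that reason.

**Homology route.**  Tags with >= 1 TP2M whose hits coincide with the
genome placements (zero-mismatch) of a known-miRNA catalog become anchors;
anchors at one position keep the most abundant tag, anchors within 100 nt
merge likewise.  A single +/-150-nt window is folded and the relaxed
criteria applied: <= 8 total defects (no bulge-size limit), strand bias
>= 0.9, abundance bias >= 0.4.  Naming matches calls to a catalog at <= 2
mismatches (<= 3 on the manual-family route); conservation is presence in a
second, other-species catalog.

**Folding.**  Structures are predicted by non-crossing base-pair
maximization (Watson-Crick plus G:U, hairpin loops >= 3), not free-energy
minimization: the discovery criteria consume only pairing topology, and a
count objective is verifiable against an independent dynamic-programming
oracle, which the test suite does on random sequences.  Pure count
maximization is highly degenerate, so the objective is lexicographic —
pairs first, then stacked pairs — implemented as an integer score of 1000
per pair plus 1 per helix continuation; at the window sizes folded here
(<= 400 nt) the stacking total can never trade against a pair, so maximal
pair count is preserved while designed stems become the essentially unique
optimum.  Remaining ties resolve deterministically: a base pairs only when
strictly required for the optimum, then with its farthest co-optimal
partner, continuing helices inward.  (Preferring to pair on ties was
rejected: it lets flanking bases steal duplex partners in count-neutral
swaps.)  An external dot-bracket can override folding per candidate, which
is also how intron-containing precursors are supported.

**Star localization and duplex statistics.**  The miRNA* spans the partners
of the miRNA's paired bases, extended to the canonical 2-nt 3' overhang on
both duplex ends; placements spanning the terminal loop, pairing both arms,
or pairing fewer than `mir_len - 4` bases (relaxed to `mir_len - 8` on the
homology route) are rejected.  Defects are counted by walking the duplex's
antiparallel pair chain: opposed unpaired runs contribute one mismatch per
opposed position pair, the unopposed remainder of an asymmetric run is one
bulge with its length recorded, and each strand's 2-nt 3' overhang is
outside the duplex.  The computation is symmetric in its two arguments.

## Target prediction and degradome prominence

A target site is a gapless antisense window of miRNA length scored with
mismatch 1 and G:U 0.5.  Two schemes exist: `uniform` (all positions equal)
and `core-weighted` (penalties doubled at miRNA positions 2-13), the
latter a declared stand-in for published scoring systems that weight the
pairing core.  Three presets mirror the three prediction programs the
field uses — (uniform, <= 7), (core-weighted, <= 4), (uniform, <= 5) — and
their deduplicated union is the reported target set.  Cleavage is placed
opposite miRNA positions 10/11: for a site `[s, s+L)` the downstream
fragment's 5' base is `s + (L - 10)`.

PARE tags (trimmed to their 5' 20 nt, hit-filtered, low-complexity-masked
when a 1-3-nt motif run exceeds 12 nt) build per-transcript, per-library
sense-strand position -> TP10M profiles.  A predicted site with a tag
starting exactly at its cleavage position in any library is "precise";
its metrics are computed in the library where that exact-position signal is
strongest (ties keep configured library order):

* abundance — TP10M at the cleavage position (criterion: >= 10);
* rank — competition rank of that position among the transcript's
  positions, ties sharing the better rank (criterion: <= 2);
* peak percentage — by default 100 x the sum of the transcript's two
  largest position abundances over its total (criterion: >= 20%).

Level = 1 + number of criteria passed, so Level 1 meets none and Level 4
all three.  Two peak-percentage definitions circulate (top-two sum vs
exact-site abundance); both are computed and reported, the top-two variant
drives level assignment because only it is well-defined as a background
statistic over all transcripts.  When more than two positions tie for the
peak, the 5'-most two are the reported peak positions (the percentage is
tie-invariant).

## Phasing

Phased siRNAs recur at a fixed 21- or 24-nt register downstream of a
trigger cleavage.  Tag 5' ends build a strand-folded profile (a
bottom-strand 5' end at `p` maps to register `p + 2`, the duplex-overhang
geometry).  The phasing score at a position is the 9-cycle log-odds

    score = (k - 2) * ln(1 + 10 P / (1 + U)),    0 when k < 3,

over a window of nine phase cycles centered on the position, with `P` the
in-register abundance, `U` the out-of-register abundance, and `k` the
distinct occupied in-register positions.  The score formula is this
package's declared choice (the underlying study defers to earlier scripts
without printing one); any score increasing in `P` and `k` and decreasing
in `U` can be substituted.  Loci are clusters of positions scoring >= 20
(edge threshold) containing at least one position >= 25, extended one
period past the last scored position; scored positions further apart than
two phase cycles (configurable — no published value exists) start a new
locus.  The locus register is the maximum-score position mod period,
5'-most on ties.

For trigger identification, PARE 5' ends within five phase cycles of a
locus are examined.  The 24-nt miRNA-complementary window is the 13 nt
upstream of the PARE start plus the first 11 nt of the fragment, with
+/-1-shifted variants for off-by-one cleavage; each candidate miRNA
(<= 23 nt) is 3'-aligned so position 10 pairs the PARE 5' base and scored
with mismatch 1 / G:U 0.5.  Calls need a score <= 5 and carry a signed
register offset; offsets are reported rather than hard-filtered (the
strict |offset| <= 1 filter is a config flag) because real loci
occasionally violate the register rule.

## Synthetic data: what it emulates, and what it does not

The generator plants, in a random 20-kb genome: hairpin precursors
(complementary flanks extending the stem, one interior mismatch by default
— see below), a relaxed-structure precursor with a 2-nt star-arm bulge for
the homology route, double-stranded siRNA loci (tags on both strands,
strand bias ~0.5), trigger-initiated phased loci, and genome-derived
background tags, plus per-precursor target transcripts whose degradome is
uniform background decay with a point mass at the cleavage site.

Deliberate design constraints, each there so that construction-by-design
truths are stable under pair-maximization folding:

* compliant plants carry one interior mismatch because a perfect duplex
  would make mature and star exact reverse complements — each tag would
  then map to both strands of its own hairpin and halve the strand bias;
* mismatch-freed bases are drawn from `{A, C}` (mutually non-pairing) so
  planted internal loops cannot chance-pair shut;
* matures are rejection-sampled to contain no repeated 5-mer; internally
  repetitive matures (rare in real catalogs) admit register-slipped
  co-optimal folds;
* the relaxed plant uses a single 2-nt bulge rather than many scattered
  defects: densely defected stems genuinely refold (a free-energy folder
  would rearrange them too), so the many-defect threshold logic is
  exercised with explicit dot-bracket structures instead;
* phased loci default to five fully occupied cycles of 400 reads: with at
  most five occupied cycles every in-register position sees the same k in
  its centered window, so the 5'-most tie-break puts the score maximum at
  the cleavage site, the qualitative single-locus property the analysis
  reproduces (that check runs with background tags disabled, the clean
  condition it describes).

Library depths are bulked to 4 x 10^5 genome-matched tags per small-RNA
library with long (30-nt, size-excluded) filler tags, so the 10 TP2M
candidate threshold binds: a singleton background read normalizes to
5 TP2M and is filtered, as singletons are at real depths.  PARE libraries
carry ~2,000 reads per transcript with a 0.6 cleavage peak fraction.
These are two to three orders of magnitude below the real experiments.

Not emulated: sequencing error and ligation bias, expression heterogeneity
across libraries (counts split multinomially at equal rates), introns,
multi-mapping repeat families, and RNA structure beyond the planted
elements.  Passing the planted-recovery suite therefore demonstrates that
the pipeline logic implements its stated criteria and recovers signals
matching its assumptions — not that those criteria are sufficient on real
tissue libraries, where folding energetics, annotation noise and repeat
content dominate the error budget.

## Numerical choices and degenerate inputs

Thresholds live only in `PipelineConfig` (YAML-serializable, hashed into
run manifests); all boundary comparisons are inclusive exactly as stated
above.  Zero-abundance denominators raise (`strand bias`, normalization
basis) or define a documented degenerate result (absent cleavage position:
abundance 0, rank = positions + 1).  Duplicate input tag rows are summed
with a warning.  Hit enumeration stops at `max_hits + 1` and flags the
tag.  Scoring comparisons against `max_score` use a 1e-9 absolute epsilon
to keep half-integer penalty sums exact in floating point.  The Nussinov
fill runs under numba when available, with an identical pure-Python
fallback; replicate simulations are pure functions of an integer seed.

## Problem sizes

The planted-recovery suite runs 20 replicates of the default study
conditions (20-kb genome, 4 precursors, 2 siRNA loci, 2 phased loci, 2+2
libraries), about 0.2 s per replicate; the oracle-equivalence suite folds
60-mers against an independent recurrence and maps 500 tags against a
10-kb naive scan.  These sizes make every threshold bind while keeping the
full suite under a minute on one CPU.

## Known limitations

Base-pair maximization is not a thermodynamic model: structures with equal
pair counts but different energies are indistinguishable, and the
homology route's tolerance of dense defects is bounded by fold stability
rather than by the defect count alone.  The core-weighted scheme and the
phasing score are declared surrogates for unpublished internals of the
tools they stand in for; their thresholds are faithful, their internals
are not.  Exact-match mapping has no mismatch tolerance outside the
catalog-naming step, no indels, and no spliced alignment; transcript
profiles are sense-only.  The per-library phased-locus boundary rule is
approximated on the combined profile.
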