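# Methods

## Model and procedure

`svannotate` treats a structural variant (SV) call as a pair of
breakpoints: `(chrom, start)` and `(chrom2, end)`. For deletions,
duplications, insertions and inversions both breakpoints lie on one
chromosome and the call additionally has a reference span; for
translocations (TRA, including BND/CTX breakends) the two breakpoints may
lie on different chromosomes and no span is defined. Internally all
positions are 0-based: `start`/`end` are breakpoint positions, so a
deletion's reference span is the half-open interval `[start, end + 1)`,
while BED-style features are stored half-open `[start, end)` as on disk.
All conversion to and from the 1-based VCF/GFF conventions happens in
the `formats` module and nowhere else.

**Merging.** Calls from different callsets are connected when they share
both breakpoint chromosomes and both breakpoint distances are at most
`max_dist` (default 1000 bp), optionally also requiring equal SV types.
Events are the connected components of this relation. Because the
relation is not transitive, a chain of mutually close calls can join two
calls whose own distance exceeds `max_dist`; this chaining is accepted as
the simplest deterministic interpretation of a pairwise-distance merge.
Representative event coordinates are the per-component medians of member
breakpoints, with even counts rounding the mean of the two middle values
downward so coordinates stay integral. Event identifiers are assigned in
`(chrom, start)` order, and the result is provably independent of the
order in which callsets are supplied (records are canonically sorted
before clustering; a test shuffles callsets and asserts equality).

**Annotation.** The overlap schema is type-specific. Span types
(DEL, DUP) collect features overlapping the span widened by the wobble
distance on both sides, `[start − w, end + 1 + w)`. Breakpoint types
(INS, INV, TRA) collect the union of features within `w` of either
breakpoint, implemented as half-open windows `[pos − w, pos + w + 1)` so
a feature touching position `pos ± w` still counts (the window is closed
at distance exactly `w`). Records of unknown type (UNK) and merged
events whose modal member type is tied take the conservative
breakpoint-only path. Known-SV VCF entries are first reduced to unique
sites by `(chrom, start, chrom2, end, type)` and match an event when the
chromosome pairs agree and *both* breakpoints lie within the wobble;
matching both breakpoints keeps the criterion consistent with the merge
relation, and an `either_breakpoint` relaxation is exposed for users who
prefer the looser reading. VCF matching is type-agnostic by default
(merged events are heterogeneous by construction) with a `require_type`
switch. `total_Annotations` counts distinct BED/GFF feature names only;
known-SV matches are reported separately through `overlapped_VCF`, so
the two sources of evidence never blur. Duplicate feature names for one
event (e.g. several exon records of one gene) are deduplicated before
counting; names are listed in source-file order, then interval order.

**Concordance.** Events are eligible when supported by at least
`min_support` callsets (default 4) and every member call has the same
type. Within an eligible event each callset's sub-calls are reduced to
`(min start, max end)`; the median start/end are taken over the reduced
per-callset pairs, and each callset contributes one row of signed
deviations `d_start`, `d_end`. Reducing before taking the median is the
only reading that lets each callset contribute exactly one pair; the
alternative — medians over all raw sub-calls — is available as
`median_over_subcalls`. Even-count medians are the arithmetic mean of
the two middle values and may be half-integral; deviations are reported
as reals. Size bands for deviation histograms use the reduced span
`end − start`; translocations are excluded from size banding.

## Parameters that matter

| parameter | unit | default | role |
| --- | --- | --- | --- |
| `max_dist` / `wobble` | bp | 1000 | positional slack for merging, feature assignment and known-SV matching; absorbs caller/technology breakpoint imprecision |
| `type_specific` | – | off | merge only calls of equal type |
| `min_size` | bp | 0 (off) | drop calls below this size at VCF read time (TRA exempt); set to 20 to mimic ">19 bp" callset conventions |
| `min_support` | callsets | 4 | eligibility threshold for breakpoint concordance |
| `require_type`, `either_breakpoint` | – | off | stricter/looser known-SV matching |

## Synthetic studies

The generator emulates a multi-caller comparison: `n_true_svs` true SVs
(default 500) with types drawn from realistic weights (40% DEL, 30% INS,
12% DUP, 12% INV, 6% TRA), sizes uniform on 50–2000 bp, placed on a
two-chromosome 25 Mb toy genome with pairwise spacing ≥ 5 kb. Each of
`n_callsets` (default 5) callsets detects a truth SV with probability
0.6, shifts each breakpoint by independent rounded Normal(0, 100 bp)
jitter, relabels 5% of detections with another (non-TRA) type, and adds
Poisson(25) false calls. Half the truth SVs also appear, independently
jittered, in a known-SV VCF, and 40%/30%/20% carry an on-target
gene/named-repeat/unnamed-repeat feature hugging the start breakpoint.

Two placement rules make the truth ledger *exact* rather than
approximate: false positives are rejected away (≥ `min_spacing`) from
every truth breakpoint **and** from every previously placed false
positive across callsets, and background features keep the same
clearance from all of those positions. Jittered ends are clamped to stay
at or after the jittered start so small SVs cannot invert. Under the
default spacing (5 kb) and jitter (100 bp, i.e. ≥ 7 SD below the merge
distance) no spurious merge or split can realistically occur, so the
merged event count equals `n_detected_truth + n_false_calls` and every
event's support equals the detection bookkeeping — asserted exactly in
the tests.

What the generator does *not* emulate: read-level evidence, alignment
artifacts, multiple representations of the same SV in repeats, clustered
or overlapping SVs, size- or type-dependent detection bias, and
genotypes. Passing tests therefore demonstrate the correctness of the
merging/annotation/statistics machinery under controlled noise, not the
behavior of real callers on real genomes, where breakpoint errors are
heavy-tailed and events can legitimately chain.

On recovered jitter: a callset's deviation is taken from the sample
median of ~5 jittered values, which is itself noisy and positively
correlated with the callset's own jitter, so the per-callset SD of
`d_start` is expected to sit slightly below the generator's `jitter_sd`
(about 7% low for five callsets). The recovery check uses a ±20% band,
measured at ≥ 500 eligible events from a high-detection configuration
(700 truth SVs, detection 0.95, no type confusion, no false calls),
since the default detection rate yields too few support-≥4 events for a
stable SD.

## Numerical and degenerate-input choices

- Point queries (`end == start`) against the interval index are widened
  to one base; stored intervals must have `end > start`.
- Integer medians round the even-count middle mean toward the lower
  value; concordance medians stay real-valued.
- `normalize_type` is total: unrecognized type strings become UNK, never
  an error. UNK records merge like any other (grouping only with UNK
  under type-specific merging) and annotate via the breakpoint path.
- Malformed data lines in VCF/BED/GFF are skipped with a logged warning
  and a count, never an exception; structurally unreadable files (no
  `#CHROM` line) raise a `FormatError` naming the path.
- Non-TRA records whose END precedes POS are repaired by swapping the
  breakpoints; non-TRA lines claiming a different second chromosome are
  treated as malformed and skipped.
- VCF feature names are sanitized (`; , = whitespace` → `_`) before they
  enter `overlapped_Annotations`, since VCF reserves those characters.
- The annotated-VCF writer preserves every input row byte-identically
  outside the INFO column and appends the three keys; this is why VCF
  handling is line-level rather than delegated to a record-rewriting
  VCF library (cyvcf2 is still used in the test suite as an independent
  parsing cross-check).

## Problem sizes used in the checks

Randomized oracle comparisons run on ~100 instances of up to a few
hundred events × features against quadratic brute-force
reimplementations; merge/annotation ledger recovery runs on studies of
100–500 truth SVs × 5 callsets; jitter recovery on 700 truth SVs. These
sizes give exact (ledger) or statistically stable (SD within ±20%)
checks while keeping the whole suite fast enough to run on every change.

## Known limitations

- Connected-component merging can chain distant calls; no splitting
  heuristic is applied.
- Known-SV matching tracks per-file hit counts but not per-file identity
  in the written INFO, so the per-source annotation summary for VCF
  sources is kind-level.
- The merged multi-sample VCF encodes member calls in a `TY:CO` FORMAT
  pair; chromosome names containing `_<digits>-` could parse ambiguously
  there.
- No genotype/FORMAT modeling, no reciprocal-overlap criteria, no
  functional-consequence prediction.
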