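# Methods

## Signal model and scope

The package operates on per-probe log2 ratios (`M` values) of two-channel
bacterial array hybridizations, one value per probe after replicate
merging. The underlying model is piecewise-constant expression along the
genomic coordinate: a transcript raises the M level of every probe it
covers by a constant, and probe noise is additive Gaussian on the M scale
(the appropriate scale for log-ratio data). Strands are treated as
independent signal tracks; no cross-strand information enters
segmentation. Normalization is deliberately minimal — each replicate
column is median-centered before per-probe averaging — which removes a
per-hybridization offset while leaving the M-ratio semantics intact.
Dye-bias loess, background correction and vendor scanner formats are out
of scope; input is a plain probe TSV.

## Window construction (CPRs)

At each candidate anchor (a probe start `x`, excluding the first and last
`m(w)` probes of a track) two windows are built: left over starts in
`[x − w, x)` and right over `[x, x + w)`. Parameters are estimated from
the data: `w` is the mean distance between consecutive probe starts
(rounded up), and `m(w)` the minimum probe count over complete width-`w`
windows anchored at probe starts, floored at 2 because the t-statistic
pools a dispersion. Probe position means probe start throughout, keeping
the estimates independent of probe length.

Each window then expands outward, probe by probe, while:

* (gap) the next probe lies within `gap_factor · w` of the window edge
  (default 2; see below),
* (consistency) once the window holds `m(w)` probes, the next probe's M
  deviates from the window mean by at most
  `k · max(sd, s0, σ̂)` with `k = 3`,
* (span) the window span stays within `max_window_expansion = 10 w`.

Three choices here are the package's own, since the window criterion is
the least formalized part of the method:

* **Gap factor 2.** With `w` equal to the *mean* gap, a skewed non-tiling
  spacing distribution puts roughly a third of gaps above `w` itself; a
  strict `gap ≤ w` rule leaves most anchors without a valid window. A
  factor of 2 bridges ordinary spacing irregularity while a 3 w hole still
  severs the window (such holes are handled separately, below).
* **Minimum growth.** Below `m(w)` probes, expansion is gated only by the
  gap and span rules — with `w` = mean gap the initial window typically
  holds a single probe, and a fresh window's sd of ~0 would otherwise veto
  any growth under noise.
* **Noise floor σ̂.** The consistency gate is floored by a robust
  track-level noise scale, `σ̂ = median|ΔM| / (√2 · 0.6745)` over
  successive probe differences; transcript boundaries are sparse among the
  differences and do not move the median.

## t-statistic, s0, change points

Window pairs are compared with the SAM relative difference
`t = (m_R − m_L)/(s + s0)`, `s` the pooled standard error built from the
within-window sums of squares. The fudge constant `s0` defaults to the
5th percentile of the pooled-`s` distribution over all anchors of the
track, floored at 0.01 — the standard role of the SAM fudge factor,
keeping `t` finite where local scatter vanishes (a noiseless track yields
`s0 = 0.01`). Because the default `s0` is computed from windows that
themselves need a gate scale, the first pass uses `σ̂` as a provisional
gate and the windows are rebuilt once with the final value.

Change points are the above-threshold runs of the |t| curve collapsed to
their maximum-|t| anchor (leftmost on ties), with one refinement: a sign
change of `t` inside a run closes it. On sparse layouts the anchors
between a transcript's rising and falling edge can all be ineligible, and
without the sign rule the two opposite steps would merge into one run.
The threshold defaults to `|t| ≥ 3` — three pooled-error units, a
conservative gate for log-ratio noise.

## Signal-area assembly

On a uniform (tiling) layout the areas are exactly the intervals between
consecutive change points plus the track edges; each takes its first
member probe's start, last member's end, and the pseudomedian `M̄` of its
probes. The pseudomedian (Hodges–Lehmann estimator) is computed exactly as
the median of all `n(n+1)/2` Walsh averages; the O(n²) cost is irrelevant
at the track sizes involved and buys exactness against the brute-force
oracle used in the tests.

On a non-uniform layout the change-point intervals are candidates only. A
left-to-right pass joins adjacent regions A, B when
`|PM(A ∪ B)| > |PM(A) − PM(B)|` (the union reading keeps the criterion
symmetric for negative M), extending the comparison rightward after each
join. Two additions make the non-tiling path robust to probe holes wider
than the windows can bridge:

* a degenerate window side at an anchor is regrown by probe count, gap
  rule waived and consistency gate applied from the first probe, so a step
  adjacent to a hole keeps an eligible anchor;
* every unbridgeable hole is tested directly — flanking count-grown
  windows, same t-statistic and threshold — and contributes a candidate
  cut when the signal differs across it.

Both additions only create *candidate* cuts; redundant ones are removed by
the merge pass, and in background signal the t-threshold suppresses them.
Auto layout detection uses the coefficient of variation of inter-probe
gaps (tiling below 0.2).

## Cross-experiment alignment

Areas from several experiments (optionally pre-filtered by
`|M̄| ≥ min_abs_M`, default 0 = keep all) are connected when they share a
replicon, strand, and at least one base — the weakest overlap reading,
maximizing recall. Connected components become consensus transcripts with
boundaries `⟨x⟩ = Σ pᵢ xᵢ` rounded half away from zero. Weights use
|M̄| — the raw ratio `M̄ᵢ/ΣM̄ⱼ` breaks down for negative log-ratios, which
real data certainly contains, while |M̄| preserves "stronger signal, more
trust" and keeps `pᵢ ∈ [0, 1]`. All-zero components fall back to uniform
weights (logged). When one experiment contributes several members to a
component, its reported `M̄` is the pseudomedian of the union of their
probes (or of their area values after a file round trip, where probe-level
membership is no longer available). An experiment absent from a component
is reported missing, never zero: zero would fake "no change".
Differential selection keeps transcripts with `|M̄| ≥ log2(fold change)`
in every named experiment — a plain fold-change cut, deliberately without
moderated statistics or FDR control.

## Classification

Classes are assigned by fixed-precedence rules, first match wins, with the
published thresholds as defaults (30 % of a single ORF's length for a
qualifying overlap, 30 bp gaps, 800 b intergenic length cap):

1. **operon** — ≥ 2 same-strand ORFs each overlapped ≥ 30 %;
2. **overlapping_utr** — two differently oriented ORFs touched, intergenic
   gap between them < 30 bp;
3. **orf** — exactly one qualifying same-strand ORF, area within 30 bp of
   its boundaries;
4. **utr5 / utr3** — one qualifying same-strand ORF plus a longer flanking
   extension; 5′ vs 3′ is strand-aware (on the minus strand the upstream
   flank lies at higher coordinates), the larger extension decides, ties
   toward 5′;
5. **antisense** — qualifying overlap only on the opposite strand;
6. **intergenic** — no ORF contact, length < 800 b;
7. **intergenic + `long` flag** — no ORF contact, ≥ 800 b (kept rather
   than dropped; dropping would silently lose signal).

Operon-before-ORF precedence prevents a polycistronic area from degrading
to a single-ORF call. The rule set as published is not total: an area
touching ORFs only below the 30 % threshold matches nothing, and such
areas fall back to antisense with a `subthreshold_overlap` flag, following
the rule set's catch-all reading of weak ORF contact. Every decision is
recorded in a per-transcript rule trace. The summary table reports long
ORF-free areas in their own `intergenic_long` row.

Two orientation symmetries hold and are tested: flipping every strand
(coordinates fixed) swaps utr5 and utr3 and fixes all other classes;
flipping strands *and* reflecting coordinates preserves 5′→3′ biology and
fixes every class.

## Synthetic study conditions

The generator's defaults describe a desk-scale bacterial design: a 20 kb
replicon, end-to-end 20 bp probes (tiling) or gamma-distributed gaps of
mean 25 bp (non-tiling, dispersion 1 ≈ geometric), baseline `M = 0`,
noise sd 0.25 — typical residual scatter of normalized two-color data —
and, in multi-experiment mode, ≤ 20 bp boundary jitter between
hybridizations. Transcript levels in the noisy-recovery conditions are
drawn uniformly from ±[1, 2.5] (fold change ≥ 2). The noiseless
change-point fixture uses a 6 kb genome at 10 bp tiling with three
1 kb transcripts at `M = 2`. These sizes keep the full test suite and the
acceptance script within a couple of minutes while leaving hundreds of
probes per track and ≥ 12 probes per transcript.

What the generator does *not* emulate — probe-sequence thermodynamics,
cross-hybridization, spatial slide artifacts, heteroscedastic
intensity-dependent noise — bounds what passing tests show: they validate
the segmentation/alignment/classification logic under the stated signal
model, not robustness to array-specific systematics, which real pipelines
address upstream during normalization.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive everywhere inside the package (GenBank
convention) and converted only at the BED boundary (0-based half-open).
Gaps count bases strictly between features. Consensus boundaries round
half away from zero. Empty tracks segment to nothing; single-probe tracks
yield one area; tracks too short to anchor any window yield one area per
track. Probes with all replicate values missing are dropped with a logged
warning. The pseudomedian of an empty list is an error, of a singleton the
value itself.

## Known limitations

* Boundary resolution is limited to the local probe spacing; on thinned
  layouts the first retained probe inside a transcript bounds what any
  method can recover, so per-boundary agreement with the full-density run
  is assessed in the mean, not the maximum.
* The pseudomedian merge rule is knife-edge for adjacent regions whose
  pseudomedians are both ~0 (it never joins them); spurious cuts in flat
  background must therefore be prevented upstream by the t-threshold,
  which the defaults do.
* The overlap-graph consensus can chain distinct but overlapping loci
  into one component (single-linkage behaviour); the optional
  `min_abs_M` pre-filter is the intended mitigation for noisy areas
  gluing components together.
* Replicate merging is a simple median-centering + mean; array-specific
  normalization beyond that is expected to happen before import.
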