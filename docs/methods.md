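# Methods

This note documents the models and procedures implemented in `meaburst`,
the defaults and why they are what they are, the numerical choices that
affect edge cases, what the synthetic generators do and do not emulate,
and known limitations.

## Data model and conventions

Spike times are seconds from recording start, stored as float64, strictly
non-decreasing and bounded by the recording duration; frame-indexed inputs
are divided by the sampling rate on ingest (`adapters.load_unit_npz`).
Burst and network-burst intervals are closed: `start` and `end` are the
first and last spike (or onset) of the event, so `duration = end − start`
and containment tests use `start ≤ t ≤ end`. All threshold comparisons in
the package are **inclusive** (an ISI exactly equal to the maximum joins a
burst, a firing rate exactly at the minimum makes a unit active): the
boundary case then behaves identically in the implementation and in any
exact-arithmetic derivation, at the cost of sensitivity to binary float
representation for non-representable decimals — tests therefore probe
boundaries with exactly representable values.

The spike archive is a flat keyed-array container (npz or HDF5 with the
same key names): `unit_ids`, `spike_times_<id>`, `duration`,
`sampling_rate`, optional `positions`, `layout`, `template_<id>` +
`template_fs`, and (HDF5) `raw_traces`. The format is deliberately
self-describing and language-portable; `save` ∘ `load` is the identity on
every field.

## Unit filtering

Active units are those with mean firing rate `n_spikes / duration` at or
above `min_firing_rate` (default 0.05 Hz — a floor that keeps units with a
handful of spikes per minute while discarding near-silent sorter output).
Contamination is estimated by the ISI-violation ratio

    ratio = C · T / (2 · N² · t_ref)

with `C` the number of consecutive-spike intervals strictly below the
refractory threshold `t_ref` (default 1.5 ms), `N` the spike count and `T`
the duration. This is the standard false-positive-rate estimator that
scales the observed violation count by the rate expected from an
uncorrelated contaminating process; a ratio near 0 indicates a
well-isolated unit. Only consecutive intervals are counted: with
`t_ref` three orders of magnitude below typical ISIs, higher-order pairs
contribute negligibly. A ceiling of 0 (the default) disables the filter
entirely rather than rejecting everything — a sentinel convention that
makes "no quality filtering" the out-of-the-box behavior. Whether an
interval exactly equal to `t_ref` should count as a violation is
underdetermined; strict `<` is used.

Binned rate timelines (`binned_rate`) use `⌈T / bin⌉` bins with the final
partial bin normalized by its actual width, so `Σ rateᵢ·widthᵢ` always
equals the event count exactly.

## Burst detection

**Fixed method.** Maximal runs of spikes whose successive ISIs are all
≤ `max_isi` (default 0.1 s); runs with ≥ `min_spikes` (default 5) become
bursts. Bursts are disjoint and ordered by construction.

**Adaptive logISI method.** Bursty units have bimodal ISI distributions:
an intra-burst mode at a few ms and an inter-burst mode orders of
magnitude slower. The per-unit threshold is found on the histogram of
log₁₀(ISI in ms), uniform bins of 0.1 decade spanning the floor/ceil
decades of the data (log values are rounded to 12 decimals first, so
identical decimal intervals never straddle a bin edge through binary
noise). Counts are smoothed with a Savitzky–Golay filter (window 3 bins,
polynomial order 1, edges handled by polynomial fit on the truncated
window, output clipped at 0). Peaks are local maxima of the smoothed
counts with minimum index separation `peak_min_distance` (2 bins). The
intra-burst peak is the highest peak at an ISI ≤ `max_intra_peak`
(0.1 s). For each later peak `p₂` the valley depth is scored by the void
parameter

    v = 1 − h(m) / √(h(p₁) · h(p₂))

with `m` the interior minimum between the pair; `v ∈ [0, 1]` since
`h(m) ≤ min(h(p₁), h(p₂))`. The threshold is the ISI at the
smallest-ISI minimum with `v ≥ min_void` (0.7). Two search questions are
underdetermined by the published parameterization and resolved as
follows: voids are computed against *all* later peaks (not just the
next), with the smallest-ISI qualifying minimum winning; and when the
valley is a flat plateau (common when the modes are far apart and the
histogram is empty in between) the *central* bin of the minimal plateau
is taken, placing the threshold mid-valley rather than hugging the
intra-burst mode. No threshold (unimodal histogram, no qualifying void,
or threshold above `max_isi_threshold` = 1.0 s) signals fallback.

Detection then follows the threshold `T_isi`: (i) absent → fixed method
with the default `max_isi`; (ii) `T_isi ≤ isi_choice` (0.1 s) → fixed
method with `max_isi = T_isi`; (iii) `T_isi > isi_choice` → burst *cores*
are found with the choice threshold (runs of ≥ 2 spikes), each core is
extended outward over adjacent spikes whose gap is ≤ `T_isi`, and
extended cores are merged when they share a spike (transitively, which
preserves disjointness). `min_spikes` applies to the final bursts in
every regime; cores are detected at ≥ 2 spikes so that a small core plus
extensions can still reach the minimum.

**Hybrid method.** The adaptive threshold (with the same fallback) used
directly as `max_isi` in the fixed grouping rule.

Burst metrics: duration `end − start`, density `n_spikes / duration`
(spikes per second within the burst). A zero-duration burst (all spikes
coincident — possible with quantized or degenerate input) gets density
NaN and is excluded from summary means and SDs.

## Network bursts, leaders, precedence graph

All bursts are pooled and sorted by onset (start time); maximal runs in
which successive onset-to-onset intervals (IBEIs) stay ≤ the threshold
are candidate events, kept when they contain ≥ `min_units` (default 5)
*distinct* units. Onset-based intervals are non-negative by construction,
which is why IBEIs are defined on onsets rather than end-to-start gaps.
A unit contributing several bursts to one event counts once, with its
earliest onset. The fixed threshold is 0.2 s; the adaptive variant runs
the same valley search as the logISI method on the pooled IBEI sequence
(intra-event peak ≤ 0.2 s, `min_void` 0.5, ≥ 3 pooled bursts), falling
back to the fixed default when no threshold qualifies. The published
parameter set lists no cap for the adaptive IBEI threshold (the per-unit
method has one at 1.0 s), so it is uncapped by default with an optional
`max_ibei_threshold` parameter.

Merging (off by default: `min_separation` = −0.01 s, negative disables)
joins consecutive events whose gap `next.start − prev.end` is ≤ the
separation, transitively: participants are unioned, earliest onsets kept,
spike counts summed once per burst. Merging is idempotent.

The leader of an event is the participant with minimal burst onset, ties
broken toward the smaller unit id (deterministic and reproducible; exact
onset ties are measure-zero in real data). Summed `n_led` over units
equals the event count. The precedence graph increments edge `u → v` once
per event in which `u`'s onset strictly precedes `v`'s; ties contribute
no edge, so there are no self-edges and weights are positive integers.
First-*onset* order (not first-spike order) defines precedence,
consistent with the leader definition; the alternative would only differ
for units whose burst starts before another unit's but fires its next
spikes later. The graph is exported as a tab-separated
`source target weight` edge list for external graph tools.

## Synchrony

**STTC** (window half-width `dt`, default 0.5 s): `T_X` is the fraction
of the recording covered by the union of ±dt windows around X's spikes,
clipped to the recording — windows are merged, not summed, which matters
at high rates; `P_X` is the fraction of X's spikes within `dt`
(inclusive) of any spike of the other train. The coefficient is the
average of the two directed terms `(P − T)/(1 − P·T)`. Identical trains
score exactly 1 (P = 1 makes each term 1 regardless of T < 1). Empty
trains and vanishing denominators (`P·T = 1`) yield NaN rather than an
exception, so matrix assembly never aborts.

**Spike distance** (ISI-distance form): each train is augmented with edge
events at 0 and `T` (the standard correction so the instantaneous ISI is
defined everywhere); at `n_bin` (default 120) sample times the
instantaneous ISIs `I_A, I_B` give `|r| = 1 − min/max`, averaged over
samples. Samples are placed at bin midpoints, which avoids evaluating at
the auxiliary edge events; identical trains score exactly 0. Refinements
of the measure that adapt the sampling to local spiking are not
implemented; results are comparable across recordings at fixed `n_bin`.

**Phase synchrony** (parameter-free): each train's phase advances
linearly by 2π per ISI; phase differences are sampled at one train's
spike times within the other's spiking span and summarized by the mean
resultant length `√(⟨cos Δφ⟩² + ⟨sin Δφ⟩²)`. Because sampling at A's
spikes is not symmetric in (A, B), the two directed values are averaged;
this symmetrized form is what the all-pairs matrix reports. Trains with
fewer than two distinct spikes are NaN.

The all-pairs matrix computes the upper triangle once and mirrors it;
diagonals carry the method identity (1, 0, 1 for STTC / spike distance /
phase synchrony). `n_processes` distributes pair computations over a
process pool but cannot change any value — determinism is a contract,
parallelism only throughput.

## Raw-trace QC and templates

Channels are flagged *constant* when any run of ≥ `const_len` (10)
identical consecutive samples occurs (saturated or disconnected
electrodes; raw ADC data are integer-quantized, so exact equality is the
right test — floating traces that have been rescaled should be quantized
before QC), and *noisy* when the channel SD exceeds `sd_factor` (1.7) ×
the median SD over channels; constant takes precedence, and the noise
test is computed on raw (pre-filter) traces. Band-pass filtering is a
third-order Butterworth applied forward–backward (zero phase, order
effectively doubled), 300–6000 Hz, with the upper corner capped at
0.95 × Nyquist when the sampling rate demands it.

Templates cover 1 ms before to 2 ms after the spike. The central channel
is the one with maximal peak-to-peak amplitude. If the absolute minimum
exceeds the maximum the unit is soma-like with height = minimum
(negative µV); if the maximum is larger it is dendrite-like with
height = maximum; the exact tie — unassigned by the two strict rules —
is classified soma-like, a deterministic convention. Duration is the
absolute trough-to-peak latency in ms (the sign/order of extrema is not
fixed by the "peak latency" notion, so the absolute value is reported).

## Synthetic generators

Each generator seeds its own `numpy` Generator from the single integer
seed, so results are reproducible and independent of call order. Default
parameters reflect mature-culture HD-MEA activity: bursts of ~8 spikes at
5 ms intra-burst ISI, burst events at 0.1 Hz, population events at
0.02–0.1 Hz recruiting all units with a 20 ms leader-to-follower onset
cascade and 5 ms Gaussian onset jitter, biphasic templates of 40–100 µV
with a 0.2 ms trough, raw noise floors of ~5 µV SD.

Construction details that matter for interpreting tests: bursty-train
events are placed so bursts never spill past the recording end, and
overlapping generated bursts are merged in the returned ground truth;
population events are thinned with a dead time (event span + 0.5 s) so
that distinct generated events remain separable — ground-truth event
counts are then recoverable *by construction* when detection thresholds
are far from the generated gaps, which is the regime the count-recovery
tests probe. Network-event onsets form a cascade (leader at the event
time, followers at successive 20 ms multiples), giving the pooled IBEI
sequence a genuine ~20 ms intra-event mode for the adaptive threshold to
separate from the seconds-scale inter-event mode. Jitter that would
disorder spikes is resolved by re-sorting, preserving spike counts.

What the generators do **not** emulate: firing-rate heterogeneity and
non-stationarity, refractory structure, spike-sorting artifacts
(collisions, drift, split/merged units), within-burst rate profiles,
spatially propagating network bursts, and correlated or non-Gaussian
electrode noise. Passing the recovery tests therefore demonstrates
algorithmic correctness under the stated generative assumptions, not
performance on real cultures; on real data the adaptive thresholds and
leader assignments depend on histogram quality and sorting quality in
ways the generators deliberately idealize.

## Problem sizes in the test suite

The suite runs at desk scale: oracle-equivalence checks use 500 random
instances of ≤ 50 spikes per operation; threshold-recovery runs 100
seeded trains of ~25 s; leader and count recovery use 8–15 units over
300–600 s; template recovery uses 1000 seeded templates. These sizes give
the binomial success criteria (≥ 95%, ≥ 80%, ≥ 99%) enough trials to be
meaningful while keeping the whole suite fast.

## Limitations

- The adaptive valley search can report thresholds on sparse, noisy
  histograms (few intervals per bin) where single-interval bins form
  spurious peaks with void 1; with very few spikes the histogram is
  skipped entirely and the fixed fallback applies, but moderately sparse
  unimodal trains (e.g. Poisson units) may still receive a small
  threshold. Raising `min_spikes` and inspecting the stored histograms
  (`peaks`, `voids`, `threshold`) is the remedy.
- Spike-distance and phase-synchrony variants differ across the
  literature; the forms here (edge-corrected ISI-ratio distance,
  symmetrized resultant length) are documented so results can be
  compared like-for-like.
- Vendor raw-recording dialects are out of scope; raw traces enter via
  the archive's `raw_traces` dataset only, and spike sorting itself is
  upstream of this package.
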