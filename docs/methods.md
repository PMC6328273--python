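# Methods

`cpgph` implements the quantitative workflow used to characterize how two
crustacean central pattern generators — the pyloric rhythm of the
stomatogastric ganglion (STG) and the rhythm of the cardiac ganglion (CG) —
respond to stepped changes in extracellular pH. Because raw recordings from
such experiments are rarely deposited, the package pairs every analysis
stage with a synthetic-recording generator that produces data with the same
statistical structure and known ground truth, so each stage can be validated
by parameter recovery rather than by eye.

## Synthetic recordings

**Waveform model.** Each bursting unit is described by `BursterParams`:
burst frequency (Hz), duty cycle (fraction), spikes per burst, inter-burst
minimum potential `v_min` (mV), slow-wave amplitude (mV, trough to peak),
spike amplitude (mV, trough to peak above the slow wave), additive Gaussian
noise SD (mV), and a phase offset (fraction of the cycle). A cycle of period
`T = 1/f` contains a raised-cosine plateau: half-cosine ramps of 0.15 `T`
on either side of a flat top lasting `duty * T`. The ramp fraction shrinks
automatically (`min(0.15, 0.45 * (1 - duty))`) so a true inter-burst
baseline at exactly `v_min` always exists. The 0.15 default keeps the
envelope's spectral content well inside a 10 Hz low-pass band at pyloric
frequencies, so the decomposition stage can recover the programmed slow-wave
amplitude to within a few percent.

**Spikes.** Spikes are monophasic raised-cosine bumps of fixed 3 ms width
whose peaks span the flat top exactly (single spikes sit at the plateau
center). This makes three ground truths exact simultaneously: the
first-to-last-spike span equals `duty * T`, the global extrema of a
noiseless trace are `v_min` and `v_min + slow + spike`, and the
trough-to-peak spike amplitude equals the `spike_amplitude` parameter. A
template with a negative lobe cannot satisfy all three at once, which is
why the kernel is monophasic. Parameter sets whose spikes cannot fit the
plateau at 3 ms spacing raise `InfeasibleParametersError`.

**pH modulation.** A `PHResponseCurve` holds piecewise-linear tables of
multiplicative scales and additive shifts per parameter, anchored so that
pH 7.8 is the identity, defined over pH 5.5–10.4, plus a state schedule
mapping pH (snapped to the protocol ladder) to the intended rhythm state.
The default curves encode the qualitative directions reported for these
preparations — pyloric frequency falls in base and is comparatively
invariant in acid; spikes per burst and amplitudes collapse toward extreme
acid; LC spikes per burst rise in acid and fall in base; the STG schedule
degrades toward silence in extreme acid while the CG schedule degrades in
extreme base. The magnitudes of these tables are design choices (the
source experiments report directions and significance, not functional
forms) and are user-overridable; nothing downstream depends on their exact
values, only the recovery of whatever values are programmed.

**Experiments and protocols.** `build_protocol` produces the stepped bath
schedule: control pH 7.8, ~0.5-pH steps along the measured-at-11-degC
saline ladder (5.5, 6.1, 6.7, 7.2, 7.8, 8.3, 8.8, 9.3, 9.8, 10.4) to an
acid or base extreme, then at least 30 min of recovery at control.
`generate_experiment` lays down spike times analytically per step (STG:
PD leads, LP and PY burst in the PD inter-burst interval at phase offsets
0.45 and 0.70; CG: each LC burst rides inside the SC burst), records the
modulated parameters and scheduled state per step as ground truth, and can
render the voltage trace of any unit over any window deterministically
(noise is seeded from the experiment seed and the window).

**Population variability.** `sample_population` draws per-preparation
baselines with lognormal spread (default CV 0.15), sharing the frequency
multiplier across a preparation's units to keep the network phase-locked.
For statistical calibration and power studies, metric-level generators are
used instead of full trace synthesis: `generate_null_dataset` (subject
random intercepts, zero condition effect), `simulate_rhythmicity_table`
(programmable ganglion-by-pH means), and `generate_correlated_frequencies`
(bivariate-normal baseline/extreme pairs with exact programmed Pearson
correlation). These generate directly at the level the tests operate on;
they model between-subject variance and within-subject noise but not
waveform detail.

## Signal metrics

Spike detection emits one event per upward threshold crossing, timestamped
at the local maximum before the following downward crossing, with a 2 ms
refractory period. Thresholds are absolute (mV) or adaptive
(`median + 4 * 1.4826 * MAD`, robust when bursts dominate the amplitude
histogram). Burst segmentation uses the inter-spike-interval gap method:
maximal runs with consecutive ISIs at or below `max_intraburst_isi`
(recommended 0.25 of the expected period), discarding runs below
`min_spikes` (default 1). Per complete cycle: period is onset-to-next-onset,
instantaneous frequency its reciprocal, duty cycle the first-to-last-spike
span divided by the period; the final burst has no period and is excluded.
Firing rate is the reciprocal ISI, timestamped at the earlier spike.
Analysis windows are the last 8 min of each 15-min step, half-open
`[end - 480 s, end)`; binned summaries are arithmetic means in uniform 10-s
half-open bins aligned to the window start (48 bins per 8-min window), with
empty bins reported as missing, never zero.

Timestamping spikes at the post-crossing maximum makes burst onsets and
offsets — and therefore duty cycle — stable under noise; the convention
matters and is fixed throughout. Burst onset is the first spike
(extracellular convention); slow-wave depolarization onset is not used.

## Intracellular decomposition

`decompose_slow_wave` low-passes the trace with a 4th-order zero-phase
Butterworth filter and defines the residual as the sample-wise difference,
so slow + residual reconstructs the trace exactly by construction. The
default cutoff is 10 Hz: far below the spike band of a 3 ms action
potential (~300 Hz) and far above pyloric burst frequencies (~1 Hz), and
high enough that envelope harmonics pass undistorted — at 5 Hz the filter
rings on the burst envelope and slow-wave amplitude recovery degrades to
~6–13% error versus ~2–3% at 10 Hz. The forward-backward pass uses a
reflected pad of three filter time constants so edge transients do not
leak into the slow wave.

Measures: minimum membrane potential per inter-burst interval (direct scan,
timestamped at the argmin); slow-wave amplitude per cycle (max minus min of
the slow wave between cycle boundaries); spike amplitude per spike (max
minus min of the residual within ±4.5 ms, 1.5 template widths, skipping
spikes whose window leaves the trace); and trough frequency (reciprocal
interval between consecutive slow-wave troughs). Troughs are located one
per excursion of the slow wave below a level 25% of the 5–95% excursion
above its floor, at the midpoint of the sub-level region: with a flat
inter-burst baseline, the raw sample argmin is decided by numerical filter
ripple and alternates between the interval's ends, which Jensen-inflates
the mean of `1/dt` by ~10%; region midpoints are phase-stable and reduce
to the true minima for rounded troughs (exact on a sinusoid). For
intracellular work the last minute of each pH step is the conventional
analysis window.

## State classification

Five pyloric states: `normal_triphasic` (all of PD, LP, PY cycling with at
least three spikes per burst each), `weak_triphasic` (all cycling, some
unit spiking only once or twice per cycle), `intermittent_triphasic`
(rhythmic cycles present but at least one unit silent), `all_silent`, and
`atypical` as the explicit fallback (e.g. tonic firing without cycles).
Four cardiac states: `sc_lc_bursting` (at least one LC spike in at least
90% of SC bursts), `sc_only`, `all_silent`, `atypical`. A unit counts as
cycling with at least two bursts of period CV below 1 in the evaluation
window; bursts overlapping the window edges (within one ISI criterion) are
dropped so truncated bursts do not masquerade as weak ones. When a window
satisfies both the weak and the intermittent description, absence
dominates: it is intermittent.

Classification runs on 10-s evaluation windows advanced by 1 s; the label
stream is annotated with hysteresis: a transition is committed only when
the new state is held at least 10 s, stamped at the start of the sustained
run, with shorter excursions absorbed into the surrounding state. The first
segment starts at the window edge regardless of length, and the final run
is committed even when short, since it is truncated by the window rather
than demonstrably transient — this also makes annotation idempotent on
already-annotated streams. Rhythmicity is the fraction of time in
`normal_triphasic` or `weak_triphasic` (STG) or `sc_lc_bursting` (CG).

## Statistics

Per protocol direction, the pH effect on each measure is tested with a
repeated-measures ANOVA (pingouin) on one bin-averaged scalar per
preparation and condition — testing on individual 10-s bins would
pseudo-replicate. For these balanced single-within-factor designs the
Type I/II/III sums of squares coincide, so the classical decomposition
matches the Type III procedure; the Greenhouse–Geisser corrected p-value
is reported alongside the uncorrected one, and the uncorrected value gates
the post-hocs. Only when the ANOVA is significant at α = 0.05 are paired
t-tests of each step against the pre-protocol control run, Bonferroni
corrected over the family of non-control conditions tested (including the
recovery step by default; the family size is reported in the result). The
two ganglia are compared with a two-way mixed-measures ANOVA (ganglion
between subjects, pH within) and Bonferroni-corrected independent-samples
t-tests per condition. Baseline-versus-extreme relationships are Pearson
correlations of per-preparation means, pairwise-deleting missing
preparations and reporting the retained n (undefined below three pairs).
Distribution summaries report mean, median, IQR, t-based 95% CI of the
mean, and a Gaussian KDE with Scott's bandwidth.

Type-I calibration is checked by Monte Carlo: 1000 null tables
(15 subjects × 6 conditions, subject intercepts, zero effect) through the
package's own ANOVA path must reject at the nominal 5% rate within
binomial error, with family-wise error at or below nominal after gating
and Bonferroni; the two-condition identity `F = t²` is verified exactly.

## Electrode calibration

The pH electrode is modelled as Nernstian: `V = a + b * k(T) * pH` with
`k(T) = 2.303 R T / F` (59.16 mV per pH unit at 25 degC) and `b` a
dimensionless efficiency fitted together with the offset by least squares
from at least two buffer readings. The realized slope scales with absolute
temperature through `k(T)`; inversion at the stated bath temperature gives
the temperature-compensated voltage-to-pH conversion, exact to numerical
round-off on the round trip.

## Numerical conventions and problem sizes

Seconds from recording start, half-open intervals throughout; all
randomness flows through `numpy.random.default_rng` seeds, and identical
seeds give bit-identical outputs (traces, experiments, pipeline CSVs).
The test and acceptance workloads use desk-scale problem sizes chosen to
exercise every code path with comfortable statistical resolution: 8-min
windows at 10 kHz for recovery checks, six-step protocols for state
fidelity, 1000 Monte-Carlo replicates for calibration, and 200 random
instances per brute-force oracle comparison.

## Limitations

The generator is phenomenological: no conductance-based dynamics, no
synaptic coupling beyond fixed phase offsets, white (not pink) noise, no
electrode artifacts, no gastric-mill activity, and stereotyped spike
shapes. Passing recovery tests therefore demonstrates the correctness of
the analysis chain on data satisfying its assumptions, not robustness to
every pathology of real recordings (waveform drift, unit misidentification,
non-stationary noise). The statistical battery reproduces the procedure,
not the published F or p values, which would require the original
recordings. The recovery criterion of real protocols ("until frequency
approaches control") is qualitative; protocols here record a recovery
duration only.
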