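# Methods

`finsong` re-creates, end to end, the analysis chain used to characterize
fin whale (*Balaenoptera physalus*) 20 Hz song from a duty-cycled
single-hydrophone deployment: synthetic audio with ground truth, Raven-style
note measurements, inter-note-interval (INI) statistics, seasonal trend
models, and song-pattern classification.  This note records the models, the
parameters that matter, and the design decisions taken where the procedure
was genuinely open.

## The measurement model

**Spectrogram.** All spectral measurements run on a Hann-window spectrogram
with a 1024-point FFT and 90% overlap at fs = 2000 Hz, i.e. a bin width of
fs/1024 = 1.953125 Hz (printed as 1.95) and a hop of floor(1024/10) = 102
samples = 0.051 s (printed as 0.05).  The grid is energy-normalized so that
its total equals the time-domain energy `sum(x²)` up to window edge effects
(verified to 1% on 60 s signals); inband power is `10·log10` of the grid sum
over the selection box, in dB re full-scale energy.

**Frequency measurements.** Peak frequency is the maximum-energy bin
(ties to the lowest bin); center frequency and the 90% bandwidth endpoints
use the discrete cumulative-energy rule — the *lowest bin frequency at which
the ascending cumulative energy reaches q* (q = 50%, 5%, 95%) — with no
interpolation.  Every reported frequency is therefore a multiple of
1.953125 Hz, which is exactly the granularity of the observed field medians
(19.53, 17.58, 27.34, 3.91, 1.95 Hz are all multiples of it).  Frequencies
are labeled by the bin's lower edge k·fs/nfft (the Raven convention).

**SNR.** Each note's noise window has the same duration and frequency
bounds as the note and ends exactly 5 s before the note begins.  The
protocol fixes only "five seconds prior"; equal duration was chosen so the
signal and noise energies are commensurable.  With S the linear inband
power of the note box (signal + noise) and N that of the noise box,
`SNR = 10·log10((S − N)/N)`.  When S ≤ N the SNR is undefined: the note is
flagged and excluded from SNR-dependent statistics rather than floored,
since only high-SNR material is retained downstream anyway.  A noise window
that overlaps a preceding note (possible when INI < 5 s + note duration) is
measured as defined — the protocol is purely positional — but flagged.
Whether "center time" should be the selection midpoint or the energy-median
time is ambiguous in the source protocol; the midpoint is the default and
the only variant used in tests.

## The analysis chain and its filters

Filters run in a fixed order, because order changes the counts:

1. **Song duration ≥ 120 s** (last note end − first note begin).
2. **Song mean SNR ≥ 10 dB** (strict ≥, over notes with defined SNR).
3. **INI range filter**: INIs (center-time differences of consecutive
   notes) outside [4.5, 30] s are removed — surfacing gaps, missed notes,
   multipath.

Per-song summaries use linear-interpolated quantiles (the default of the
analysis environments practitioners use; configurable).  Period means pool
the kept INIs of all included songs in the period months — short-INI period
= September–December, long-INI period = March–May — and report mean ±
s.e.m. treating INIs as independent.  That independence is knowingly wrong
(INIs within a song are autocorrelated); dependence is the trend model's
job, not the summary's.  The pooled 75th-percentile SNR threshold and the
≥ 10 high-SNR-notes-per-day rule gate the spectral-characteristics subset.

Effort subsampling reviews every other calendar day starting with the first
full day of each deployment leg (the restart-per-leg reading of the rule is
an assumption), six recordings per day at hours 00/04/08/12/16/20, first
30 min of each — 3 h per reviewed day, so 653 reviewed days = 1959 h.
Singer identity is the ISO recording date (at most one analyzed song per
day); amplitude-based splitting of two-singer recordings assigns notes
within ±3 dB of a singer's running median level and declares the song
ambiguous — hence excluded — on any temporal overlap or two-sided match
(the ±3 dB tolerance and the ≥ 6 dB separation the generator guarantees are
package choices; the exclusion rule itself is the field protocol).

## Seasonal trend models

Two generalized additive mixed models describe INI seasonality, both Gamma
with log link (INIs are positive, right-skewed interval data) and a
per-singer random intercept:

- **M1**: `INI ~ s(month, cyclic, k ≤ 12) + s(song_year, k ≤ 5)` — one
  seasonal shape shared across years;
- **M2**: `INI ~ song_year + s(month, cyclic, k ≤ 12, by = song_year)` —
  a categorical year effect with a separate seasonal shape per year
  (first song year as reference level).

The month smooth is a cyclic P-spline: a periodic cardinal cubic B-spline
basis on 12 equally spaced knots at month midpoints (period 12) with a
circulant second-difference penalty, so predicted values and derivatives
join across December → January; month 13 wraps exactly onto month 1.  The
year smooth is an open cubic B-spline with a second-difference penalty
(with fewer than three distinct years it degenerates to a centered linear
term).  Sum-to-zero constraints make smooths identifiable next to the
intercept.

The engine is penalized IRLS (convergence at 1e-8 relative penalized
deviance, 200 iterations maximum, non-convergence warned never silently
accepted).  Random intercepts are ridge-penalized dummy coefficients —
the classical mixed-model equivalence.  Smoothing parameters, including
the random-effect variance ratio, minimize a Laplace approximation to the
negative marginal likelihood (Nelder–Mead over log λ).  The ML-type
criterion matters: a prediction-error criterion such as GCV lets the
random-intercept block absorb month-by-year structure (each singer sits in
exactly one month × year cell under the one-song-per-day design), which
masks exactly the M1-vs-M2 distinction the models exist to test.  Under
the marginal-likelihood criterion a group effect with no real variance is
shrunk away.  AIC uses the Gamma log-likelihood at the Pearson-estimated
dispersion with edf + 1 parameters, where edf is the trace of the hat
matrix; AICs are comparable across M1/M2 on identical data (enforced), and
selection is minimum AIC with ties to the smaller edf.  R² is reported as
adjusted deviance-explained and labeled as such; the 95% bands are
frequentist Wald intervals on the linear predictor, exponentiated under
the log link — both choices open in the source description and documented
here as package decisions.

Spectral-characteristic models (center frequency, peak frequency, 90%
bandwidth of high-SNR notes) reuse the machinery with Gamma family and
identity link, month basis dimension ≤ 10 (May–June notes can be absent),
year smooth ≤ 5, and a per-date random intercept.  Identity-link Gamma
fits can in principle produce non-positive means on pathological data; the
fit warns and clamps rather than failing silently.

Smooth-term p-values are Wald-type (block coefficient vector against its
posterior covariance pseudo-inverse at rank ≈ edf); parametric p-values are
t-tests at n − edf residual df.  These are approximations in the usual GAM
sense and are used for direction/significance properties, not for
reproducing printed coefficient tables — the observed-data coefficients are
not recoverable without the original recordings, which are not deposited.
An R `mgcv` fit serves as an independent oracle in the test suite (seasonal
shape correlation and level agreement), never as the implementation.

## The synthetic-data generator

The generator emulates exactly the statistical structure the chain
assumes:

- **Notes**: linear downsweeps with a named amplitude envelope.  The
  canonical note — 22.5 → 17.5 Hz, 0.9 s, Hann envelope, amplitude 0.5,
  noiseless — is frozen package-wide; measured with the standard
  spectrogram it reproduces the observed median peak frequency (19.53 Hz),
  median center frequency (19.53 Hz) and median 90% bandwidth (3.91 Hz).
  Its sweep bounds sit inside the conventional 23 → 18 Hz envelope of the
  20 Hz note; note duration and received levels are not reported for this
  population, so 0.9 s and −20/−26 dB re full scale peak are conventional
  assumptions, flagged in the configuration.
- **Songs**: 41 notes by default (40 intervals), inter-onset intervals
  Normal(mean, 0.3 s) clipped to [4.5, 30] s, singlet patterning by default
  (doublet alternation available; whether the population's INIs alternate
  is not documented), every 15th interval replaced by a surfacing gap
  drawn Uniform(35, 90) s — above the INI filter's 30 s bound by
  construction, so gap removal is exact.
- **Deployments**: 30-min recordings every 60 min; colored Gaussian noise
  (default −40 dB re full scale RMS, −3 dB/octave) scaled exactly to its
  target level; at most one song day⁻¹, placed at a reviewed hour;
  per-day child RNG streams keyed by calendar date, so extending the date
  range never perturbs existing days and equal seeds give bit-identical
  audio and truth tables.
- **Presets**: month-to-mean maps parameterized from the observed period
  means per song year (short ≈ 9.8–9.9 s in Sep–Dec, long ≈ 15.4–15.9 s
  in Mar–May).  Transition months (Jan–Feb, Jul–Aug) interpolate linearly
  between the flanking stable periods with 4× inflated jitter — an
  invention matching the qualitative description of variable transitional
  INIs, since no numeric transition profile is published.  The
  "constant long" preset models the anomalous year: one long-INI mean in
  every month plus configurable short-INI intruder songs; for the
  recovery scenarios its long mean is solved so that the *pooled*
  September–December truth mean (36 long songs + 1 October and 2 November
  intruders at ≈ 9.9 s, equal INI counts per song) equals the observed
  value for that year.

What the generator does **not** emulate: propagation and multipath,
hydrophone response, clock drift, vessel/fish noise taxa, overlapping
song sequences across recordings, or SNR that varies within a song.
Passing recovery tests therefore demonstrate that the measurement and
filtering chain is faithful — truth selection boxes go in, the right
period statistics come out — not that note *detection* (out of scope) or
real-ocean acoustics are solved.

## Classification rules

Songs are SHORT when the median kept INI is below 12.5 s (midpoint of the
~10 s and ~15 s modes; the boundary itself is LONG), else LONG; IQR > 2 s
flags a variable song.  A song year is SEASONAL_SHIFT when SHORT
predominates in Sep–Dec and LONG in Mar–Apr; CONSTANT_LONG (CONSTANT_SHORT
symmetric) when ≥ 75% of labeled songs carry one label including the
months where the other is expected; UNDETERMINED below 4 labeled months.
Within-month co-occurrence of both labels (≥ 2 songs) is flagged with
per-label counts.  Transition months are those whose across-song median
dispersion exceeds twice the stable-month dispersion or whose monthly
median is intermediate by > 1 s on each side of the two modes — the rule
measures intermediacy, so an abrupt step with no intermediate months
yields none.  All of these thresholds are package inventions exposed in
configuration: the original classification was done by visual inspection,
and the defaults merely reproduce it on well-separated data.

## Problem sizes and numerical choices

Recovery scenarios use the per-period song counts of the observed effort
(16 Sep–Dec songs for the year-2 short period, 13 Mar–May songs for
year 1, 39 Sep–Dec songs including 3 intruders for year 4), five
independent seeds pooled, full 30-min recordings, and the complete
waveform → spectrogram → center-time → filter chain; the acceptance
criterion is agreement with the observed period mean within two pooled
standard errors.  Model-selection simulations use 2–5 song years with 2–3
songs per month × year cell and 12 INIs per song, with a small (2%)
log-normal singer effect — enough data for the AIC direction properties
to hold in ≥ 90% of seeds while keeping a full simulation suite in
minutes on one CPU.  Spectrogram arithmetic is float32 (the 16-bit audio
path makes double precision moot); all statistics are float64.  Quantiles
are linear-interpolated except the spectral cumulative-energy rules, which
are deliberately discrete as described above.

## Known limitations

- Coefficient-level reproduction of the published model tables is
  impossible without the undeposited recordings; the models are validated
  structurally (direction, significance, periodicity, oracle agreement).
- The Wald/approximate p-values and frequentist bands understate
  uncertainty in the smoothing parameters themselves.
- The amplitude-based singer splitter is a deliberately simple two-level
  rule; it is exercised only on well-separated or clearly ambiguous
  synthetic scenarios, matching its role as an exclusion gate.
- Period s.e.m.s ignore within-song autocorrelation by design (see above).
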