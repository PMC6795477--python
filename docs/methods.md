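# Methods

This note documents the models and numerical procedures implemented in
`orifire`, the assumptions behind them, and the choices made where the
design was genuinely open.

## The population model of origin firing

A genome is a set of chromosomes carrying replication origins.  Each
origin has three parameters:

* **competence** `c ∈ [0, 1]` — the probability, per cell cycle, that the
  origin assembles a functional initiation complex and is *able* to fire;
* **t_mean, t_sd** (minutes into S phase) — the mean and spread of its
  firing time, drawn per cell from a Normal truncated at zero.

Per cell, each origin independently becomes scheduled with probability
`c`.  Outside hydroxyurea (HU), a scheduled origin whose locus has
already been replicated by an incoming fork is *passively replicated*
instead of firing.  Because all forks move at the same speed `v`, the
time at which locus `x` is first replicated is `min_j (t_j + |x − x_j|/v)`
over origins `j` that actually fired, so firing resolves by processing
scheduled origins in time order (ties broken by coordinate).  Population
**efficiency** — the fraction of cells in which an origin truly fires —
is therefore an emergent quantity: competence minus losses to passive
replication.

Each fired origin launches two divergent forks.  In HU, dNTP pools are
the limiting resource: a cell that fired `k` origins can synthesise at
most `D` kb in total (`dntp_budget`), split equally over its `2k` forks,
so each fork stalls after

    d_max = D / (2k)   [kb].

This makes the qualitative claim "fewer active origins per cell ⇒ each
fork travels farther" exact: halving the number of fired origins doubles
per-fork travel.  The functional form (equal split) is the simplest
budget model consistent with that claim; nothing downstream depends on
its details beyond monotonicity.  HU-stalled forks persist at their
stall positions and keep their ssDNA label; passive demotion is disabled
in HU because travel distances (≲1 kb) are negligible against
inter-origin spacing.  Checkpoint suppression of late origins is *not*
modelled; depletion and overexpression are represented purely as changes
to competence and firing-time parameters.

### Read-outs

* **Marker frequency (MFA)**: cells are assigned G1/S/G2 by the
  asynchronous-population fractions (default 0.3/0.5/0.2, matching an
  S-enriched cycling culture); S cells are sampled uniformly through S
  phase.  The per-bin mean copy number (1 unreplicated → 2 replicated)
  is the G1-normalised marker frequency and lies in [1, 2].
* **ssDNA profile**: every fork of every HU cell deposits a Gaussian
  footprint (sd `ssdna_footprint_sd`, default 1 kb — the scale of stable
  ssDNA at a stalled fork after smoothing); the population mean, scaled
  by `ssdna_amplitude` (default 3, giving wild-type peak ratios of ~3–4
  over a baseline of 1), is evaluated at microarray probe positions.
  Peak *splitting* emerges when per-fork travel exceeds roughly the
  footprint sd: the two fork signals flanking the origin separate.

### Tandem-array (rDNA) model

One origin per repeat (default 9 kb) fires with probability `p_fire`.
The replication fork barrier blocks the fork opposing 35S transcription,
so each initiation contributes a single productive fork moving toward
the next repeat downstream; the span to the next fired origin must be
covered by that one fork within the time budget, and repeats upstream of
the first fired origin have no covering fork.  The mean distance between
fired origins is `repeat_len / p_fire` (geometric waiting time) — 45 kb
at one-in-five firing.  The empirical Monte-Carlo mean sits ~2–3% below
the analytic value because spacings are truncated by the finite array.
Fork direction is uniformly "downstream"; the orientation of the barrier
relative to the transcription unit is abstracted away, since only
unidirectionality matters to the gap argument.

### Noise layers

Sequencing counts are Poisson per 1 kb bin with mean
`depth × copy number`.  Microarray noise is multiplicative log-normal
(default sd 0.15, a typical two-colour array CV) plus rare extreme
spikes (default rate 10⁻³, magnitude 20–100×baseline) so the outlier
filter has real work to do.  Probe spacing is irregular with ~1 kb mean
(Gamma-distributed gaps), an emulation choice — the real array design
pitch is not modelled.

## The processing pipelines

**MFA**: raw counts per 1 kb bin are divided by the sample's mean depth
over non-excluded bins (the rDNA array, 2-micron plasmid and
mitochondrial genome are excluded from the mean but still reported);
the S/G1 per-bin ratio is masked with the poorly-mapped-region list and
LOESS-smoothed in 50 kb windows.

**ssDNA**: per-probe S/G1 ratios are filtered genome-wide — values more
than 8 SD above or 2 SD below the genome mean are discarded, with mean
and sample SD (n−1) computed once before any removal — then
LOESS-smoothed over a 6 kb window (9 kb for noisier overexpression
samples) onto a regular 0.25 kb grid.  For cross-sample comparison each
sample is affinely rescaled so the modal smoothed value maps to 1.0 and
the genome-wide maximum to 2.0:

    rescaled_i = (v_i − baseline)/(v_max − baseline) + 1.

The baseline is estimated as the argmax of a Gaussian kernel density
(Silverman bandwidth) over all smoothed values; "mode of the
distribution" does not pin down a procedure, and the KDE argmax is
affine-equivariant, so the rescaled mode sits at 1.0 by construction.

**LOESS** is tricube-weighted local *linear* regression with a fixed
bandwidth in base pairs (the window is the full width; weights vanish at
±window/2).  Polynomial degree and kernel are unstated choices; local
linear with tricube is the standard default and reproduces constants and
straight lines exactly, which the tests rely on.  NaN observations are
excluded per local fit; output is NaN where fewer than 3 points carry
positive weight.  An independent brute-force weighted-least-squares
oracle cross-checks the smoother to 1e-9 in the test suite.

**Peak calling**: raw peaks are all interior grid points where the first
difference changes sign + to − (plateaus report their leftmost point;
NaN gaps split the profile).  The significance threshold is the 95th
percentile of raw peak heights — "top 5% of all peaks" ranked by
smoothed height, the only per-peak scalar defined at that stage.  The
single-instance shoulder exclusion is generalised to a rule: significant
peaks closer than 5 kb are merged keeping the taller (ties → leftmost).
Peak calling runs on smoothed but un-rescaled values; rescaling (affine,
rank-preserving within a sample) is applied before window areas, so the
significant set is unaffected by the order.

**Windows and areas**: windows are inclusive-symmetric on the grid — a
10 kb window at 0.25 kb step has 41 points, a 16 kb window 65.  The peak
area is the window sum of rescaled values (flat baseline ⇒ exactly 41.0);
missing points contribute the baseline 1.0 and are logged.  Tornado
matrices impose the reference sample's descending-area row order and a
shared colour scale on every sample of a group.

**Area regressions**: ordinary least squares `y = a + bx` over paired
per-origin areas, with R², residuals and fitted values.  The visual
judgment "are the residuals skewed?" is operationalised by two
diagnostics: the *t* statistic of a centred quadratic term added to the
model (convexity ⇒ weak origins disproportionately affected; note the
naive correlation of residuals with fitted values is identically zero in
OLS and useless here), and a Wald–Wolfowitz runs test on residual signs
ordered by fitted value.  Both are invariant to the per-sample affine
rescale.  Two caveats discovered on synthetic ground truth and worth
knowing when reading real data: (i) multiplicative measurement noise in
the *x* sample produces a small spurious *concave* bend
(errors-in-variables attenuation growing with signal), so only *convex*
curvature should be read as weak-origin bias; (ii) windows centred on
spurious reference peaks contribute a common baseline-area cluster to
every sample and inflate cross-sample R² — hence the reference origin
set is confirmed against an independent origin catalog before reuse.

## The synthetic studies (what the defaults emulate)

The wild-type ssDNA study runs on six 2 Mb chromosomes with origins
every ~100 kb (±20% jitter): ~120 origins over 12 Mb, the genome scale
and early-origin density of the budding-yeast assay.  Competences span
0.3–0.95 and mean firing times 5–15 min, so efficiency varies widely
across origins.  HU forks move at 0.3 kb/min and the per-cell budget is
100 kb, so a wild-type cell firing ~75 origins gives d_max ≈ 0.7 kb —
below the 1 kb footprint, hence resolved, origin-centred peaks, as in an
early HU sample; depletion (fewer fired origins) raises d_max and
broadens or splits peaks.  Populations are 800 cells.  Under these
conditions the pipeline calls ~120 significant peaks of ~2500 raw maxima
and recovers ≥95% of true origins within 1 kb, and two independent
wild-type runs correlate with R² ≈ 0.7 — the same reproducibility regime
as real untagged-strain comparisons, which emerged from the noise
parameters rather than being fitted to it.

Depletion regimes are competence transforms: *uniform* (×f), *biased*
(`c ← c·(c/c_max)^3·exp(ε)`, ε ~ N(0, 0.3²) — the most competent origin
untouched, weak origins hit super-linearly with origin-to-origin
susceptibility scatter; a purely deterministic monotone map would leave
areas collinear and could not reduce R², contradicting how severe
non-uniform depletion presents), and *equalized* (identical high
competence and early timing everywhere).  Slope comparisons across
depletion levels use baseline-subtracted *absolute* areas, because the
per-sample max-rescale cancels a uniform activity factor.

The five-origin marker-frequency fixture is a 1 Mb chromosome with two
early (5 min), one mid (15 min) and two late (25 min) origins firing at
deterministic times (every cell behaves identically), forks at 1 kb/min
and a 50 min S phase.  The MFA study sequences it at 2000 reads/bin
(~a few million reads for a 1 Mb chromosome, within the ~10 M reads/
sample effort the assay assumes) with 20,000 cells.  At 100 reads/bin
the post-smoothing noise floor exceeds the apex curvature left by the
50 kb window and maxima wander ±3–10 kb — a genuine resolution limit of
50 kb-smoothed marker frequency, consistent with the few-kb accuracy of
real MFA origin localisation.  Even at 2000 reads/bin, half-competence
late-origin apexes localise to ~2 bins at best; the dampening test pins
positions to ±2 bins and checks strict per-origin amplitude reduction.

### What passing tests do and do not show

The generator emulates stochastic firing, budgeted fork travel,
irregular probes, multiplicative noise and outliers.  It does *not*
emulate mappability artifacts, repeat families, copy-number segments,
array spatial effects, checkpoint feedback, or fork-speed heterogeneity.
Passing tests therefore validate the *inference machinery* — that the
pipeline recovers known origins, that amplitude dampening, peak
splitting, residual skew and decorrelation are detected when and only
when their causes are present — not that any particular biological
sample will show them.

## Numerical details and degenerate inputs

* Coordinates are 1-based inclusive internally; BED/bedGraph conversion
  happens only in `orifire.io`.  Missing values are explicit NaN, never
  dropped silently.
* `rescale_track` raises on a flat genome (max = baseline); LOESS
  windows must span ≥3 grid steps; `marker_frequency` turns zero/missing
  G1 bins into NaN with a logged count; zero-G1 probes are dropped.
* The truncated firing-time Normal uses proper truncation
  (`scipy.stats.truncnorm`), not clipping; `t_sd = 0` short-circuits to
  the deterministic time.
* Peak merging processes significant peaks in descending height
  (ties → leftmost), keeping a peak only if no kept peak lies within
  the merge distance on the same chromosome.
* All randomness flows from explicit `numpy.random.Generator` objects;
  scripts derive per-stage children from one seed via `SeedSequence`.

## Known limitations

* The equal-split dNTP budget ignores fork-level competition dynamics
  and any recycling of budget from terminated forks.
* The rDNA model ignores fork entry from the flanking unique sequence
  and clustering of active repeats (observed in reality), both of which
  would change completion probabilities at the array edges.
* The peak caller's top-5% rule couples the significant-peak count to
  the raw-maximum count; on genomes whose true origin count exceeds 5%
  of raw maxima, real origins are necessarily dropped.
* Background subtraction in the gel arithmetic assumes the background
  section approximates the lane/well background up to an optional scale
  factor supplied by the caller; no area normalisation is performed
  internally.
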