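# Methods

## Delta-event scoring

A dual-probe single-molecule RNA ISH assay images two probe sets for one
gene.  The C1 probe binds the exon region missing from the aberrant
isoform; the C2 probe binds a region shared by all of the gene's
transcripts.  A full-length molecule therefore contributes one signal to
each channel, while an exon-skipping molecule contributes only to C2.  Per
cell, the number of exon-skipping (Δ) transcripts is scored as

    Δ = max(C2 − C1, 0).

The clamp is deliberate and per cell.  Cells with more C1 than C2 signals
occur in real data (plausible causes include probe-efficiency asymmetry,
background, and transcripts truncated in the C2 region); their biological
interpretation is unresolved, so they score zero Δ events and are flagged
`discordant` rather than contributing negative counts.  Scoring is never
done on channel totals: one discordant cell would otherwise cancel genuine
Δ events in other cells.  A regression test encodes this distinction.

"Expressing" means any signal in either channel; a `c2`-only definition is
available via `expressing_mode` for analyses that prefer to condition on
the all-transcript channel.  Mean molecules per cell is the signal total
(C1 + C2) divided by all scored cells, expressing or not; full-length
molecules are counted once per channel, i.e. the quantity is a signal
mean, not a molecule mean.  Reports round means to one decimal and OR/CI/p
to two; machine output keeps full precision.

## Association statistics

Two 2×2 comparisons are built per carrier/control pair:

* transcript level: (Δ events, non-Δ signals) per row;
* cell level: (Δ-positive cells, Δ-negative cells) per row, the negative
  count always computed as n_cells − n_delta_pos.

Independence is tested with the Yates continuity-corrected chi-square,
χ² = Σ (max(|O−E|−½, 0))² / E with df = 1 and the expectation from the
product of marginals; the correction term clamps at zero so near-null
tables cannot acquire a positive statistic from the correction itself.
The uncorrected Pearson statistic is always computed alongside, because
for tables with small cells the two straddle conventional significance
thresholds and published small-table p-values are not always
continuity-corrected.  Empty margins are an error naming the margin.

Effect size is the cross-product odds ratio ad/bc with the Woolf (logit)
interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); z is the exact normal quantile
for the requested level, not the 1.96 shorthand.  With a zero cell the OR
and interval are undefined; the Haldane correction (0.5 added to every
cell) is available by flag and applied automatically by the bundled
`associate` convenience when a zero cell is present (and recorded in
`method_notes`).  Fisher's exact test and conditional-MLE intervals are
out of scope.

## Packaged 50-cell fixtures

No raw per-cell data exist for the published samples, so each fixture is a
hand-constructed 50-cell (c1, c2) table whose summary reproduces that
sample's published row exactly: cells expressing, total signals, total Δ
events, Δ-positive cells, per-cell Δ range, and the one-decimal means
(2.1 / 0.3 / 3.2 / 0.6).  Individual cell pairs are otherwise arbitrary;
fixtures include a few discordant cells, which real samples show.

Two published inconsistencies cannot be reproduced by any integer table:
the BRCA1 control per-cell signal maximum of 10 (c1 + c2 and c2 − c1 share
parity, so a Δ = 5 cell cannot have an even total; the fixture's maximum
is 9 with every other quantity exact), and the BRCA1 carrier cell-level
row whose Δ-positive (8) plus Δ-negative (37) cells sum to 45, not 50.
Summaries always use the computed complement (42); the printed table
(8, 37; 1, 49) is available as `PRINTED_CELL_TABLES["BRCA1"]` for
reproducing the published statistics as printed, and reports flag the
discrepancy when it applies.  Likewise the published BRCA1 cell-level CI
(2.26–137.60) and p (0.01) are reproduced by neither Woolf/Haldane nor the
Yates statistic — the p matches the uncorrected chi-square — so both
statistics are emitted and neither published value is treated as a
reference.

## Single-cell simulator

Per-cell transcript totals follow a zero-inflated negative binomial: a
cell is silent with probability π (`silent_fraction`); otherwise
T ~ NB(mean μ·m, dispersion k) with variance μ + μ²/k, Poisson as k → ∞.
The zero-inflation plus heavy-tailed NB is the simplest generative model
consistent with bursty transcription: >40% of cells with no target mRNA
next to single cells carrying tens of molecules.  Each transcript is
independently the Δ isoform with probability δ.  The multiplier m
(`nmd_multiplier`, default 1) scales the mean to emulate
nonsense-mediated-decay inhibition; presets describe treated cultures.

Detection: C1 ~ Binomial(n_full, eff_c1) + Poisson(bg_c1),
C2 ~ Binomial(n_full + n_delta, eff_c2) + Poisson(bg_c2).  Backgrounds are
unpaired between channels, so simulated data can show c1 > c2 discordance
just as real counts do.  Preset efficiencies are 1 and backgrounds 0 —
the assay's working assumption is one signal per molecule — and the four
detection parameters exist for sensitivity exploration.

Presets are moment-matched per sample from the published marginals.  With
perfect detection, signal totals satisfy Σc1 + Σc2 = (2 − δ)·T_total and
ΣΔ = δ·T_total, which inverts the published totals to transcript space;
μ then solves E[T | T > 0] = μ / (1 − NB(0; μ, k)) for the observed mean
among expressing cells (Brent root find), and π is set so that
P(T > 0) = (1 − π)(1 − NB(0; μ, k)) equals the observed expressing
fraction exactly.  Note π is below the observed silent fraction because
the NB component itself produces zeros: for the BRCA2 carrier
(58% expressing), π ≈ 0.17 with NB zeros making up the rest.  Dispersion
is fixed at k = 0.8 for all presets — small enough that a mean-4 sample
plausibly contains a 25-molecule cell, as the published ranges require;
it is a shape choice, not a fitted value, since per-cell distributions
were never published.  The treated/untreated fold changes (5.2×, 1.2×,
1.6×, 4.4×) are known only as mean ratios, so untreated presets simply
divide the mean and warn that they are uncalibrated.

Randomness: one `numpy` Generator per (seed, pipeline stage), all per-cell
draws vectorised in cell-index order — identical parameters and seed give
byte-identical output files.  Per-cell child streams were considered and
dropped: the package runs single-threaded and a generator per cell is pure
overhead at simulation sizes of 10⁴–10⁵ cells.

## Image rendering and quantification

Rendering places each observed signal as a symmetric Gaussian spot
(σ = `psf_sigma`, default 1.5 px) at a uniform-random sub-pixel position
inside its cell's disc, on a constant background with optional Gaussian
read noise; discs are non-overlapping by construction (grid layout
helper).  Coordinates are 0-based with x = column, y = row, documented in
every writer.  Page order of the TIFF stack: labels, C1, C2.  Placement
enforces a minimum pairwise spot separation (default 4σ) by dart throwing
and raises when a cell is too crowded — unresolvable spot pairs would make
the noise-free count round trip ill-defined; this also means the
simulator's counts-per-cell must stay within the disc's packing capacity
(the default 18-px discs hold ~15 spots per channel).  No subcellular
structure is modelled, and images are 2D only; neither does the renderer
emulate real-microscope artefacts (uneven illumination, chromatic shift,
autofluorescence), so detection results on these images bound what the
detector can do, not what real micrographs would yield.

Quantification: the label page gives exact masks (cells touching the
border are excluded and logged; a label split into disconnected pieces is
a corrupt-geometry error).  Detection per channel computes the negated
scale-normalised Laplacian of Gaussian at the PSF scale, centers it on its
median (the truncated kernel does not sum exactly to zero, so a flat
background otherwise leaves a constant offset), takes strict local maxima
above a threshold, and refines centers by the centroid of the positive
response patch (≈0.1 px accuracy on isolated spots).  The default
threshold is 6 robust-noise units (1.4826·MAD) of the response, floored at
10⁻⁴ of the image dynamic range so quantisation-level ripple in a
noise-free image cannot surface as peaks; a Gaussian spot's peak response
is ≈ amplitude/2, so at amplitude/noise = 10 spots stand ~20 response-σ
above noise, and maxima of pure noise over a megapixel (~5σ) stay below
the threshold.  Spot-to-cell assignment is containment of the rounded
center, boundary pixels inclusive; spots outside all masks are tallied in
a QC discard bin.  No C1↔C2 colocalisation is attempted, matching the
per-wavelength counting design of the assay.

## Sizes, tolerances, determinism

Monte-Carlo tests use 10⁴–4×10⁴ cells with 3–3.5 standard-error bands;
the calibration check pools 200 replicates of 50 cells (the study's
per-sample cell count) inside the 95% binomial band around the published
58%; Woolf coverage uses 2000 tables of 50 per row at a true OR of 2 and
asserts 93–97% coverage at nominal 95%.  Chi-square p-values are checked
to 6 significant figures against an adaptive-quadrature tail integral, and
OR/Woolf intervals against an independent implementation (statsmodels).
Image tests render 50-cell (360²) and 25-cell (625²) scenes; the full
suite runs in seconds.  Every stochastic component is seeded; property
tests run hypothesis derandomised.
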