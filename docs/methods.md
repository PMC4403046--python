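# Methods

## The assay and the analysis problem

A dual-condition cytotoxicity screen measures, for each siRNA pool of a
library, the luminescence of reporter-bearing tumour cells after knockdown,
in replicate plate sets incubated *with* cytotoxic T lymphocytes (toxicity
set) and *without* them (viability set). Because surviving cells produce the
signal, a knockdown that sensitises tumour cells to CTL killing lowers the
with-CTL signal only, whereas a knockdown that is simply toxic (or
protective) moves both conditions together. The analysis must therefore (i)
remove plate- and screen-level technical variation, (ii) put the two
conditions on a common scale, and (iii) score each gene by the component of
its with-CTL effect that its without-CTL effect does not explain. An
additional ATP-readout screen (no CTLs, luciferase-independent) guards
against reporter artifacts and generally cytotoxic knockdowns.

## Plate scoring

Scores are per-plate robust z-scores of log2 intensity over the plate's
sample wells: `score = (median − log2 I) / (1.4826 · MAD)`. The MAD
(median absolute deviation) with the 1.4826 normal-consistency factor makes
the denominator an outlier-resistant standard-deviation estimate, so a
plate with a handful of strong hits is scored on the scale of its bulk.
The sign flip encodes the convention *positive score = reduced viability*.
Control wells are scored on the sample-derived scale but never contribute
to the median or MAD. Scoring only depends on intensity ratios within a
plate, so it is exactly invariant under positive rescaling of a plate
(reader gain, reagent lot) — the property that makes scores comparable
across plates and screens. Replicates are scored separately and then
averaged per gene (median optional); computing per-replicate scores first
keeps the replicate layer available for QC.

Degenerate inputs: a plate needs at least 8 sample wells with finite,
positive intensity; a plate whose sample wells have zero MAD (no spread) is
an error naming the plate, because its scores would be undefined. Zero
intensities are treated as missing for scoring (log2 undefined).

Replicate QC reports both Pearson (primary) and Spearman correlation per
(screen, condition): rank-based agreement is the standard robust companion,
and reporting both sidesteps choosing between them.

## Cross-condition quantile normalization

The with- and without-CTL score vectors of one screen are forced onto a
common distribution: the target is the elementwise mean of the two sorted
vectors, and each value maps to the target at its rank; ties within a
vector receive the mean of their tied ranks' targets. For tie-free input
(the generic case — scores are continuous) the two sorted outputs are the
identical multiset; with ties the tie-averaging can make the multisets
differ slightly, a standard property of tie-averaged quantile
normalization. Normalization is applied to replicate-summarized vectors,
once per screen.

## Loess differential score

Within a screen, toxicity is regressed on viability by loess: at each point
the `ceil(span · n)` nearest neighbours by |Δx| (boundary ties all
included) are fit with a weighted polynomial under tricube weights
`w = (1 − (d/d_max)³)³`, and the fitted value is the polynomial at the
point. Defaults are span 2/3, degree 1, no robustness iterations — the
classic lowess settings — all exposed in config. The differential score is
the residual `d_g = tox′_g − fit(via′_g)`; positive d means knockdown
enhances CTL-mediated killing beyond its viability effect. A
`simple_difference` mode (`d = tox − via`, no normalization or regression)
is kept as the first-order version of the same contrast; the loess residual
is the default because it absorbs any smooth, possibly nonlinear
relationship between the two condition scores instead of assuming slope 1.

Numerics: the local fit solves a square-root-weighted least-squares problem
by QR (numpy `lstsq`); points exactly at the neighbourhood boundary get
weight zero (the tricube vanishes there); a neighbourhood collapsed onto a
single x value degenerates to the flat weighted mean; rank-deficient local
designs fall back to the minimum-norm solution. The implementation is
checked in the tests against an independent brute-force solve of the
explicit normal equations and against the classic lowess implementation in
statsmodels.

## Filters and consensus

Three independent per-gene predicates, strict inequalities, defaults
(2, 0.5, 1.5):

- excluded if |without-CTL score| > 2 in any screen (intrinsic-viability
  artifact);
- required |with-CTL score| > 0.5 in every screen (a reproducible effect
  under CTL pressure);
- excluded if |ATP-readout score| > 1.5 (orthogonal viability filter).

Because the predicates are independent, the surviving set is a single
conjunction and cannot depend on application order. The published wording
of the two luciferase-score clauses admits either polarity; the default
reading (exclude on viability, require an effect) matches the stated goal
of removing viability artifacts while keeping CTL-dependent effects, and
both polarities are switchable (`Thresholds.viability_excludes`,
`Thresholds.effect_requires`).

A surviving gene is a consensus hit when sign(d) is identical across all
screens and min |d| ≥ 0.5 in each; the effect cutoff 0.5 is reused for the
differential axis since no separate cutoff is published. Classes are named
by mechanism: `suppressor_candidate` (d > 0 everywhere: knockdown enhances
killing, the PD-L1-like case) and `activator_candidate` (d < 0 everywhere).
Clustering of the gene × screen differential matrix (agglomerative,
Euclidean distance, complete linkage, both configurable) orders the heatmap
export; rows are pre-sorted by gene id so results are independent of input
row order. Clustering is descriptive — the hit call is the mechanical
filter + consensus rule, not a cluster membership.

## Synthetic screen generator

The generator realises, per well, `log2 I = b + plate + row + col + v_g +
[with_ctl](k + m_{g,s}) + ε` with `ε ~ N(0, σ)`; intensity is `2^L`
(log-additive = multiplicative on the raw scale, the standard form for
luminescence data). The ATP-readout condition ignores `k` and `m` (no CTLs
present). Heterogeneity of immune modulation across screens — different CTL
donors, stable versus transient reporter delivery — is collapsed into one
parameter: `m_{g,s} = m_g (1 + h · η_{g,s})`, `η` standard normal per
(gene, screen).

Defaults (log2-scale effects unless noted):

| parameter | default | rationale |
|---|---|---|
| `baseline_log2` b | 10 | typical plate-reader RLU magnitude (~1000) |
| `kill_effect` k | −0.5 | baseline CTL killing hits all with-CTL wells |
| `noise_sd` σ | 0.3 | replicate Pearson ≈ 0.8–0.9, the range good screens report |
| `plate_effect_sd` | 0.15 | modest inter-plate variation for normalization to absorb |
| `row/col_gradient` | 0 | edge gradients exist in HTS but are off by default; enable to stress scoring |
| `background_v_sd` | 0.6 | intrinsic-viability spread of ordinary knockdowns; see below |
| `heterogeneity` h | 0.2 | visible but not sign-flipping cross-screen variation |
| planted modulator \|m\| | U(1.25, 2.0) | sized like the reference immune-suppressor control (−1.5) |
| planted lethal v | −U(3.5, 4.5) | sized like the lethal control (−4) |
| `control_suppressor_m` | −1.5 | reference immune-suppressor effect |
| `control_lethal_v` | −4 | survival-gene knockdown, near-complete killing |
| `fluc_log2_offset` | −8 | reporter-targeting control drops to instrument background |

Neutral genes (no immune modulation, m = 0) carry a background
intrinsic-viability effect `v ~ N(0, background_v_sd)` rather than v = 0
exactly: real siRNA pools always perturb viability somewhat, and without
any spread among sample wells a noise-free plate would have MAD = 0 and be
unscorable by design. Planted suppressors and activators have v = 0
exactly, mirroring the geometry of the biological controls (the reference
immune-suppressor moves only the with-CTL axis). Set `background_v_sd = 0`
for the idealised library in which neutral means v = m = 0 literally.
Luciferase-targeting control wells sit at a fixed background
`2^(b−8+ε)`; the noise is applied on the log scale so intensities stay
positive and the σ = 0 closed form is exact.

The noise stream is drawn in a fixed well order independent of the truth
values, so perturbing one gene's planted effect under the same seed changes
only that gene's affected wells (monotonicity). One master seed is split
into independent child streams for the truth draw and the well noise; the
run manifest records seed and config hash, and no output carries a
timestamp, so identical config + seed reproduces every output byte for
byte.

What the generator does **not** emulate: siRNA off-target structure,
transfection-efficiency spatial waves, duplex-level deconvolution (the 4
duplexes per pool are metadata), non-Gaussian heavy-tailed well failures,
and any real correlation structure between viability and immune modulation.
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under this generative model, not that it would achieve the
same sensitivity on a real screen.

## Problem sizes

The default simulated experiment is the full published geometry — 520 pools
on two 384-well plates, three dual-condition screens × 2 replicates plus an
ATP-readout screen × 2 replicates (28 plate instances, ≈ 9,700 wells) — and
runs in well under a second per seed; the recovery evaluation averages 20
seeded experiments. Loess/oracle agreement is checked on 100 random
instances of 20–50 points, the regime where every neighbourhood boundary
case (small k, ties, span 1) is exercised.

## Known limitations

- With only 2 replicates per condition there is no meaningful per-gene
  variance estimate; selection is threshold-based, not inferential, and no
  p-values or multiple-testing control are produced (by design).
- The loess residual removes any trend shared by the two conditions; an
  immune modulator whose effect is exactly proportional to its viability
  effect across all genes would be absorbed into the fit.
- Quantile normalization assumes the bulk of genes are unaffected by CTL
  exposure beyond the global kill; screens where most knockdowns modulate
  killing would violate it.
- The generator's heterogeneity parameter is a one-dimensional surrogate
  for real biological differences between screens (CTL source, reporter
  delivery); it reproduces cross-screen score spread, not its mechanism.
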