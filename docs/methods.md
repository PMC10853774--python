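# Methods

This note documents the models, conventions and numerical choices behind
`minishape`, and what its synthetic-data tests do and do not demonstrate.

## Construct model and coordinates

A minimized construct is an ordered concatenation of inclusive native spans
joined by synthetic junction elements. Coordinates are 1-based and inclusive
throughout, matching 23S rRNA residue numbering; there are no half-open
intervals anywhere in the API. Inserted junction residues receive integer
labels continuing the preceding segment's numbering (the A4 tetraloop closing
the helix that ends at 2091 is labelled 2092–2095 — unambiguous because the
following native residues are excised). If an auto-continued label would
collide with a retained native position, assembly refuses and asks for
explicit labels. Flank residues are labelled `F5.k`/`F3.k`, since they carry
no native number. Segments listed out of 5′→3′ order are an error, not
silently sorted: strand order is a design statement. DNA input (`T`) is
converted to RNA (`U`) with a logged warning rather than rejected, because
transcription templates are DNA.

The coordinate map is stored explicitly per position, making
native→construct→native round trips exact by construction; excised native
positions map to *absent* (`None`), not an error, so callers can distinguish
"not in this construct" from "bad query".

The exact reference-hairpin flank sequences of a probing construct are an
experimental choice, so flanks are user input rather than constants. The
`simulate` module ships a synthetic 73-nt flank pair (GAGUA loops on short
stems) solely so the 284 → 357 nt arithmetic and the normalization contract
can be exercised end to end.

## Mutation algebra

Mutations are substitution-only triples (wild-type base, native position,
substituted base). Duplicate positions within one list are a hard error —
catalogued designs never repeat a position, and silent last-wins would hide
typos. `apply` verifies the declared wild-type base against the construct and
`diff` returns substitutions in ascending native order, so `apply ∘ diff` and
`diff ∘ apply` are mutual inverses on constructs sharing a coordinate map
(property-tested).

The allowed-position rule for crowdsourced design is a thresholded union over
user-supplied tables: positions whose variant frequency among homologs
exceeds 1% (strict), or whose retained ribosome activity upon mutation is at
least 40% (inclusive). The union reading is the default because loosening a
frequency-only rule by an activity criterion widens, never replaces, the
allowed set; `mode="frequency"`/`"activity"` keep the single-rule readings
available. The underlying comparative-sequence and activity datasets are
external and not bundled; the shipped tests construct synthetic tables (44
positions passing the frequency rule, 35 more passing the activity rule,
union 79) to pin the arithmetic, not the biology.

## Reactivity processing

Replicate handling averages modification replicates and control replicates
separately, then subtracts — the simplest contract consistent with
subtracting control reactivities, since no replicate pairing is defined.
Errors propagate the two standard errors of the mean in quadrature. Negative
differences are clamped to zero (and counted in the log): reactivities are
non-negative by definition. Missing data use the `.shape` community sentinel
−999 and are excluded from every statistic.

Hairpin normalization divides by the mean reactivity over the designated
GAGUA loop positions, making the profile scale-free (normalize(c·x) =
normalize(x), property-tested) and pinning the reference mean at exactly 1.
A non-positive reference mean is an error — it means the reference hairpins
did not react and the experiment cannot be normalized.

Unit scaling is plain min–max over non-missing values; a winsorized variant
(quantile clipping before scaling) is available but off by default. Heatmap
classification uses strict inequalities — high above 1.5 (experimental) or
0.5 (predicted), low below 0.5 / 0.25, values exactly at a cutoff are
intermediate — so every non-missing position falls in exactly one class.

The significance predicate behind the paired-reactive count (the fraction of
Watson-Crick-paired positions reacting over background) is pluggable; the
default is "reactivity > 0.5", the low-experimental cutoff.

## Profile comparison and outliers

Pearson correlation is computed over pairwise-complete positions (≥ 3
required). "Noise-adjusted" correlation is implemented as attenuation
correction: reliability = 1 − mean(error²)/var(exp), clipped to (0, 1], and
ρ_adj = ρ/√reliability, clipped to [−1, 1]. This is one standard
disattenuation; because other definitions exist, the unadjusted ρ is always
reported alongside.

Distribution selection fits each candidate family (default Cauchy, Normal,
Laplace, Logistic) by maximum likelihood and ranks by the sum of squared
errors between the fitted density and the empirical histogram density on
fixed 0.1-wide bins over [−1, 1] — the natural bin rule for unit-scaled
differentials. Ties keep the candidate listing order.

Outlier calling uses quartiles by linear interpolation between order
statistics (the common default; other quantile rules shift fences slightly)
and Tukey-style fences at Q1 − m·IQR / Q3 + m·IQR with m = 3 ("extreme"
outliers). The alternative absolute reading (|Δ| > m·IQR) is available via
`mode="absolute"`. Fences satisfy lower ≤ Q1 ≤ Q3 ≤ upper for any input, and
widening the multiplier never adds outliers (property-tested). Region
assignment is first-declared-wins over the annotation list, with the shipped
defaults covering the P-loop, A-loop, tetraloop, L75–L80, L89, L91, L90–L93
and the central loop. Design ranking sorts descending by adjusted ρ with ties
broken by name, and flags each design as improved (strictly above the
reference) or worse.

## Footprinting and yields

Protection calls use bound-minus-free deltas with a default threshold of 0.3
normalized reactivity units — the cutoff is configurable because published
footprints are shown on a continuous colour scale without a stated numeric
boundary — plus an optional z-gate (|Δ|/pooled error ≥ 1.96) when replicate
errors are available. Free and bound profiles must be in the same processing
state; either hairpin-normalized or unit-scaled profiles are accepted, as the
calls only require a common scale. The reference protected-residue set is a
user-supplied annotation, not a constant.

EIC extraction keeps records with |m/z − target|/target ≤ tolerance (ppm,
inclusive boundary with a 10⁻⁹-ppm round-off guard) and integrates intensity
over retention time by the trapezoid rule; an empty window yields area 0,
flagged rather than raised. The yield is (product area / internal-standard
area) × 10³, homogeneous of degree zero in the areas. Cross-condition
statistics on yields (ANOVA and post-hoc tests) are deliberately out of
scope; yields are emitted as tidy values for external tools.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical shape* of the pipeline's inputs:

- paired positions draw reactivities from a half-normal law (scale 0.15),
  unpaired from a gamma law with mean 1.2 (shape 4, scale 0.3) — a standard
  caricature of SHAPE reactivity by pairing class;
- three modification and two control replicates, Gaussian replicate noise
  (default SD 0.1) and an additive background (default 0.2), clipped at zero;
- predicted/experimental pairs from a bivariate normal at a chosen
  correlation, min–max rescaled to [0, 1] (affine, so the correlation is
  preserved exactly);
- planted outliers, planted protections and Gaussian chromatographic peaks
  with recorded true areas.

All randomness flows through one seeded `numpy` generator, so equal seeds
give byte-identical outputs, and every generator returns the pre-noise truth
for recovery tests. What the synthetic data does **not** emulate:
capillary-electrophoresis artefacts (band overlap, reverse-transcriptase
drop-off, ladder misassignment), position-dependent background, or the
spatial correlation structure of real predicted profiles. Passing
recovery tests therefore demonstrate that the *computations* are correct and
well-conditioned at realistic problem sizes (n = 284 positions, 200-seed
Monte-Carlo batches, 5000-sample distribution fits), not that any particular
biological construct folds as designed.

The synthetic numbered source in `simulate` plants the catalytically
important motifs and every catalogued wild-type base at its native position
and fills the rest at random: sequence lengths, numbering, motif content and
mutation arithmetic are faithful; the remaining bases are not biological.

## Problem sizes and numerical tolerances

Default test and acceptance problem sizes — 284-position profiles, 200 seeds
for correlation recovery (tolerance ±0.05 on the mean, against a sampling SE
of ≈0.002), 100 seeds for outlier and footprint recovery, 5000 samples for
distribution selection (location/scale recovered within ±0.02), 2000-point
retention-time grids (trapezoid area within 1% of the closed form) — were
chosen so each statistical check has comfortable power while the whole suite
runs in seconds. Degenerate inputs fail loudly: constant profiles cannot be
unit-scaled or fit, zero-variance profiles have no correlation, and fewer
than four deltas have no quartiles.
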