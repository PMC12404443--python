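# Methods

## Variant spectra

A "variant type" is a distinct alternate amino acid observed at a residue,
regardless of the underlying nucleotide change; rows of a gnomAD-style
export that encode the same substitution through different nucleotide
variants are summed, never deduplicated. Allele counts feed abundance
(normalized spectra); type counts deliberately ignore abundance, so a
position with {Val:121, Thr:8, Ile:2, Arg:2} has 4 types. Rows without an
allele count default to 1 with a logged warning; zero-count alleles are
dropped so every stored count is ≥ 1. Nonsense (`Ter`), frameshift and
synonymous consequences are rejected with distinct errors and skipped (and
tallied) by the CSV reader.

Ortholog numbering is mapped by a constant signed offset (human TRPV1 →
rat TRPV1 is −1 across the ARD). Arbitrary per-segment offsets can be
composed by applying different `NumberingMap`s to row subsets; nothing
beyond offset maps (no alignment-based liftover) is in scope.

## Solvent-accessible surface area

SASA is computed with the Shrake–Rupley method: each atom's solvent-expanded
sphere (van der Waals radius + 1.4 Å water probe) is covered with *n* test
points, and its area is 4π(r+p)² times the fraction of points outside every
neighbor's expanded sphere. The point set is a golden-angle spiral — fully
deterministic, so identical inputs give identical areas — with 960 points
by default, where the isolated-sphere error against the closed form is
< 0.01 % and doubling the count moves helix-fixture totals by < 1 %.
Neighbor search uses a k-d tree; exactly coincident atoms raise a
degenerate-geometry error rather than silently occluding each other.

Elements map to Bondi-style radii (C 1.70, N 1.55, O 1.52, S 1.80 Å …);
unknown elements fall back to 1.8 Å with a warning. Fractional SASA
(relative solvent accessibility) divides the per-residue sum by the
theoretical maxima of Tien et al. 2013; values above 1 can occur in
extended conformations and are reported as-is, with a warning above 1.2.

Burial in an oligomer is context dependent: the default is to compute SASA
with all chains present (for a tetrameric channel, the assembly buries
inter-subunit surface) and then report one chain. Residues missing from
the structure are simply absent — never imputed — and are therefore
excluded from burial ranking. Hydrogens, waters and hetero records are
excluded; for alternate locations the highest-occupancy conformer is kept.

## Burial profile and discordance

Residues are sorted by ascending fractional SASA (ties broken by residue
number) and ranks 1..N assigned; variant-type counts are then smoothed
along the rank axis with a centered moving mean of width 20, truncated at
the edges with the divisor equal to the number of in-window points (so a
constant series is preserved and the interior impulse response is 1/20).
For the even default width the window is left-heavy, [i−10, i+9], matching
the pandas `rolling(center=True)` convention that the test suite uses as
an independent oracle.

The discordance score of a residue is its raw type count minus the
smoothed expectation at its rank. Two permutation p-values are offered,
because two different questions arise:

* **Discovery** (`discordance`): the null permutes all type counts across
  ranks and the reference statistic is the maximum raw score over the
  buried (lowest-SASA) half; p = (1 + #{null max ≥ observed})/(B + 1).
  The p-value attached to the top-scoring buried residue is uniform under
  the exchangeable null (KS-verified in the test suite), which is the
  right calibration when the residue was found by scanning the profile.
  By construction this null retains every observed count — including a
  lone extreme one — so a singleton outlier's own count props up the null
  maximum and its p-value plateaus near the probability that the count
  lands in the buried half. That is intentional for discovery (it is the
  multiplicity price of scanning), but it is the wrong null for a residue
  chosen in advance.
* **Pre-specified site** (`conditional_discordance_p`): the candidate's
  count stays at its rank, only the other counts are permuted, and the
  candidate is excluded from the null maximum. For a buried residue with
  4 types over a flat Poisson(0.5) background this gives p = 1/(B+1).

Under a SASA-coupled background the exposed half genuinely contains
residues with more types than a buried outlier, so permutation nulls that
scatter those counts into the buried half are conservative there; the
outlier is still identified as the top raw score among buried residues.

Conservation is quantified per alignment column: the column holding a
reference residue is located by counting the reference sequence's non-gap
letters from its stated start, and identity is the fraction of non-gap
letters matching the reference's letter (gaps shrink the denominator).

## Dose–response fitting

Normalized currents (reference: the response at 5 µM capsaicin, which is
assumed saturating) are fitted to the Hill equation
I = Imax·[L]ⁿ/(EC50ⁿ + [L]ⁿ) by bounded least squares with all three
parameters free, EC50 ∈ (0, 100] µM and n ∈ (0, 10]. Because the Hill
surface has local minima for steep curves sampled at few concentrations,
the fit restarts from a 3×3 grid (EC50 ∈ {0.03, 0.3, 3} µM,
n ∈ {1, 2, 4}) and keeps the best residual; non-convergence sets a flag
on the result instead of raising. On its own forward model the fit is an
exact inverse (< 1e-6 relative error); with additive noise σ = 0.05 the
median EC50 error over 200 replicates is ~8 %.

## Single-channel analysis

The +80 mV segment of each voltage sweep is concatenated in sweep order.
Baseline drift is removed with a rolling 10th-percentile estimate
(default window 1 s, evaluated on quarter-window blocks and linearly
interpolated), then the trace is re-zeroed on the peak of its amplitude
histogram: a low percentile of noisy closed-state samples sits ~1.3 σ
below their mean, and the histogram mode (bin width tied to a robust
noise estimate from first differences) is the closed-state level whenever
the channel is shut more than half the time — the regime the estimator is
intended for; traces with Po > 0.5 would need the polarity of the
correction checked.

Idealization uses half-amplitude thresholds: with unitary current *i* and
k channels the occupancy level is round(sample/i) clipped to [0, k]
(thresholds at (m−½)·i), and Po is the mean level divided by k. Openings
are treated as positive deflections; a flag flips polarity for −80 mV
segments. The estimator is exact on square waves, scale-invariant, and on
two-state Markov simulations (Po = 0.3, 60 s at 20 kHz) lands within
Monte-Carlo error of the true time-averaged Po, whose standard error we
take as √(2Po²(1−Po)²(1/α+1/β)/T).

Macroscopic "approximate Po" is the current under a condition divided by
the maximal reference response; this assumes Po ≈ 1 at the reference
stimulus, which is documented, not asserted — over-unity ratios are
reported with a flag rather than clipped.

## Temperature relations

Each cell's steady-state +100 mV currents are normalized by that cell's
mean current inside the room-temperature window (20–25 °C — "room
temperature" made concrete); cells are pooled and summarized per 2 °C
half-open bin (centers on multiples of 2 °C) as the median across cells
with the standard error across cells. Normalizing per cell before pooling
cancels the large cell-to-cell spread in channel expression.

## Calcium-imaging responder counts

Per-cell fluorescence traces are classified by a relative-rise rule:
baseline F₀ is the mean over all pre-capsaicin frames; a cell is a
capsaicin responder if max ΔF/F₀ between the capsaicin and ionomycin
additions reaches θ, else ionomycin-only if the post-ionomycin rise
reaches θ, else excluded (dead cells and start-bright-and-flat cells never
rise, so both are excluded; F₀ ≤ 0 is excluded with a logged cause). The
published counting was a manual brightness judgment on contrast-adjusted
movies; θ = 0.5 is this package's explicit stand-in and must be reported
with any result. The response fraction is responders over healthy
(responder + ionomycin-only) cells; excluded cells never enter the
denominator. Same-day control normalization is a plain ratio of fractions
(control against itself is exactly 1); ratios above 1 are permitted.
Duplicate cell ids are rejected structurally. Segmentation, ROI
extraction and bleaching correction are out of scope — the module starts
from per-cell traces.

## Synthetic data: what it does and does not emulate

Every generator uses `numpy.random.default_rng` with an explicit seed and
returns ground truth next to the data; identical configuration is
bit-reproducible, and generators emit the same file formats the readers
consume.

* **Variant tables**: per-residue type counts ~ Poisson(exp(a + b·fSASA))
  truncated at 19, defaults a = −1, b = 2 (a buried-residue mean of ~0.4
  types rising to ~2.7 when fully exposed); allele counts per type are
  geometric on {1, 2, …} with p = 0.3, mimicking the heavy-tailed allele
  spectrum. Planted outliers add extra types at chosen positions. Not
  emulated: mutational-opportunity structure of the genetic code, linkage
  between sites, per-population stratification.
* **Structures**: ideal α-helix backbone + Cβ (φ = −57°, ψ = −47°,
  standard peptide bond lengths/angles, Cα–Cα ≈ 3.8 Å) as valid PDB text.
  Terminal residues are more exposed than central ones, which is all the
  SASA fixtures need; there are no side chains beyond Cβ, no packing, no
  quaternary context.
* **Channel records**: continuous-time two-state (closed⇌open) Markov
  gating per channel, sampled at the recording rate, plus Gaussian noise
  and optional linear drift. Defaults (α = 30 /s, β = 70 /s, i = 8 pA,
  20 kHz, 60 s, σ = 0.1·i) give stationary Po = 0.3 with thousands of
  gating events. Not emulated: filtering artifacts, flicker/subconductance
  states, multi-state kinetics.
* **Dose–response**: Hill curve at the six assay concentrations (0.03,
  0.1, 0.3, 1, 5, 10 µM) plus additive Gaussian noise (σ = 0.05 default).
* **Temperature ramps**: two-state van 't Hoff occupancy (ΔH = 60
  kcal/mol, midpoint 44 °C — a steep heat-activation curve in the
  physiological range) times a log-normal per-cell maximal current, plus
  fractional leak and multiplicative noise, on a 10–60 °C ramp.
* **Cell fields**: multinomial labels at the planted fractions; step
  responses at the stimulus times; excluded cells are flat (half dim,
  half start-bright). Noise scales with intensity (shot-noise-like) so
  dim dead cells do not generate spurious relative rises.

Passing tests on these generators show that each analysis inverts its own
forward model at realistic sizes and noise; they do not show robustness
to the artifacts real recordings add (seal instability, perfusion
transients, photobleaching, segmentation errors).

## Numerical choices and degenerate inputs

Burial ties break by ascending residue number; empty series, empty
selections, zero references, windows that do not fit, and zero healthy
cells all raise distinct, documented errors. Permutation p-values carry
the +1 correction, so the floor is 1/(B+1). The acceptance script derives
all sub-seeds from one `--seed` via `numpy.random.SeedSequence` and keeps
them below 2³¹.

Problem sizes used by the test suite and the acceptance script — 251
residues (the ARD span), 200 dose–response replicates, one 60 s single
channel record at 20 kHz, 100 correlation seeds, 200-cell imaging fields,
199–999 permutations — are the package's chosen defaults for exercising
every stage at full fidelity.

## Known limitations

The structural rank of a residue depends on the SASA context convention
(isolated subunit vs. full assembly); the package defaults to the full
deposited assembly, and the check against the published rank-35 anchor for
M308 in PDB 7LP9 requires fetching the deposited tetramer at test time.
The discordance formalization replaces a visual outlier call and should be
read as a screening statistic, not a calibrated pathogenicity measure; the
macroscopic Po is approximate by construction; and the ΔF/F₀ threshold θ
is a reporting parameter, not a biological constant.
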