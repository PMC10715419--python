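# Methods

This note documents the models, defaults and numerical choices behind
`uremia-omics`, and what the synthetic-data validation does and does not
demonstrate about real cohorts.

## Study design being modeled

Three serum arms: healthy controls (CTRL, n = 10), ESKD patients before
dialysis (PRE, n = 10) and the same patients after one session (POST,
matched within subject). Pooled-QC injections (equal parts of every
sample) gauge technical stability; blank injections gauge background.
TMT proteomics uses five reporter channels per condition (15-plex
layout). All thresholds default to the study values: feature QC at
CV 50% / blank ratio 5 / S/N 3 / peak width 6 scans; metabolite
significance at |FC| ≥ 2, p < 0.05, FDR < 0.05; clearance at ≥ 2-fold
significant POST/PRE drop; protein significance at FC > 1.5; mass
tolerance 1 ppm (positive) / 2 ppm (negative); RT window 2.0 min (the
largest RT shift observed across the 21 confirmed standards); MS2 score
0.7.

## Synthetic cohort generator

Intensities are log-normal: measurement = 2^(µ + ε) with ε ~ N(0, σ),
σ = `noise_sigma` (default 0.25 on the log2 scale, i.e. ~19% CV —
a mid-range figure for serum LC-MS after alignment; the study does not
publish its variance components, so this is a stand-in, not an
estimate). Per-feature baselines are uniform on log2 [14, 20].

Planted effects (fold changes on the raw scale):

| category | PRE vs CTRL | POST vs PRE | default share |
|---|---|---|---|
| I | × `effect_fc_up` (8) | ÷ `clearance_fc` (4) | 8.3% |
| II | × 8 | × 1 | 5.6% |
| III | ÷ 8 | × 1 | 2.2% |
| unchanged | × 1 | × 1 | remainder |

The default shares put category I/II/III at the proportions the study
reports among its detected features (697/470/186 of 8,410), so a default
run reproduces the published 51.5/34.7/13.7 split up to rounding of the
planted counts. Category III is planted as depleted in both patient
arms; the study does not subdivide it by dialysis response.

PRE/POST columns of a patient share a subject baseline offset
(`subject_sigma`, log2 SD), which makes paired POST/PRE testing
meaningful. The default is 0 so that noiseless runs (`noise_sigma=0`)
are fully deterministic and planted labels are recovered with zero
errors — the strictest recovery invariant. QC columns resample the
pooled arithmetic mean of all biological columns with one fifth of the
sample noise; blanks sit at 1/50 of the mean biological intensity
(ratio 50, comfortably above the removal threshold of 5) so compliant
features survive the blank filter by construction. Feature metadata is
drawn compliant (S/N ≥ 5, width ≥ 6 scans); QC-violating features for
filter tests are constructed explicitly in fixtures.

Identified features adopt a reference standard's theoretical adduct m/z,
RT and polarity. Standard MS2 spectra are synthetic (12 fragments,
positions/intensities from an RNG keyed by a CRC32 of the compound name,
so they are stable without a global seed). Real fragmentation chemistry
is not modeled; the spectra exercise the matching arithmetic, not
spectral realism. Everything the generators emit is deterministic given
the seed.

### What passing tests do and do not show

Recovery tests demonstrate that the statistical machinery is correct and
calibrated under the generator's assumptions: independent log-normal
noise, exactly planted effects, no RT drift, no missing values, no
batch structure, no correlated features. Real serum data violate all of
these to some degree, so passing tests validate the implementation, not
the biological conclusions reachable from any particular cohort.

## Statistical choices

* **Tests.** Welch's t-test on log2 intensities for unpaired contrasts;
  paired t-test for POST vs PRE (the matched design); the study names no
  test. Features with fewer than `min_n` = 3 values per group are
  flagged untestable and excluded from FDR.
* **FDR.** Benjamini–Hochberg step-up (the field default where a
  procedure is unnamed), via statsmodels; verified against the
  definitional tail-minimum oracle on all small instances.
* **Zeros.** Replaced by half the smallest positive intensity in the
  matrix before log2 — a simple documented pseudo-count.
* **Fold changes** are geometric (2^Δmean-log2), so reported ratios are
  ratios of group geometric means.
* **Degenerate features.** Zero variance in both groups resolves exactly:
  p = 1 for equal means, p = 0 otherwise (scipy returns NaN there).
* **Normalization.** Median scaling: each column is multiplied by
  target/median(its nonzero values), the target being the median of the
  *biological* columns' medians; QC/blank columns are rescaled but never
  influence the target. Blank ratios are computed before normalization.
* **Joint p-and-FDR gating.** Both p < α and q < α are enforced by
  default (both appear in the study's thresholds) and can be relaxed
  independently.
* **Classification.** "Cleared" requires both significance and a ≥
  `clear_fc` POST/PRE drop; `cleared_requires_fc=False` switches to the
  looser "any significant decrease" reading. Features decreased post
  dialysis without a PRE/CTRL flag are "none" — no such class is
  defined.

## Identification

Accurate mass compares the observed feature m/z against the
*theoretical* adduct m/z computed from the standard's formula
(monoisotopic masses via pyteomics; proton mass 1.007276 Da). Printed
library m/z values are treated as observations — several deviate from
theory by more than the stated tolerance, so they cannot serve as mass
ground truth. MS2 similarity is a square-root-intensity cosine over
greedy nearest-peak pairs within 0.05 Da (ties to the lower-m/z pair);
it is symmetric, scale-invariant, 1 for self-matches and 0 for disjoint
spectra, and cross-checked against matchms' greedy cosine. The composite
scoring of the original vendor software is unpublished; the 0.7 cutoff
is kept.

## Proteomics

Quantile normalization acts jointly on all 15 log2 channels (the study
states a single normalization): each value is replaced by the
across-channel mean of the order statistics at its rank, ties receiving
their rank-block mean; afterwards all channels share one sorted vector
exactly. A known consequence: when a sizable fraction of the proteome
shifts in one direction (83/600 ≈ 14% planted up, mirroring the study
scale), QN compresses the planted log2 fold change (≈ 0.82 observed for
a planted 1.0), because its equal-distribution assumption is violated.
Differential calls absorb this at FC > 1.5; recovery tests use the mean
recall over a fixed block of seeds.

## Enrichment and network

Over-representation is the one-sided upper-tail hypergeometric test
(ORA convention), verified against combinatorial enumeration for all
universes up to N = 12. The default universe is the identified,
QC-surviving feature set (the study never states its background set;
this is configurable). The network treats STITCH-style associations as
undirected, deduplicates pairs keeping the maximum score, defaults to
the medium-confidence cutoff 0.4 (no cutoff is stated), and includes
exactly one-hop neighbors of seeds; isolated seeds are retained and
flagged. Metabolite-to-vocabulary mapping is exact-identifier via an
optional synonym map — no fuzzy name matching, which can silently
mismatch.

## Dose–response

The 4PL is fitted by trust-region least squares on log-dose with
multi-start over hill slopes {±0.5, ±1, ±2} and IC50 initialized at the
geometric mean of the doses. Parameters are bounded — top/bottom within
the observed response range plus 50% headroom and never below 0 (a
viability fraction), |hill| ≤ 10, log-IC50 within two decades of the
dose window — because with a five-point dilution series an unbounded
bottom asymptote can drift negative and drag the IC50 outside the assay
window entirely. IC50s outside the tested dose range are therefore
reported at the window edge rather than extrapolated. Noiseless curves
are recovered to optimizer precision (~1e-9) for either hill sign; the
fit is dose-unit equivariant (IC50 scales linearly, hill unchanged).
Monte-Carlo recovery tests plant IC50 = 10 µM — a tested dose near the
centre of the serial-dilution window — since a value near the window
edge is weakly identifiable at realistic noise. The study's printed
IC50s cannot be recomputed here: the raw absorbances are unpublished,
and the curve family it used is unstated (4PL is this package's
assumption).

## Problem sizes

Default and test problem sizes (2,000-feature cohorts, 600-protein
proteomes, 21 standards, ≤ 3 Monte-Carlo seeds per property) were chosen
so the full suite and the end-to-end run each complete in seconds while
keeping planted-set sizes at the study's own scale where it matters
(83 differential proteins, 21 standards, category proportions).

## Known limitations

* No retention-time drift, isotope patterns, adducts beyond ±H, missing
  values or batch effects in the generator.
* Peptide→protein rollup, PSM-level FDR and spectral search are out of
  scope; protein-level reporter matrices are assumed.
* No moderated (limma-style) variance shrinkage; plain t-tests at n = 10
  (metabolites) and n = 5 (TMT channels).
* Pathway topology/impact scoring is not implemented; ORA only.
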