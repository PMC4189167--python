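# Methods

## The inference problem

A TRFLP fingerprint reduces a bacterial community to the set of
fluorescently labelled terminal restriction fragment sizes observed on
a capillary sequencer, two channels per amplicon (6FAM on the forward
799f primer, Max550 on the reverse 1492rh primer). The package infers,
for every fragment-size category present in a soil-grown plant, whether
it is better explained by inheritance through the seed or by uptake
from soil, using only co-occurrence with reference profiles measured in
the same experiment: the parental seeds, sibling plants grown on
sterilized sand (which can only have inherited their bacteria), sibling
plants grown on a geographically distant soil, and the two bulk soils.

This is deliberately *not* a model of biological origin: a peak shared
with seed may still have entered from soil, and one peak size can hide
several taxa. The classifier is a bookkeeping device over presence
sets, and all conclusions inherit the resolution limits of TRFLP.

## Preprocessing conventions

* **Height cutoff 35 fluorescence units, inclusive** (`height >= 35`
  retained). The cutoff is read literally; the boundary behaviour is
  pinned by tests (34 removed, 35 retained).
* **Primer-dimer window 1–26 bp, inclusive**: categories binned to
  ≤ 26 bp are removed; 27 bp survives.
* **Integer binning, round half up.** Sizing is fractional; category
  identity is the (dye, nearest-integer bp) pair. Round-half-up keeps
  the x.5 boundary deterministic instead of numpy's banker's rounding.
* **Water-control subtraction** is applied per PCR trial to summed
  per-category intensities, floored at zero (intensities are physical).
  A water trial with no surviving peaks is a valid zero control; only
  a manifest without any water sample triggers the uncorrected-intensity
  warning. Detection — and therefore presence — is decided by surviving
  peaks, not by the adjusted intensity, so subtraction affects displayed
  pseudo-profiles and nothing downstream of presence/absence.
* **Presence rule**: a category is present when detected in ≥ 2 of the
  sample's PCR trials, whatever that sample's trial count is (6 for
  plant tissues, 4 for the short replicate cell, 3 for seed pools).
  This single rule across designs is a choice; the alternative
  (proportional thresholds) would change seed profiles only.
* Organellar signals (chloroplast 16S, mitochondrial 18S) are removed
  as per-dye integer size windows, which can be generated directly from
  digest predictions of reference sequences.

The order height-filter → dimer-removal is immaterial (the filters
commute; tested), and filtering is idempotent.

## Provenance classification

Strict precedence: Seed → Plant-on-Sand → Soil-or-Plant-on-Soil →
Same-Soil-Match-Only → No-Match. Two genuinely open design points:

* **Rule 3 OR vs AND.** Whether promiscuous uptake requires
  co-occurrence in the opposite-soil *plant* or the opposite *soil*
  (OR), or in both (AND). The OR reading matches the idea that either
  observation demonstrates the taxon exists outside the same-soil
  context; it is the default, with `rule3="and"` available.
* **Profile granularity.** Classification defaults to whole-plant
  unions over tissues and both dye channels; per-tissue breakdowns are
  available by passing tissue-level presence sets directly.

Display percentages round half up to integer percent; full precision
is kept internally. Counts always partition the plant's present-peak
total, and enlarging an earlier-precedence reference set can only grow
that category and shrink later ones (property-tested).

## Sharing significance

The closed-form screening statistic P(b,c) = (1/N)^c [b!/(b−c)!] a is
implemented exactly as written, N = 314 categories by default. It is
kept verbatim because its value is what the accompanying workflow
reports; its quirks are surfaced rather than patched:

* at c = 0 it degenerates to `a` and generally exceeds 1 — a warning is
  emitted whenever the value passes 1;
* it is a true upper bound of the exact tail only for small first
  samples. Against the hypergeometric tail the leading-order ratio at
  c = 2 is ≈ 2/(a−1): an upper bound for a ≤ 3, an underestimate for
  larger a. The comparison is logged by a test, not asserted, and both
  calibrated oracles are always reported next to the formula.

The exact null is Hypergeometric(N, a, b) with the upper tail
P(X ≥ c); "at least c" tail semantics are the default, with the
exact-c point mass also reported since either reading is defensible.
The Monte-Carlo oracle draws uniform b-subsets via partial argsort of
uniform variates, chunked to bound memory, and is reproducible by seed.
The assumed number of strains hiding behind one peak size (10) is
carried as documentation only: it scales the effective pool and the
sharing opportunities identically and cancels.

## Diversity

Sørensen's QS = 2c/(S1+S2) over presence sets; "species" means a
(dye, integer size) category, with dyes pooled when whole-profile
comparisons are made. Two empty communities raise rather than return
0 — the quantity is undefined, and silent zeros would poison group
averages. The rank-sum test enumerates all C(n, n1) rank assignments
(midranks, so ties are handled as a permutation test on U) for combined
n ≤ 20, where exactness is cheap and the group sizes of tissue/genotype
contrasts live; above that it defers to the tie-corrected normal
approximation.

## Ordination

Covariance PCA with *samples as variables*: the input matrix has one
row per category (observation) and one column per sample, entries the
0..n trial counts. Columns are mean-centered, not scaled; the
covariance matrix is eigendecomposed (`numpy.linalg.eigh`, exact for
symmetric matrices); eigenvalues below 1e-12 of the spectrum are
clamped to zero. Sample biplot coordinates are loadings
(eigenvector × √eigenvalue), so vector length reflects a sample's
variance and angles between vectors its covariances. Signs are fixed by
making each component's largest-magnitude loading positive, giving
byte-stable outputs. A transposed mode is just `pca_covariance(m.T)`.

## The synthetic-data generator

The generator emulates the targeted experimental design: three
genotypes × three substrates (sterile sand plus two soils) × two
tissues, 3 biological × 2 technical PCR trials per tissue (6
replicates; one configurable short cell with 2 pools → 4), 3 trials per
seed pool, two dye channels, and a global pool of 314 possible integer
size categories per channel (default range 27–340 bp).

Community structure: per-genotype seed-inherited taxa (appearing in
seed, sand-grown and all soil-grown plants), promiscuous soil taxa
(both soils and plants on either soil, never seed/sand), and
soil-specific taxa (one soil and its plants). Observation noise is a
flat per-trial detection probability and Poisson-rate spurious peaks
per trial; water controls carry only spurious peaks. Ground truth maps
every generated non-noise (group, dye, size) peak to its origin.

Default parameters, chosen once as realistic for this kind of
fingerprint and then left alone:

| parameter | default | rationale |
|---|---|---|
| seed / promiscuous / specific taxa | 24 / 10 / 6+6 | ≈ 40 peaks per plant profile (profiles of this type typically show 35–50), giving a 60/25/15 plant-peak split |
| detection probability per trial | 0.9 | high but imperfect PCR detection; the ≥2-of-6 rule then retains true peaks with probability ≈ 0.9999 |
| false peaks per trial | 0.5 | rare spurious calls; almost never repeat in ≥ 2 trials at a 314-category pool, which is exactly why the replicate rule suppresses them |
| true peak height | log-normal, median 200 FU, σ = 0.5, clipped at 36 | well above the cutoff so true peaks survive filtering by construction |
| false-peak height | uniform 35–80 FU | dim, cutoff-adjacent junk |
| sizing jitter | ±0.4 bp uniform | exercises integer binning without crossing bins |

What the generator does **not** emulate: sequence evolution, chimeras,
primer bias beyond the flat detection probability, abundance structure
(heights are cosmetic above the cutoff), tissue-specific detection
differences, or correlated trial failures. Passing recovery tests
therefore show that the *bookkeeping* — filtering, replicate logic,
classification — is correct under the stated observation model, not
that real communities satisfy that model.

Seed-inherited taxa colonize soil-grown plants with the same detection
probability as everything else (no niche advantage) — the simplest
null, configurable by editing community membership. Each taxon gets a
fixed tissue affinity (root / shoot / both at 0.35/0.35/0.30) so
whole-plant unions and tissue contrasts are both meaningful.

## Problem sizes used by tests and the acceptance script

Simulation-based checks use the full 314-taxon pool with the default
community sizes; noisy-recovery statements average 20 seeded
replicates of the single-genotype design; Monte-Carlo/hypergeometric
agreement uses 10⁵ reps per grid point; digestion properties use 100
random sequences per assertion. The whole suite runs in well under a
minute on one core, and `scripts/acceptance.py` in ~10 s.

## Known limitations

* The classifier cannot distinguish a seed-inherited taxon that is
  also present in soil from pure inheritance; precedence resolves the
  ambiguity by fiat (inheritance first), matching the vertical-
  transmission framing.
* One fragment size can represent many taxa; all shared-peak
  statements are upper bounds on taxon sharing.
* The exact rank-sum enumeration cost grows as C(n, n1); the n ≤ 20
  boundary keeps it instant while covering the intended group sizes.
* Digest predictions carry ±1 bp convention differences against other
  in-silico digestion tools (whether the cut base and primer ends are
  counted); the matching tolerance default of 1 bp absorbs this.
* The water-control pairing assumes control trials share (bio, tech)
  indices with sample trials; unmatched trials fall back to a zero
  control when a water sample exists.
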