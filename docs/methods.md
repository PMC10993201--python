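# Methods

## Signal model

A peptide monomer with elemental composition derived from its residue
formulas (+H₂O, acetyl cap +C₂H₂O, amide cap −OH+NH₂) assembles into
noncovalent n-mers of mass exactly n·M — no condensation water loss.
Protonated oligomers n^z+ appear at m/z = (nM + z·1.007276)/z. Species
with equal n:z ratio form an isobaric family sharing one m/z channel;
within a channel, the isotopologue spacing ≈ 1.00336/z Th identifies the
charge and hence the member.

### Isotope envelopes

Envelope abundances are exact: per-element isotope distributions (NIST
table shipped with pyteomics) are convolved by binary exponentiation,
aggregated by total neutron count, truncated at `min_abundance` (default
1e-4) and renormalised; pruning at 1e-10 of the running maximum bounds
the cost for 25-mers. Peak *positions* are placed on a ¹³C comb,
(mono + k·1.0033548 + z·mH)/z, rather than at exact per-isotopologue
centroids: for peptide compositions the centroid drifts by ~3×10⁻⁴ Th
per neutron (¹⁵N/²H/¹⁸O substitutions), far below the ±0.05 Th matching
tolerance used anywhere downstream, and the comb keeps the spacing
identity exact. An envelope-equivalence oracle (brute-force isotopologue
enumeration for ≤ 8-atom compositions) pins the abundances in the tests.

### (n, z) inference

z = round(1.00336/spacing); n = round(z(m/z_obs − mH)/M); the candidate
is accepted only if its theoretical m/z back-computes within `tol_ppm`
(default 50 ppm — the worked examples use nominal channel values like
1580.0, which sit ~27 ppm from the exact species m/z). Rejections return
the best candidate and its error instead of nothing.

## Instrument model (synthetic data)

The generator emulates a mobility-cell → quadrupole → collision-cell
instrument. Each planted species contributes envelope × Gaussian
mobility-profile intensity on a regular grid (TIMS default: 0.001
V·s/cm² bins, σ = 0.008; TWIMS: 0.05 ms bins, σ = 0.08). Two
fragmentation loci:

* **interface** (before the quadrupole): neutral monomer loss only;
  the product keeps the precursor's mobility and changes m/z *before*
  mass selection;
* **collision cell** (after the quadrupole): binary splits of the
  selected ion; intensity is divided among charged products in
  proportion to their charge (yields are not modelled; the proportional
  split is a documented, configurable convention), again keeping the
  precursor's mobility.

Intensity is redistributed, never created: before noise, the feature
total equals the planted abundance that survives the quadrupole (applied
per species m/z, a valid approximation since the ±5 Th window is much
wider than an envelope). Noise is an additive uniform baseline of
scattered features plus multiplicative Gaussian jitter on peak samples;
all randomness flows from one integer seed, and identical configs give
byte-identical fixture files.

The canonical `quad_mz1580` fixture plants the m/z 1580 family at the
published TIMS apexes (1.959, 1.606, 1.416, 1.299, and the
fragment-assigned 1.203 and 1.126 V·s/cm²) with monomer-loss collision
pathways per member, 10⁵⁺ additionally splitting to 2²⁺+8³⁺, and an
intact 13⁵⁺ that loses three monomers at the interface. The intact
monomer (2.200), 13⁵⁺ (1.320), the TWIMS drift times of the m/z 2369
family, the abundances and the fragmentation fractions are **synthetic
choices** — plausible values selected once for test robustness; nothing
downstream is tuned to them. What passing tests show is therefore that
the algorithms recover planted truth under this idealised signal model;
they do not certify behaviour on profile ToF peak shapes, detector
saturation, charge stripping, or real yield curves, none of which are
modelled.

## Coincidence assignment

Given a quadrupole-selected dataset and the family inside the window:

1. enumerate each member's charged fragment channels; channels whose m/z
   falls back inside the selection window are excluded (indistinguishable
   from the family itself); channels are grouped by m/z, so isobaric
   fragments such as 1¹⁺/2²⁺ form one channel with several
   interpretations;
2. extract each channel's EIM (union isotope-envelope selection, ±0.05
   Th per isotopologue) and pick apexes with 3-point parabolic
   refinement. A peak must exceed 1% of the channel base peak **and**
   5× the channel noise floor (25th percentile of positive bins): the
   floor sits at baseline level for noise-only channels, killing stray
   spikes, but on the far Gaussian flanks for real channels, keeping the
   weak shoulders on which one published-style assignment rests;
3. single-linkage cluster apexes across channels with link threshold
   `tol_mobility` (defaults 0.01 V·s/cm² TIMS / 0.2 ms TWIMS — half the
   smallest separation that must be resolved);
4. a cluster assigns member P when all its channels are predicted
   fragments of P and it spans ≥ `min_channels` (default 2, because a
   valid published-style assignment rests on exactly two channels)
   distinct channels;
5. contested clusters are resolved by iterative sole-contender
   elimination (a channel like 11⁵⁺ uniquely pins 12⁶⁺, and each
   assignment cascades), then minimum-total-monomer-loss parsimony
   (dissociation is dominated by small losses, so the precursor
   explaining the cluster with the fewest lost monomers wins), then the
   raw support count; residual ties are reported on all contenders with
   an ambiguity flag rather than silently broken;
6. leftover apexes are classified, in order: **intact** (coinciding with
   the same channel's apex in a reference run without selection),
   **collision-cell fragment** of a family member whose mobility is
   known (assigned, or estimated from the reference run via its
   charge-specific envelope comb), **interface fragment** when the apex
   lies above the assigned mobility of a member predicting that channel
   and matches the reference mobility of a same-charge precursor within
   `max_monomer_loss` = 3 monomers, else **unexplained**. Without a
   reference run the interface label lists candidate sources instead of
   naming one.

Assigned mobilities must decrease strictly with n inside a family
(larger n at fixed m/z means higher charge, smaller 1/K₀); violations
raise `FamilyMonotonicityWarning` rather than silently reordering.

## Calibration

* **TIMS**: monotone piecewise-linear map anchored at calibrant ions
  matched on m/z (±0.5 Th); anchors reproduce their reference 1/K₀
  exactly; edges extrapolate linearly. Mason–Schamp conversion uses
  T = 273.15 K, the standard gas number density and N₂ mass 28.00615 Da
  (the reduced-mobility convention); all constants are arguments, and
  relative cross-platform comparisons are insensitive to the bundle.
* **TWIMS**: dt′ = dt − EDC·√(m/z)/1000 (the Synapt transit-time
  convention), Ω′ = Ω√μ/z, least-squares fit of ln Ω′ on ln dt′ over ≥ 3
  calibrants; the reported R² is 1 − SS_res/SS_tot of that log-log fit,
  and a non-positive corrected drift time names the offending calibrant.
  Calibrant reference CCS values are user-supplied (the shipped table is
  synthetic, generated from a known power law and labelled as such).
* **Comparison**: species matched on exact (n, z); symmetric relative
  differences 100|a−b|/mean(a,b), their mean and max, a linear fit with
  R², and a which-platform-reads-larger tally.

## Screening

The dataset is collapsed over mobility onto a 0.02 Th mass-spectral
grid. Signal per candidate (n, z) is the highest bin within ±0.05 Th of
an expected isotopologue position; noise is median + 1.4826·MAD of the
positive background in bins away from every candidate envelope (a
robust, deterministic estimator — vendor S/N definitions differ, so
absolute detection counts are estimator-dependent). Detection uses the
strict inequality S/N > threshold (default 3), making the grid monotone
in the threshold by construction.

## Numerical and interface choices

* Monoisotopic masses throughout; average-mass mode available.
* m/z display labels: nearest integer above 1000, one decimal below
  (1580 vs 790.5).
* Feature tables are flat TSV with `#key=value` preamble and
  repr-formatted floats (bit-exact round trip); vendor raw formats are
  upstream of this tool, mzML import being an extension point only.
* Defaults n_max = 25, z_max = 8 cover the observed oligomer range with
  margin.
* Degenerate inputs: empty m/z selections return zero spectra with a
  flag and a warning; all-zero spectra yield no peaks; empty family or
  missing quadrupole metadata are rejected with actionable messages.

## Problem sizes

Fixture simulations use 6–8 species on a 1300-bin mobility grid
(~5 000–15 000 features); recovery statistics run 20 seeded replicates;
exhaustive invariants cover all (n ≤ 25, z ≤ 8) precursors and their
binary splits. These sizes were chosen so the full suite runs in
seconds while every combinatorial claim is checked exhaustively rather
than sampled.

## Known limitations

* Covalent backbone fragments (b/y ions), proton-transfer charge
  reduction, Na⁺/K⁺ adducts and PTMs beyond terminal caps are out of
  scope.
* Overlapping-envelope least-squares deconvolution is not implemented;
  identification relies on apex/spacing logic, matching the intended
  workflow.
* The Mason–Schamp constant bundle is a convention; absolute CCS values
  shift if a vendor uses a different one, relative comparisons do not.
* Fig-6-style absolute detection counts depend on the (undocumented)
  vendor S/N estimator and are not bit-reproducible; the screening
  contract is the threshold monotonicity and planted-species recovery.
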