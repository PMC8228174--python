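# Methods

## Pattern grammar and matching

Patterns are sequences of tokens in a PROSITE-flavoured dialect: `[XYZ]`
residue classes, single residue letters (singleton classes), `x` wildcards,
and an optional repeat suffix `(n)` or `(n,m)` on any token. Compilation
expands tokens left-to-right into per-position constraints; a pattern's
length range is the sum of the token repeat ranges. The built-in catalog
holds the 14-position GC catalytic-center motif
`[RKS][YFW][GCTH][VIL][FV]x(3)[VIL]x(4)[KR]` (`GC_CORE_STRICT`), the
monocot expansion with `[KRM]` at position 14 (`GC_CORE_MONOCOT`), and both
with the downstream metal rule appended as `x(1,2)[DE]` (`GC_FULL_*`,
length 16–17). Functional roles are annotated at expanded positions 1
(purine hydrogen bond), 3 (substrate specificity) and 14 (transition-state
stabilization). No AC pattern ships: AC centers are thought to differ from
GC centers only at position 3, but the residue classes there are not
established, so users supply their own pattern if needed.

Matching slides every fixed-length expansion of a pattern along the
sequence and counts **mismatches only at constrained positions**; wildcards
accept any alphabetic character and can never mismatch. Non-canonical codes
(X, B, Z, J, U, O) never satisfy a class — conservative candidate calling
on real proteomes, where ambiguity codes should not create hits. Sequences
and patterns are uppercased on ingestion. A window is reported when its
mismatch count is ≤ `max_mismatch` (default 0; near-miss diagnostics are
typically run at 1–2). For variable-length patterns the default reports the
shortest satisfying expansion per start (avoiding near-duplicate rows);
`all_expansions` reports every satisfying length. Two expansions with equal
start and length collapse to the one with fewer mismatches. The inner loop
is vectorized with per-position 256-entry lookup tables over the byte-coded
sequence, which scans ~10⁷ windows per second; an independent, recursive
brute-force scanner (`bench.brute_force_scan`, no shared code) serves as
the oracle in tests.

All reported coordinates are 1-based inclusive protein-residue coordinates
(the convention behind residue citations like S1053/M1066); internal 0-based
indices are converted at the boundary.

### Metal-binding rule and scoring

`check_metal_binding` looks for D or E at offsets +2 then +3 after expanded
position 14; +2 wins when both qualify (the "two residues behind the motif"
phrasing singles it out). In full proteome scans the check is anchored at
expanded position 14 of the match when the match spans ≥ 14 residues,
else at the match end (user patterns may be shorter than the GC core).

The candidate score is `0.9 · f + 0.1 · m` with `f` the fraction of
satisfied constrained positions and `m` the metal indicator. The weights
are fixed tool constants chosen so that a complete core match without metal
support (0.9) still outranks any single-mismatch near-miss with metal
support (≤ 0.9·6/7 + 0.1 ≈ 0.871).

### The worked near-miss

The published BdPepR2 catalytic-center string `SYGVVELLCRKMPVD` is treated
literally: its first 14 letters violate the strict motif exactly at
positions 9 (C ∉ [VIL]) and 14 (V ∉ [KR]), and D follows the stated
position-14 methionine at offset +3. The string's own numbering is
internally inconsistent (the bracketed residue range spans more positions
than the string has letters, and the stated position-14 methionine is the
string's 12th letter); the package does not attempt to reconcile that
numbering and simply exposes the diagnostics for the literal string. This
is also why, in the README's scan example, the metal column is empty: the
scanner anchors the metal check at the literal 14th window position, where
the D sits at offset +1.

## Protein statistics

Fragment length is `end − start + 1` on 1-based inclusive ranges. Average
molecular mass is the sum of the standard average residue masses (table in
`scan.AVERAGE_RESIDUE_MASS`, 4 decimals, e.g. G = 57.0519 Da) plus one
water (18.0153 Da); tests cross-check it against
`Bio.SeqUtils.molecular_weight`. Mass is undefined over non-canonical
residues and raises, naming the residue and position. Isoelectric point is
deliberately not computed: pI depends on the chosen pKa scale, and no
single scale is canonical.

## Kinetics

Rates follow the Michaelis–Menten law v = Vmax·S/(Km+S) with S in mM and
rates in pmol mg⁻¹ min⁻¹ (numerically identical to fmol µg⁻¹ min⁻¹ — the
10³ factors cancel, and `convert_activity_units` makes that algebra
explicit while validating unit strings). Fitting is unweighted nonlinear
least squares (no weighting scheme is standard for these assays) via
`scipy.optimize.least_squares`, initialized at Vmax₀ = 1.2 × max observed
rate and Km₀ = the concentration at half-maximal rate obtained by linear
interpolation along the concentration-sorted curve (nearest observation as
fallback); convergence is a relative parameter change below 1e-8, capped at
500 function evaluations. Designs with < 3 observations, < 2 distinct
nonzero concentrations, or all-zero rates raise a non-identifiability error
rather than fitting silently.

The saturation simulator adds independent Gaussian noise truncated at zero
— the simplest model consistent with symmetric error bars on rate means —
and is fully determined by its seed. Replicate-level wet-lab rates are not
published for these assays, so the statistical surface of the module comes
from simulation, not from reproducing any published ANOVA; published bar
means enter only as scalar inputs (e.g. the 72.1 / 16.26 GTP/ATP pair).

Substrate preference is labelled from the GTP/ATP fold change with a fixed
2-fold threshold (documented constant; the motivating case sits at ≈ 4.4).
Cofactor preference orders cofactors by mean rate at concentrations shared
by every series; exact ties are reported as tie groups, never broken
arbitrarily. Note the measured rate at 1.5 mM GTP (72.1) exceeds the
fitted-curve prediction from the published (Vmax, Km) (≈ 62.5); the package
reports both and asserts nothing about their agreement.

## Synthetic benchmark

`generate_proteome` draws background residues i.i.d. from the configured
frequencies (uniform 1/20 by default), with sequence lengths normal
(mean, sd), rounded, and clamped below at the largest planted-pattern
length. Planted realizations are drawn by `sample_realization` (uniform
over repeat counts, allowed sets, and the 20 canonical residues for
wildcards) and placed at uniform positions in uniformly chosen sequences;
plants never overlap one another (rejection sampling, with a packing error
when placement fails). One integer seed drives a single
`numpy.random.default_rng` generator, so the contract is "same seed, same
bytes". The generator emulates only the i.i.d. null plus exact planted
instances — no domain architecture, homology structure, or compositional
bias — so passing benchmarks demonstrate scanner correctness and calibrated
false-positive behaviour under the null, not performance on real proteomes,
where true centers may be near-misses and backgrounds are not i.i.d.

Evaluation counts a truth entry as recovered only on an exact
(seq_id, start, end) hit; because the i.i.d. background can contain chance
true matches, sensitivity/precision runs screen unmatched predictions with
the brute-force oracle first. The analytic null is
P(match per window) = Π over constrained positions of the summed background
frequency of allowed residues (1296/20⁷ ≈ 1.0125 × 10⁻⁶ for the strict
core under a uniform background; exactly 3/2 of that for the monocot
variant). Exact frequencies (`fractions.Fraction`) propagate exactly.
Empirical calibration checks the observed match count on plant-free
windows against the central 95% Poisson interval of the analytic
expectation; the default problem size is 2 × 10⁷ background residues
(10⁷ windows, expectation ≈ 10 matches), which the vectorized scanner
covers in about a second.

## Problem sizes used by the test suite and acceptance script

Noisy-recovery simulations use 100 replicates of n = 50 observations on
S ∈ [0.2, 4] mM with noise sd = 5% of Vmax; oracle equivalence uses 200
random (pattern, sequence ≤ 300) instances at mismatch tolerances {0, 1};
planted recovery uses 100 strict-core instances across 500 sequences of
length 500 ± 50; the null calibration uses 10⁷ windows. These sizes give
stable statistics (the Poisson check has ≈ 10 expected events; the median
Km error estimate has ~100 effective samples) at a few seconds of runtime.

## Known limitations

- Set-membership degenerate patterns only: no PSSM/profile or HMM scoring,
  and no structural modelling or docking.
- The scanner does not predict domain context (no LRR/transmembrane/signal
  peptide annotation); it flags catalytic-center candidates only.
- The 2-fold specificity threshold and the 0.9/0.1 score weights are
  conventions, not estimates; both are fixed and documented.
- Whether published ± values on rates are SD or SEM is unspecified
  upstream; the simulator's noise level is therefore a parameter, not a
  calibrated quantity.
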