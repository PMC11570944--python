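# Methods

## Scope and model

`hdxsim` simulates bottom-up hydrogen/deuterium-exchange mass spectrometry
(HDX-MS) at the level of ensemble-average deuterium occupancies, and uses
those simulations to audit the standard back-exchange correction. The
kinetic core is the Linderstrøm-Lang picture in its EX2 limit: each backbone
amide *j* spends most of its time in a closed, H-bonded state and exchanges
only during rare openings, so its observed rate is

    k_HDX_j = K_op_j × k_ch_j = k_ch_j / P_j ,

where `k_ch_j` is the intrinsic (fully open) chemical exchange rate and
`P_j ≥ 1` the protection factor. During any interval with constant
conditions the occupancy relaxes in closed form,

    D_j(t) = target + (D_j(0) − target) · exp(−k t) ,

with `target = 1` for labeling in D2O and `target = 0` for processing in
H2O. A workflow is an ordered list of such stages (labeling, quench
digestion, LC, …) chained exactly, plus one terminal electrospray retention
factor (default 0.95) that multiplies all occupancies. Individual opening
and closing rates are deliberately not represented: under EX2 only their
ratio is identifiable, so EX1/opening-limited kinetics are out of scope and
protection enters solely as rate division.

Peptide-level readout follows the bottom-up conventions: digestion turns the
first residue's amide into an amine and residue 2 back-exchanges essentially
completely, so a peptide of N residues reports the sum of occupancies over
positions 3..N excluding Pro, with maximum ideal deuteration N − 2 for
Pro-free peptides. Peptides whose first two residues are W/L/V/I can in rare
cases retain some residue-2 deuterium; the package warns when such peptides
are constructed but does not model the retention. Nominal mass shifts are
identified with deuteron counts directly; isotope envelopes, gas-phase
scrambling, and fragmentation are not simulated.

## Intrinsic rates

`k_ch_j` is the sum of acid-, base-, and water-catalyzed pathways:

    k_ch_j = kA·FA_j·[cat+] + kB·FB_j·[cat−] + kW·FB_j ,

with catalyst concentrations from the acidity and the solvent ionization
constant, and per-pathway Arrhenius scaling from the reference temperature
(293 K). The perturbation factors `FA_j`, `FB_j` multiply the side-chain
contributions of residue *j* ("own") and residue *j−1* ("next"), taken from
the NMR dipeptide calibration of Bai et al. (1993) with ionizable-residue
variants after Connelly et al. (1993), as distributed in the
Englander-laboratory exchange-rate spreadsheets. The water pathway reuses
the base factors, matching that calibration. The packaged table
(`hdxsim/data/rate_params.tsv`) is checksummed and loads bit-identically;
its transcription is gated by five literature anchor values exercised in the
test suite: poly-Ala 6.9 s⁻¹ at pD 7.4 / 295 K, His-flanked contexts above
40 s⁻¹, Ile/Leu contexts near 1 s⁻¹, a rate minimum near pH 2.5, and a
>10-fold spread across the 400 interior dipeptide contexts.

Specific numerical conventions:

- **Acidity scales.** Input may be a pH measured in H2O, a pD, or a D2O
  electrode reading; the conventional `pD = reading + 0.4` correction is
  applied exactly once, at construction. Labeling (H→D) must be specified in
  D2O units, back exchange (D→H) as pH in H2O; each direction has its own
  reference rates and solvent pK (D2O: log kA/kB/kW = 1.62/10.18/−1.50,
  pK 15.05; H2O: 1.40/10.00/−1.79, pK 14.17, all at 293 K in min⁻¹ and
  M⁻¹min⁻¹). Published compilations differ in the water-pathway constant for
  the D→H direction; the packaged value is the one that reproduces the
  printed worked-example back-exchange levels used as anchors (see the
  acceptance tests), alongside the unambiguous D2O set fixed by the
  6.9 s⁻¹ anchor.
- **Temperature.** Arrhenius activation energies of 14/17/19 kcal mol⁻¹
  (acid/base/water) are constant-acidity effective barriers: the
  base-pathway value folds in the solvent ionization enthalpy, so catalyst
  concentrations are always computed with the reference-temperature pK.
  Stage temperatures quoted in °C are used as exact kelvin values
  (22 °C → 295.15 K, 15 °C → 288.15 K, 0 °C → 273.15 K).
- **Ionizable side chains.** Asp, Glu, and His carry protonated and
  deprotonated factor sets, population-averaged on the linear scale with
  model-compound pK values per solvent (packaged in the table); there is no
  user override. At quench pH 2.5 the carboxyls are ~96% protonated; at
  pD 7.4 His sits near its pK and the averaged factors make His-flanked
  amides the fastest standard contexts (~10² s⁻¹).
- **Termini.** The free α-ammonium factor is always applied to the amide of
  residue 2 — a position that is never observable at the peptide level. The
  α-carboxyl factor ships in the table but is applied only on request
  (`include_cterm_factor=True`): applying it by default would give the last
  observable site of a homopolymer its own back-exchange rate, breaking the
  uniform-rate exactness of the classic correction for poly-X peptides,
  which this package treats as a structural property of the model. Its
  effect on the shipped worked examples is below 0.01 %BX points.
- **Non-exchanging positions.** Residue 1 and Pro carry NaN markers that
  propagate through every computation; they are excluded from all sums.

## Workflow simplifications

The quench pipeline copies the usual idealizations: no exchange between
quench and digestion onset; digestion treated as taking place entirely in
H2O; quenched peptides fully unprotected (k_BX = k_ch); electrospray losses
collapsed into a single scalar retention factor applied once after the last
stage. These are stated assumptions of the model, not configuration knobs.
Trajectories are sampled on a geometric grid of 50 points per stage plus
every stage boundary, so the peak raw deuteration needed for %BX always
falls on a grid point; the retention factor appears as a duplicated final
time point labeled `esi`, the only discontinuity in a trajectory.

The back-exchange level of a workflow is measured exactly as in practice:
a fully deuterated control (occupancy 1.0 at every exchanging site) enters
the pipeline at the quench point, passes only the unprotected stages plus
the retention factor, and

    %BX = 100 × (1 − D_pep_max_RAW / (N − 2)) .

Rates for peptide-stage exchange are evaluated in the peptide's own context
(its termini are the termini created by digestion).

## Correction audit

The classic correction rescales the measured curve by the fully deuterated
control, `D_CORR(t) = D_RAW(t) / D_max_RAW × (N − 2)`. `assess_correction`
sweeps the labeling time, computes raw/ideal/corrected curves in closed
form, and reports three distortion metrics defined here (the distortion is
usually shown only graphically): the maximum absolute deviation
|D_CORR − D_IDEAL| over the grid, the RMSD, and the signed per-point bias.
Two exactness theorems are verified to near machine precision: a single
observable site (tripeptide) and uniform back-exchange rates (homopolymer)
both make the decay factors cancel, so D_CORR ≡ D_IDEAL. For heterogeneous
peptides the distortion grows with both the back-exchange extent and the
spread of per-site rates.

The shipped sweep scenarios dial %BX with a single back-exchange stage at
pH 2.5 / 0 °C (no electrospray factor): 200/1000/2000 s on the ACDEFGHI
test peptide give ≈9/33/50% back exchange. The three protection sets used
in the sweep examples (uniform-flexible, uniform-rigid, mixed) are this
package's own documented choices made to span the qualitative regimes; they
reproduce the qualitative finding — distortion grows with %BX and rate
heterogeneity — rather than any specific published panel, whose protection
values are not available.

## Synthetic data

`generate_synthetic` draws a sequence (uniform over the 20 standard
residues by default, weights configurable), a protection profile of
alternating flexible (log P uniform in [0, 1]) and rigid (log P in [4, 7])
blocks of 4–12 residues — spanning the range from unprotected loops to
strongly protected secondary structure — and an overlapping peptide tiling
(lengths 5–15, overlap 3) in which every peptide has at least one
observable site. One integer seed drives a single `numpy` generator stream;
identical specs give byte-identical files. The generator emulates the
*structure* of real inputs, not their biology: no pepsin cleavage
specificity, no correlation between sequence and protection, no
experimental noise, no incomplete-m100 artifacts. Tests passing on these
fixtures therefore validate the kinetic bookkeeping and the correction
algebra, not agreement with any particular protein.

## Numerical choices and verification

The piecewise closed form is exact for piecewise-constant conditions, so no
ODE solver is used in the library. The test suite cross-checks it against a
brute-force fixed-step Runge-Kutta integration of dD/dt = k(target − D)
(5 ms steps) to 1e-5 occupancy on 50 seeded random workflows, and checks
the two-site correction against a hand-derived two-exponential expression
to 1e-10. Property tests use moderate, fixed problem sizes chosen to be
decisive yet quick: 100 random tripeptide scenarios for single-site
exactness (1e-12), five homopolymers with heterogeneous protection (1e-10),
and 1000 generated peptides for the capacity law. Degenerate inputs are
defined behavior: zero-duration stages are identity operations, peptides
shorter than three residues (or with all-Pro observable ranges) are
rejected, a zero fully-deuterated control raises a diagnostic division
error, and an empty labeling-time grid is a configuration error raised
before any computation.

## Known limitations

- EX2 only; opening-limited (EX1) kinetics are rejected, not approximated.
- Deuterium bookkeeping is at centroid/occupancy level; no isotope
  envelopes or spectral simulation.
- The quench-stage simplifications above bias retained deuterium slightly
  high relative to a pipeline with residual D2O during digestion.
- Side-chain and His-C2 hydrogen exchange are not modeled; solvent
  additives and co-solvent effects on k_ch are not represented.
- The rate-parameter transcription is validated against anchor values at
  the few-percent level; per-residue rates inherit that uncertainty.
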