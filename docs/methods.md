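# Methods

## Model and procedure

The package operationalizes conformational-selection screening in four
steps: (i) dissect a free-ligand conformational ensemble into sub-ensembles
defined by structural criteria, (ii) dock random samples of each
sub-ensemble independently against a receptor, (iii) convert binding
energies to dissociation constants and compare the sub-ensembles
statistically, and (iv) characterize the resulting complexes by
helix-contact patterns. The premise is that the ligand's preformed
conformation is conserved on binding (the ligand is rigid inside the
docking backend); receptor flexibility is likewise out of scope.

### Frame classification

Two criteria partition every frame:

* **Proline isomer.** The ω dihedral CA(i−1)–C(i−1)–N(i)–CA(i) of the bond
  preceding the proline (residue 7 by default), computed with the atan2
  formulation in the range (−180°, 180°] and the sign convention of
  standard structural-biology libraries (cross-checked against biotite).
  A frame is cis iff |ω| < 90°; the boundary goes to trans. 90° is the
  midpoint between the ideal isomers; real ω values cluster tightly near 0°
  and ±180°, so the window position is uncritical.
* **Tail compactness.** The distance between the Tyr2 and Arg8 η-hydrogen
  markers; compact iff r < 1.0 nm (strict). Both the selection and the
  threshold are configurable; the η–η pair is the default marker, and a
  δ-hydrogen variant can be selected instead where preferred.

Frames, not time-weighted segments, are the classification unit, because
snapshots are sampled uniformly in time. Classification is done per
replica; replicas are never pooled before snapshot sampling.

### Mixture mode analysis

Distance distributions are summarized by 1-D Gaussian mixtures (k = 1, 2)
fitted by EM with 5 seeded restarts each (scikit-learn), selected by
minimal BIC, with an sd floor of 10⁻³ nm against singular components.
One deliberate refinement: the quantity of interest is the number of
*distinct density maxima*, not the mixture order. A hard-truncated
single-mode sample is skewed, and at n ≈ 10⁴ the BIC reliably prefers two
heavily-overlapping components to absorb that skew even though the density
has one maximum. The selector therefore evaluates the chosen k = 2 density
on a 4001-point grid over the data range and collapses to the k = 1 fit
when it finds a single maximum, flagging the result
(`collapsed_unimodal`). On the default synthetic data this yields two modes
for trans and one for cis, stably across seeds.

### Screening and K_D

Defaults follow the study protocol: 50 structures per sub-ensemble, 25
docking repeats each (1250 complexes per sub-ensemble per run), 3 runs, so
a full campaign is 9 screening experiments. Sampling is without
replacement. Energies are canonicalized to the negative-favorable
convention at ingest (scores produced under a positive-favorable
convention are negated once, and the flag recorded), which makes
K_D = exp(ΔG/RT) coherent. T defaults to 298.15 K (configurable);
R = 1.987204·10⁻³ kcal mol⁻¹ K⁻¹. Top-N selection pools all records of a
sub-ensemble, sorts by energy and breaks ties by (conformer, repeat).

Seeds are hierarchical: a master seed plus the (run, class, conformer,
repeat) counters feed `numpy.random.SeedSequence`, so any subset of a
campaign reruns identically and the full output is byte-identical across
executions.

The built-in docking backend is a deliberately coarse stand-in with no
claim of physical realism: one bead per residue, ~200 seeded rigid-body
placements around the receptor pocket centroid, each scored by a 12-6 well
ε[(σ/r)¹² − 2(σ/r)⁶] per bead pair (ε = 0.5 kcal/mol, σ = 0.55 nm, capped
at +10ε), best pose kept. Its absolute energies are not meaningful —
consistent with the screening philosophy that docking scores should only
be compared among each other. Real engines plug in through the backend
contract `dock(conformer, receptor, n_poses, seed) → BindingScore` or
through the energy-table reader.

### Statistics

Box plots use linear-interpolation quantiles (the common "type 7" rule,
fixed so that values 1..9 give quartiles 3/5/7), whiskers at the most
extreme data within 1.5·IQR, outliers beyond. The default between-class
test is Welch's two-sided t on log₁₀ K_D — dissociation constants are
log-scale quantities and the compared groups are small (n = 5) — with
Mann–Whitney available as a distribution-free alternative. Because
log K_D is an affine function of ΔG at fixed T, testing on energies gives
identical t and p; the choice matters only for other statistics. Two
identical zero-variance groups return p = 1 by convention. Fold change is
the ratio of best (minimum) K_Ds, with group A the putatively better
binder. No multiple-testing correction is applied (three raw pairwise
p-values per run).

### Contacts

A ligand residue contacts a helix iff the minimum distance over all
atom/bead pairs is strictly below the cutoff: 0.45 nm for all-atom heavy
atoms, 0.8 nm for one-bead-per-residue models (no cutoff is canonical; the
distance criterion is our operationalization of "interacts with").
Contacts are per pose; aggregation across poses is a reporting layer.

### Line shapes

Peaks are Lorentzians parameterized directly by FWHM,
L(x) = A(w/2)²/((x−x₀)² + (w/2)²), fitted by bounded least squares
(`scipy.optimize.least_squares`) with one shared constant baseline per
trace; polynomial baseline correction is considered preprocessing.
Automatic initialization takes the n tallest local maxima subject to a
minimum mutual spacing (⅛ of the trace per peak), which prevents two
starting guesses from landing on one broad noisy peak. Non-convergence
raises an error carrying the last residual norm.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure of the study system:

* **Trans trajectory** — a two-state Markov chain over
  {compact, extended} with truncated-Gaussian emissions: compact
  N(0.5, 0.08²) nm, extended N(1.9, 0.3²) nm, both truncated to
  [0.3, 2.5] nm (the observed distance range). Switch probabilities
  0.01/0.02 per frame give ~100-frame mean dwells and a ~2/3 compact
  stationary fraction; the real relative populations and switching rates
  were never quantified, so these are modelling choices, not calibrated
  claims.
* **Cis trajectory** — a single truncated-Gaussian state,
  N(2.2, 0.35²) nm on [1.0, 2.8] nm.
* Default length 12,000 frames at 10 ps/frame (~120 ns); 3 replicas × 2
  isomer states = 6 trajectories per replication design.
* **3-D realization** — one CA bead per residue (ring residues on a fixed
  hexagon), marker pseudo-protons on residues 2 and 8 placed so their
  separation equals the series value to 10⁻⁶ nm, and backbone pseudo-atoms
  around residue 7 constructed to give ω = 0°/180° ± 5° seeded jitter.
  Sufficient for every downstream geometric operation; not a physical
  peptide model.
* **Receptor** — seven 10-bead helix columns on a 1.1 nm circle around a
  central pocket, annotated 1–7 with disjoint residue ranges.
* **Energy tables** — Gaussian energies per class (mean −6.0 kcal/mol,
  sd 0.5); the extended-trans mean is shifted by −RT ln(ratio)
  (ratio = 3 by default) so the expected best-K_D separation matches the
  observed two- to three-fold reduction in direction and magnitude.

Consequently, passing tests demonstrate that the pipeline recovers known
structure from data with the right statistical shape — mode centers,
switching counts, class separations, contact patterns. They do not
demonstrate force-field accuracy, docking-score realism, or transferability
to ensembles whose sub-ensembles are not separable by a single distance
criterion.

## Numerical choices

* Internal unit is nm; PDB I/O converts Å↔nm at the boundary. Hydrogen
  name variants (`1HH1` ↔ `HH11`) are normalized on read.
* Dihedral range (−180°, 180°], atan2 formulation; −180° maps to +180°.
* Mixture fitting requires ≥ 50 points; a zero-variance series returns a
  flagged degenerate single component at the sd floor.
* Problem sizes in the test suite and the acceptance script (12,000-frame
  mixture fits, 2,400-frame screening fixtures, 200 seeded replicates for
  the selectivity check) were chosen so each check is statistically
  decisive at desk scale.
* The acceptance script derives all randomness from `--seed`; the GMM seed
  is reduced mod 2³¹.

## Known limitations

* The built-in scorer's energy scale is arbitrary; derived K_D magnitudes
  from it are not affinities. Use the energy-table route for real scores.
* No population or kinetics estimation from trajectories (deliberate:
  finite trajectories at slow-switching regimes do not support it).
* Classification requires the compact/extended criterion to be a single
  interatomic distance; multi-criterion dissection is out of scope.
* No mmCIF/XTC/DCD readers; multi-model PDB is the trajectory exchange
  format. No hydrogen placement or topology inference.
* 2-D NMR processing (apodization, zero-filling, cross-peak analysis) is
  out of scope; the line-shape module fits 1-D traces only.
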