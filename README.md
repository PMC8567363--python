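# vcss — virtual conformational space screening

`vcss` asks whether a receptor binds a flexible peptide ligand by
*conformational selection*: does it preferentially bind one of the distinct
conformational sub-ensembles the free peptide already populates in solution?
The package was built around the cyclic nonapeptide vasopressin
(CYFQNCPRG, disulfide ring 1–6, flexible three-residue tail) and its class-A
GPCR receptor, but every stage is generic.

The pipeline has four stages, each usable on its own:

1. **Dissection** — every trajectory frame is classified by two structural
   criteria: the cis/trans isomer of the peptide bond preceding a proline
   (ω dihedral CA(i−1)–C(i−1)–N(i)–CA(i); cis iff |ω| < 90°) and the
   compactness of the tail (marker distance between the Tyr2 and Arg8
   η-hydrogens; compact iff r < 1 nm). This yields the sub-ensembles
   C_TRANS (compact trans), E_TRANS (extended trans) and E_CIS (extended
   cis). Distance distributions are characterized by a 1-D Gaussian mixture
   with BIC model selection plus a unimodality check, so the reported
   component count is the number of distinct density maxima.
2. **Screening** — from each sub-ensemble, *n* structures are drawn at
   random and docked *m* times each against the receptor (default
   50 × 25 = 1250 complexes per sub-ensemble per run, three runs). Binding
   energies ΔG (kcal/mol, negative = favorable) convert to dissociation
   constants via

   K_D = exp(ΔG / RT), R = 1.987204·10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K,

   i.e. ΔG = −RT ln K_binding with K_binding = 1/K_D. The docking backend is
   pluggable: a built-in seeded rigid-body scorer over a capped 12-6 bead
   potential, or a TSV of externally computed energies.
3. **Statistics** — the top five complexes per sub-ensemble (lowest ΔG) give
   box-plot summaries of K_D, pairwise Welch t-tests on log₁₀ K_D and the
   best-K_D fold change between sub-ensembles.
4. **Contacts / line shapes** — per-pose maps of which transmembrane helices
   each ligand residue touches, and a Lorentzian line-shape fitter
   (FWHM-parameterized) for comparing cis/trans NMR resonance widths.

A synthetic module generates all inputs with the statistical structure of
the study system — Markov-switching bimodal trans trajectories, monomodal
cis trajectories, a seven-helix toy receptor and energy tables with a
controlled best-K_D separation — so the full pipeline runs and is testable
without MD or a docking engine.

## Worked example

`examples/screen_and_compare.py` generates a synthetic energy table with a
3-fold target separation, selects the top five complexes per sub-ensemble
and compares them:

```
3750 complexes (1250 per sub-ensemble)

E_TRANS: best K_D = 9.17e-07 M, top-5 median log10 K_D = -5.88
C_TRANS: best K_D = 2.00e-06 M, top-5 median log10 K_D = -5.46
E_CIS: best K_D = 2.76e-06 M, top-5 median log10 K_D = -5.47

E_TRANS vs C_TRANS: p = 3.68e-04, fold change (best K_D) = 2.18
E_TRANS vs E_CIS: p = 9.33e-06, fold change (best K_D) = 3.01
```

The extended-trans sub-ensemble reaches the lowest dissociation constant;
the 2–3-fold best-K_D advantage with small p-values is the signature of
conformational selection. The other examples cover ensemble dissection
(`dissect_ensemble.py`: bimodal trans modes at ≈0.50/1.88 nm, monomodal cis
at ≈2.17 nm), helix-contact mapping (`contact_pattern.py`) and Lorentzian
fitting (`fit_lineshape.py`).

A thin CLI mirrors the library:
`vcss simulate|dissect|screen|stats|contacts|lineshape --help`.

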