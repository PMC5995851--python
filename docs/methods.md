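# Methods

This note documents the models implemented in `c1ring`, the defaults and
their rationale, what the synthetic data do and do not emulate, and the
numerical choices that matter.

## Phosphoform cycle

KaiC's two C2-domain phosphosites cycle in the fixed order
S/pT → pS/pT → pS/T → S/T → (S/pT). The model is a linear first-order
chain with generator matrix Q (columns summing to zero, which *is* the
conservation law); the trajectory is the matrix exponential
A(t) = expm(Qt)·A(0), exact up to floating point. The cycle-closing rate k₄
(S/T → S/pT) is retained in the type but defaults to 0: re-phosphorylation
requires KaiA, which the auto-dephosphorylation assay lacks. One model
therefore serves both the assay and full-oscillator contexts.

Default rates are package constants, k₁ = k₂ = k₃ = 0.4 h⁻¹, chosen so the
relaxation to the fully dephosphorylated state is essentially complete
within ~20 h, matching the hours-scale assay window. They are deliberately
*not* fitted to published gel densitometry, which is graphical only. The
default initial mix (0.30, 0.45, 0.15, 0.10) represents a mostly
phosphorylated population at the start of dephosphorylation. Units: hours
and h⁻¹ everywhere; ATPase turnovers quoted per day are converted by /24 at
the boundary (`atpase_to_rate`).

## Fluorescence decomposition

FI_app(t) = Σᵢ FIᵢ·Aᵢ(t) is fitted by least squares with the measured
abundances as the design matrix. Choices:

* **Nonnegativity default.** FIᵢ are physical emission intensities, so the
  default fit is NNLS; the unconstrained fit is available for diagnostics
  and, by feasible-set nesting, never has larger RSS.
* **Strict grid equality.** Abundances are data, not a smooth model;
  resampling/interpolation is an explicit preprocessing step, never done
  silently inside the fit. The reconstructed fit consequently inherits the
  abundances' point-to-point scatter.
* **Identifiability.** A state whose abundance never exceeds 0.01 (the
  practical resolution of gel densitometry) is reported as unidentifiable
  by name rather than silently assigned a coefficient; rank of the design
  is checked as well.
* **Replicates.** Default: fit each replicate separately and report the
  mean ± SE with SE = sample SD/√n (n = 3 experiments is the standard
  design). A pooled global fit is provided but not default. With n = 3 the
  replicate SE has 2 degrees of freedom, so ±2 SE intervals cover the truth
  with Student-t probability ≈ 82%, not the Gaussian 95% — intervals should
  be read accordingly (±3 SE ≈ 90%).
* Probe contributions difference two fits (masked: WT − mutant; inserted:
  mutant − WT) with component-wise quadrature SEs.

## Binding kinetics

Schemes (concentrations in µM, monomer basis, 1:1 site stoichiometry;
hexamer cooperativity is out of scope):

* **CS** (conformational selection):
  C_pre ⇌ C_post (k_cf, k_cr); C_post + B ⇌ C_post·B (k_on, k_off).
* **IF** (induced fit): C + B ⇌ C·B_enc (k_on, k_off);
  C·B_enc ⇌ C·B\* (k_cf, k_cr). The observable tracks the *converted*
  complex C·B\*, because the fluorophore reports the C1-ring rearrangement,
  not mere encounter; this yields the standard increasing
  k_obs = k_cr + k_cf·L/(K_d + L).
* **CS_dual**: CS plus B_gs ⇌ B_fs (k_bf, k_br) with only the
  fold-switched B_fs binding. Initial condition puts KaiB at its
  fold-switch equilibrium (the proteins are pre-incubated separately before
  mixing). When the fold switch is not slower than the KaiC transition the
  titration profile keeps the decreasing CS shape.

Initial condition at mixing: all KaiC unbound in the pre-transition ground
state, no complex. The observable is
FI_app(t) = fi_free + (fi_bound − fi_free)·complex(t)/C_total with
fi_bound ≤ fi_free (binding quenches the probe). AMP-PNP (non-hydrolyzable
ATP) is modelled simply as k_cf = 0 — no separate nucleotide state — which
reproduces the flat-curve/no-complex phenotype and raises a typed
"no transition" error from the half-life extractor.

Defaults: k_on = 100 µM⁻¹h⁻¹ and k_off = 50 h⁻¹ (K_d = 0.5 µM, binding
rapid-equilibrated on the hours scale of the conformational step);
dissociation slow in the tight-binding contexts because stable complexes
survive gel filtration. Integration: LSODA, rtol 1e-8, atol 1e-10 µM;
default grid 0–18 h at 5-min spacing (the incubation window); mass
conservation is asserted to ≤1e-6 µM at every point.

**Half-life convention.** t½ is the first midpoint crossing of FI_app
between its initial and final values, located by linear interpolation
(matching the first/last-point amplitude convention of titration analysis).
A separate single-exponential fit op reports t½ = ln2/k; the two are never
silently substituted. For a near-exponential relaxation 1/t½ = k_obs/ln 2:
quantities read off 1/t½-vs-concentration profiles are therefore on the
1/t½ scale, a fixed factor 1/ln 2 ≈ 1.44 above the underlying rate
constant. The CS saturation statement that is exactly true is: the fitted
exponential rate at saturating ligand equals k_cf (verified in tests to
within 5% in the rapid-equilibrium regime).

**Classifier.** Both hyperbolic forms are fitted to the profile
(nonnegative bounds; data-driven starting points); the lower-RSS form wins
provided its fitted span across the measured range exceeds 5% of the mean
level, otherwise "ambiguous" (a flat profile — e.g. k_cr = 0 — degenerates
both forms). The CS-profile fitter flags K_d as unidentifiable when the
profile is flat or the fitted k_cr vanishes.

## Structural metrics

Parsing via biotite (PDB and mmCIF), first model only, altlocs resolved by
occupancy, author residue numbering preserved verbatim (S. elongatus
numbering for KaiC; T. elongatus numbering, e.g. A158 ↔ S157, for the
KaiB–KaiC complex entries). Superposition is the closed-form SVD (Kabsch)
optimum with the reflection guard; atoms are paired by (chain mapping,
residue number, insertion code, atom name) over common residues, default
backbone {N, CA, C, O}, default chain mapping first-chain-to-first-chain
(the single-protomer comparison) with an explicit override.

SASA is Shrake–Rupley point quadrature (default 960 points/atom, probe
1.4 Å, Bondi-style single-atom radii; unknown elements error unless an
override radius is supplied). Waters are always excluded; other
heteroatoms (bound ATP, ions) are excluded by default with an `include_het`
opt-in — published burial numbers rarely state the convention, so both
modes should be reported when validating them. Residue SASA sums all atoms
of the residue (backbone + side chain). Burial = SASA(isolated chain) −
SASA(assembly) under identical settings; ≥ 0 up to quadrature noise
(960 vs 4000 points agree within 2% on fixtures).

## Synthetic data

The generators emulate: four-state abundance trajectories with
multiplicative "densitometry" noise clipped at zero and renormalized to
row-sum 1 (renormalization is an assumption — relative band intensities sum
to one by construction); FI_app as the linear mixture of the *true*
abundances plus additive Gaussian detector noise (the two noise sources are
instrumentally independent); KaiB-mixing relaxation curves with additive
observation noise; triplicate experiments with per-replicate seeds derived
deterministically (SeedSequence spawning) from one master seed, so
serialized datasets are byte-for-byte reproducible. Default noise is 1% of
signal for both sources — the real measurement noise is not quantified
publicly, so this is a stated assumption.

Not emulated: instrument response, photobleaching, inner-filter effects,
spectral shape realism (the log-normal emission band exists only to
exercise band integration — trapezoidal on the 1-nm grid — and NATA/
concentration normalization). Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to every instrumental artifact of real spectroscopy.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 20–25 point
time grids, 5-point (titration) to 49-point (saturation scan) concentration
grids, 100–200 Monte-Carlo draws for the calibration/recovery studies, and
0–18 h or 0–48 h integration windows — sizes at which every statistical
conclusion asserted is stable under the fixed seeds used. All randomness
flows from explicit seeds; the two headline quantities recomputed by
`scripts/acceptance.py` are deterministic.

## Known limitations

* Published abundance/fluorescence figures are graphical only; no numeric
  ground truth for ΔFIᵢ exists, so decomposition claims are validated by
  round-trip and calibration properties on synthetic data.
* The kinetic schemes are the standard two-step limits; the full oscillator
  (KaiA feedback, hexamer-resolved stoichiometry, nucleotide exchange) is
  out of scope.
* Structural validation against the published crystallographic numbers
  requires the user to fetch the PDB entries (4TL7, 5YZ8, 5JWO); the
  which-structure/which-atom-subset conventions behind the published SASA
  values are not fully specified, hence the ±15% tolerances used there.
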