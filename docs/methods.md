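# Methods

This note documents the models, procedures, defaults and design choices
behind `esiptkit`, and what the synthetic ensembles do and do not establish.

## Scope and data model

The package analyses *conformational ensembles* of an intramolecularly
hydrogen-bonded chromophore: ordered frames sharing one atom topology, read
from multi-model PDB (fixed-column ATOM/HETATM, MODEL/ENDMDL delimited,
occupancy/B-factor written as 1.00/0.00 and ignored on read) or XYZ
trajectories.  Coordinates are Å throughout; no unit auto-detection.  The
XYZ dialect carries only elements and coordinates, so atom and residue
naming is regenerated on read — round trips are exact for coordinates (PDB
to its 3 printed decimals, XYZ to 6) but XYZ does not preserve atom names.

Two free torsions describe the chromophore's internal state:

- **dihedral_1** — the inter-ring twist about the bridge bond
  (N3–C2–C1′–C2′ quadruple in the shipped template);
- **dihedral_2** — the hydroxyl torsion (C1′–C2′–O–H), which controls the
  N···HO contact distance.

Note the first atom of the inter-ring quadruple: the bridge carbon of a
2-arylbenzothiazole has only the ring N and S as neighbours, so a
"thiazole-carbon" reference for this torsion does not exist chemically; the
ring nitrogen is used, making 0° the conformation with N cis to the
hydroxyl-bearing carbon (the hydrogen-bonded arrangement).

## Geometry

Torsions use the IUPAC sign convention computed via the two-argument
arctangent form (numerically stable near 0°/180°), wrapped to (−180°, 180°].
The signed dihedral is *invariant* under reversing the atom order (all three
bond vectors negate pairwise, leaving both atan2 arguments unchanged) and
*negates* under mirror reflection; the tests assert both.  Degenerate inputs
(collinear consecutive atoms) raise rather than return a value.

Superposition RMSD solves the optimal rigid-body alignment (Kabsch) via
`scipy.spatial.transform.Rotation.align_vectors`; congruent sets return 0 to
within SVD round-off (~1e-8 Å).

Circular statistics: the circular mean is the argument of the mean unit
phasor and is undefined (raises) when the resultant length is < 1e-12, e.g.
for {0°, 180°}; circular standard deviations are computed on deviations
wrapped about the circular mean.

## Hydrogen bonds

A geometric criterion, boundary-inclusive: donor–acceptor heavy-atom
distance ≤ 3.0 Å AND deviation of the D–H···A angle from linearity ≤ 30°
(the convention of common trajectory-visualisation tools).  Occupancy
reports, per donor–acceptor pair, the fraction of frames with at least one
event and the pair's share of all detected events (shares sum to 100% when
any event exists).  The hydrogen must be the one bound to its donor — the
caller's responsibility; no protonation-state detection is attempted.

## Metastate identification

1. **Embedding.**  Each torsion column is made linear either by unwrapping
   (`raw_degrees`, default) or by expanding to (sin, cos) (`sincos`).
   Unwrapping cuts the circle *in the middle of the column's largest angular
   gap*, so no populated basin straddles the seam.  (Cutting at the circular
   mean ±180° — the more obvious choice — fails for symmetric multi-basin
   landscapes, where the mean direction can point straight at a basin; for
   unimodal columns both rules coincide.)
2. **Scaling.**  `auto` (default): none when all descriptors share one kind
   (the homogeneous case, e.g. two dihedrals → covariance PCA), unit
   variance when kinds are mixed so degrees and Å are commensurable.  With
   exactly two standardized columns a correlation PCA would always return
   the ±45° diagonals as components regardless of the data — the reason
   homogeneous matrices are analysed on the covariance scale.
3. **PCA.**  scikit-learn, all components kept (explained variances sum to
   100%); each component's sign is fixed by forcing its largest-magnitude
   loading positive, making the fit fully deterministic.
4. **Clustering.**  Default k-means (fixed seed, `n_init=10`) on the score
   space; a density alternative (DBSCAN with a k-distance heuristic, noise
   attached to the nearest cluster) infers the cluster count.  The
   `components` argument restricts clustering to the leading components:
   the pipeline clusters long-lived metastates on PC1 only, which mirrors
   their separation along the leading coordinate and avoids a genuine
   k-means failure mode — on a flattened six-basin landscape the full-2D
   k=3 objective has strong local optima that merge basins across the two
   axes.  Sub-states are then split along PC2 by an *exact* 1D 2-means
   (all sorted splits enumerated; deterministic, no seed), labelled
   `<parent>A`/`<parent>B` with A the lower centroid; a unimodal parent
   splits near its median by construction (documented behaviour), and
   parents with < 2 frames are left undivided with a warning.
5. **Numbering.**  `cluster_metastates` defaults to descending population
   (ties by ascending PC1 centroid).  The pipeline uses `order="pc1"`:
   clusters are numbered along the torsion dominating PC1 by wrapped
   circular mean, which is stable across seeds and independent of where the
   angular seam fell — ends/centre basins keep the same numbers run to run.
6. **Populations.**  Per-metastate counts and percents (2 decimals, plus a
   nearest-integer display value).  Per-metastate descriptor means are
   circular for torsions, arithmetic otherwise.

## Representatives and the geometric ESIPT criterion

For each metastate the representative is the equilibrium-ensemble frame
minimising a standardized distance to the metastate's mean descriptors:
torsions contribute wrapped angular differences divided by the column's
circular standard deviation, other descriptors absolute differences divided
by the plain standard deviation, combined as a Euclidean norm; ties break to
the lowest frame index.  Metastate means are computed on the flattened
(biased-like) ensemble, which visits rare basins; the frames come from the
equilibrium ensemble.  If the best equilibrium frame lies above a
configurable ceiling (a basin never visited at equilibrium), the nearest
flattened-ensemble frame is used and flagged.  The pipeline adds an "EQ"
representative at the global equilibrium means — the equilibrium
conformation itself.

A conformation is **ESIPT-capable** iff its N···HO distance is strictly
below the threshold (default 3.00 Å): the proton transfer needs the
hydrogen-bond contact between the photoacid and the accepting nitrogen.
The ensemble-level statistic is the percentage of frames satisfying this.

## Photophysics

Inputs are per-conformation energy differences in eV along the four-state
ESIPT cycle — ΔE₁ (enol S₁→S₀ emission gap), ΔE₂ (keto S₁ minus enol S₁;
negative favours transfer), ΔE₃ (keto S₁→S₀ emission gap) — read from CSV
where a missing value is an empty field or an em-dash (absent, never zero).
Absolute four-state energies are accepted as an alternative input and
reduced to the same deltas.

Wavelengths use λ = hc/E with hc = 1239.84193 eV·nm (CODATA), rounded to
2 decimals.  The Stokes shift is the difference of the two *rounded*
wavelengths, keeping printed wavelength and shift tables mutually consistent
(e.g. ΔE₁ = 3.37, ΔE₃ = 2.43 eV gives 510.22 − 367.91 = 142.31 nm, where the
unrounded subtraction would print 142.32).

ESIPT occurrence is the geometric call: ΔE₃ present AND (distance unknown OR
< 3.00 Å).  ΔE₂ enters only as a favourability annotation (favourable when
negative) — a conformation with ΔE₂ barely below zero is still capable.
An absent ΔE₃ is interpreted as "no keto pathway", so keto wavelength and
Stokes shift are never reported for it.  Spectral-region labels are
descriptive only: ≤ 380 nm "UVA", above it "visible" (the conventional
violet onset; chosen so near-violet emission around 391 nm is labelled
visible while 368 nm remains UVA).

The ensemble summary sums the population fractions of the metastates whose
representatives can perform ESIPT (fractions must total 100 ± 0.1%).

## Synthetic ensembles

The generator replaces the MD/QM engines for testing and emulation.  A
`TorsionalLandscape` is a mixture of states over (dihedral_1, dihedral_2),
each with a weight and von Mises concentrations (default κ = 50, σ ≈ 8°).
Frames are i.i.d.: state by weight (`equilibrium`) or uniformly over states
(`flattened`, a qualitative stand-in for expanded-ensemble sampling — no
bias potential or reweighting factors exist).  Coordinates are built by
natural-extension placement from an idealized Z-matrix template whose
N···HO distance runs monotonically from ≈2.33 Å (φ₂ = 0°) to ≈4.15 Å
(φ₂ = 180°); the bridge and hydroxyl angles are widened relative to
textbook values so this range brackets both hydrogen-bonded (~2.3 Å) and
broken (~4.2 Å) contacts, with the 3.0 Å criterion crossing near |φ₂| ≈ 75°.
No claim of quantum-level accuracy is made for the template.

Presets (10,001 frames by default, a typical analysis-stride frame count):

- `system1` (vacuum-like): two near-equal states split only in the ring
  twist (0°/45°), hydroxyl intact — weights 5012/4989 out of 10,001.
- `system2` (water-like): the same two main states (4849/4876) plus two
  sparsely populated hydroxyl-flipped states (138 each, φ₂ = 180°):
  ≈97.2% of frames keep the ESIPT-capable contact.
- `system3` (protein-like): three long-lived basins in the hydroxyl torsion
  (φ₂ = −130°/0°/+130°, weights 1791/6294/1916 out of 10,001), each bimodal
  in the ring twist (±35°, 50/50): ≈62.9% capable.

The ring-twist means (45° second state, ±35° sub-states) keep every
"capable" basin's contact ≥ 4σ below the 3.0 Å crossing, so the emulated
capable fractions are sharp; a 120° twist would itself break the contact on
this template.  Landscape weights, not the analysis, define the study
conditions; they were set once from the emulated population layout.

**What passing tests show — and don't.**  Frames are independent draws with
isotropic von Mises noise and exact topology; real trajectories are
autocorrelated, anharmonic, and noisy in all internal coordinates, and real
basins need not be axis-aligned in the two dihedrals.  Recovery of weights
within binomial 3σ and of the 3×2 basin hierarchy on these ensembles
validates the pipeline's statistics and bookkeeping, not the conformational
sampling of any real system.

## Pipeline semantics

The metastate model is fitted on the flattened ensemble (full basin
coverage); populations and the capable percentage are then computed from the
*equilibrium* ensemble's nearest-centroid assignment, because an ideally
flattened ensemble carries no population information.  (In a real partially
flattened run the biased populations retain meaning; `population_source:
biased` switches to them.)  No free-energy reweighting is performed
anywhere — the chain selects conformations, it does not reweight
observables.

Determinism: fixed seeds make every stage bit-reproducible (seeded
generators, deterministic PCA sign convention, seeded k-means, exact 1D
splitter); re-running a config reproduces all numeric outputs exactly.

## Problem sizes

Default ensembles are 10,001 frames; the full pipeline (two ensembles,
descriptors, PCA, clustering, representatives, hydrogen bonds, photophysics)
runs in a few seconds on one CPU at that size.  Tests use 10–10,000-frame
ensembles chosen to make their statistical tolerances (binomial 3σ) sharp.

## Known limitations

- The template is a rigid idealized fragment; only the two named torsions
  move, and its distances should not be read as quantum-accurate.
- Density clustering's ε heuristic is simple; for oddly shaped basins
  k-means with an explicit k (or `sincos` embedding near the seam) is the
  safer route.
- The ensemble summary trusts the representative-to-metastate join by
  conformation id (`2A` → metastate 2, `EQ` → the basin of the EQ frame);
  tables keyed differently need an explicit mapping.
- Trajectory-dependent statistics of any particular real simulation
  (specific RMSD values, hydrogen-bond partner shares, docking scores)
  cannot be reproduced from synthetic ensembles and are out of scope.
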