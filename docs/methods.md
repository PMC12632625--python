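# Methods

This note documents the models implemented in `hostguest`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## One-site calorimetric isotherm

The titration model describes a perfusion (overflow) cell of volume V₀
holding host at initial concentration M₀, titrated with guest at syringe
concentration X₀ in injections dVᵢ. Because injected volume displaces cell
contents, concentrations after cumulative injection v follow the
mean-displacement convention

    [M] = M₀ (1 − v/2V₀) / (1 + v/2V₀)
    [X] = X₀ (v/V₀) / (1 + v/2V₀)

With n equivalent, independent sites per host and association constant
K_a, the bound concentration is the root of the 1:1 mass balance,

    [MX] = ½ [ b − √(b² − 4 n[M][X]) ],   b = n[M] + [X] + 1/K_a,

taking the physical (smaller) root; the discriminant is non-negative for
any valid inputs. The cumulative binding heat is Q = [MX]·ΔH·V₀ (joules),
and the observed heat of injection i adds back the heat carried out with
the displaced volume:

    qᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2.

Instrument vendors differ in the exact dilution/displacement convention;
the differences enter fitted parameters below the 1% level. The convention
above is used consistently by the simulator and the fitter, so parameter
recovery closes exactly on noiseless data. One consequence worth knowing:
the summed heats of a titration driven far past saturation approach
n·ΔH·(M₀V₀) only up to terms of order (v/2V₀)², so "total heat equals total
binding enthalpy" holds to ~1% only when the injected volume is a few
percent of the cell.

**Fitting.** `fit_one_site` minimises weighted squared residuals against
this forward model with `lmfit` (trust-region least squares). K_a is
parametrised as log K_a with bounds [ln 10⁻³, ln 10¹⁵] for conditioning;
n ∈ [0.05, 20] or fixed at exactly 1 (`fix_n`, the standard choice for
weak binders where n is not identifiable); ΔH ∈ ±10⁴ kJ/mol. Initial
values: ΔH from the integral heat divided by the host amount, K_a from a
mid-range c-value (c = n·K_a·M₀ = 100) unless supplied. Standard errors
come from the local curvature; K_D's by the delta method from log K_a.
Degenerate data never raise: all-zero heats return a flagged
uninformative fit, and c outside [1, 1000] attaches a warning, since
outside that window the isotherm shape carries little information about
K_D. Temperature defaults to 298.15 K throughout.

## Free-energy bookkeeping

`dg_from_kd` implements ΔG = RT ln(K_D/c°) with c° = 1 M and
R = 8.31446 J mol⁻¹ K⁻¹; `entropy_term` is the Gibbs relation
−TΔS = ΔG − ΔH, stored with the printed sign convention (negative =
entropically favourable). `ThermoRecord.is_consistent` flags rows whose
printed (ΔG, ΔH, −TΔS) violate the Gibbs relation beyond 0.15 kJ/mol —
the tolerance consistent with three independently rounded one-decimal
values.

The additive ("assembled") binding free energy is the exact six-term sum

    ΔG_calcd = ΔE_int + ΔE_disp + ΔG_solv − TΔS + ΔE_def,host + ΔE_def,guest

over components supplied as data: supermolecular interaction energy,
two-body SAPT dispersion, implicit-solvent solvation free energy, an
entropic term from restraint-based (attach–pull–release) simulations, and
the strain energies of host and guest at the complex geometry. Components
tabulated once per complex (typically ΔG_solv) are inherited by the other
conformers of that complex, with the inheritance recorded in provenance.
Nothing in this package computes electronic energies; `interaction_energy`
and `deformation_energy` are bookkeeping over supplied values, the latter
warning when the "relaxed" reference lies above the strained geometry.

**Conformer combination.** Guests resolved in N binding poses combine as

    ΔG_total = −RT ln Σᵢ exp(−ΔGᵢ/RT),

evaluated with `scipy.special.logsumexp` so the T→0 limit and widely
separated conformers are handled without overflow. The result is ≤ the
minimum conformer value, equals it as T→0, and equals g − RT ln N for N
degenerate poses. With components spanning ±300 kJ/mol the combination is
almost always dominated by the best pose; the packaged reference series
shows shifts between 0 and 0.31 kJ/mol.

## QTAIM classification

Inputs are bond-critical-point properties from a wavefunction-analysis
code: ρ(r_c), ∇²ρ(r_c), V(r_c) in atomic units (tabulated as au × 10³).
Derived quantities:

* local kinetic energy density from the local virial theorem, which in
  atomic units reads ¼∇²ρ = 2G + V, hence G = (¼∇²ρ − V)/2 (G ≥ 0; a
  negative value indicates inconsistent inputs and warns);
* Cremer–Kraka local energy density H = V + G;
* empirical interaction energy E = (−172.5·V + 0.33) kcal/mol, converted
  to kJ/mol (×4.184). The relation is calibrated on hydrogen bonds;
  applying it to other closed-shell contacts (e.g. C–F⋯O) is an
  extrapolation the annotate step performs but does not hide.

Classifications:

* Hayashi: ∇²ρ > 0 ∧ H > 0 → pCS (pure closed shell, electrostatic);
  ∇²ρ > 0 ∧ H ≤ 0 → rCS (regular closed shell, incipient covalency);
  ∇²ρ ≤ 0 → SS (shared shell). The SS branch is retained even though
  intermolecular contacts in this domain essentially never reach it.
* Jeffrey geometric, on the H⋯acceptor distance: strong < 1.5 Å ≤
  moderate < 2.2 Å ≤ weak ≤ 3.2 Å, beyond which the label carries an
  out-of-band flag. The d column is interpreted as the H⋯A contact
  distance, not donor⋯acceptor.
* Jeffrey energetic, on E: weak < 16.7 ≤ moderate < 62.8 ≤ strong
  (kJ/mol; the 4 and 15 kcal/mol boundaries). Boundary values fall in the
  higher class.

`annotate_table` composes all of the above over a pandas table, checks any
supplied G column against the virial identity (default tolerance
5×10⁻⁵ au), types each contact from its label or explicit element columns,
and is idempotent and row-order equivariant. Because every classification
depends only on signs and fixed thresholds, it is invariant under a common
positive rescaling of the density columns.

Re-deriving H and E from printed (∇²ρ, V) reproduces published two-decimal
tables within ±0.05 in their units; tables printed to one decimal carry
combined input/output rounding of up to ~0.09, which the tests account for
explicitly. All published class labels reproduce exactly.

## Pose geometry

Structures are occupancy-aware Cartesian models. The CIF reader (gemmi)
honours cell parameters and the atom_site loop — label, type symbol,
fractional coordinates, occupancy, disorder group — and orthogonalises
fractional coordinates once on read; everything else in the file is
ignored. The labelled-XYZ dialect is a plain-text Cartesian format with
label/occupancy/group columns, used for synthetic structures.

Planes are total-least-squares: the normal is the smallest principal
direction of the centred selection (SVD), the plane passes through the
selection centroid, and the rms perpendicular residual is reported.
Collinear selections (second singular value ≈ 0) are rejected. Descriptor
conventions:

* d(N⋯Plane1): unsigned perpendicular distance of the charged nitrogen
  from the portal-oxygen plane; a signed variant is positive on the cavity
  side when the plane is oriented toward a reference point.
* ∠(Cen1-Cen2-N): vertex angle at the equatorial centroid Cen2, so small
  values mean the nitrogen sits on the portal axis.
* ∠(Phenyl··Plane2): acute angle between the aryl-ring and equatorial
  planes, folded to [0°, 90°].

Host planes and centroids use all (ordered) host atoms unweighted; guest
descriptors are computed per disorder group with the refined occupancy
carried through, and no occupancy-weighted mixing of poses is performed —
collapsing across components is left to the caller. All descriptors are
invariant under rigid-body isometries of the structure.

## Synthetic data

Each generator embeds the ground truth it was built from and derives its
random stream from `SeedSequence(seed, spawn_key=(KIND,))` with a fixed
per-generator KIND, so outputs are byte-reproducible and adding a
generator never shifts the others.

* **Titrations** are forward-model heats plus i.i.d. Gaussian noise per
  integrated injection heat. The default scale, 1% of the first-injection
  heat, is a repository convention chosen to be of the order of a modern
  power-compensation instrument's integrated-heat repeatability; it is not
  a measured figure. Default conditions mirror a typical experiment on
  this system: 20 × 2 µL of ~10 mM guest into ~1 mM host in 200 µL at
  298.15 K. Not emulated: raw thermograms, baseline drift, first-injection
  artifacts, heat-of-dilution curvature (blanks are whatever the caller
  supplies).
* **Energy tables** draw the six components uniformly from ranges spanning
  the magnitudes of the reference series (interaction −290…−220,
  dispersion −185…−150, solvation +255…+285, entropic −75…+45, host
  deformation +125…+160, guest deformation +10…+25 kJ/mol) with the
  solvation term tabulated once per complex. Truth: per-row sums and
  per-complex Boltzmann combinations.
* **BCP tables** are constructed from (V, ∇²ρ) pairs: V is chosen inside a
  Jeffrey energy band (with a margin from the 16.7/62.8 boundaries) and
  ∇²ρ relative to −4V to fix the sign of H, so the virial identity holds
  to machine precision by construction and every planted label sits away
  from its decision boundary — the classifier must recover 100% of them.
* **Toy complexes** are idealized barrels: 7-fold portal-oxygen rings at
  radius 3.5 Å, z = ±3.05 Å, and 14 equatorial carbons at 4.4 Å — CB[7]'s
  approximate dimensions — with pseudo-guests placed to realise requested
  descriptors exactly (the seed only randomizes azimuth, to which all
  descriptors are invariant). They carry no thermal motion, no hydrogens,
  no solvent and no symmetry; passing descriptor round trips therefore
  validates the geometry code, not the crystallographic refinement that
  produces real coordinates.

Because simulator and consumer share the forward models, recovery tests
demonstrate internal consistency and numerical correctness; they do not
probe model misspecification against real instruments.

## Problem sizes and numerical choices

The test suite runs at deliberately small sizes — 20-injection titrations,
100 noise replicates for the median-K_D study, 500-row BCP tables,
10-point plane-fit oracles — which complete in a few seconds while leaving
every statistical margin wide (the median K_D error at 1% noise is ~1%,
against a 5% bound). Tolerances follow the data's printed precision:
±0.1 kJ/mol for one-decimal energy tables, ±0.05 for two-decimal derived
columns, 10⁻⁶ for geometry round trips, machine precision for algebraic
identities. Ties and degenerate inputs are rejected or flagged, never
silently resolved.

## Known limitations

* Single-site 1:1 binding only: no multi-site, competitive or displacement
  isotherms, and no baseline integration of raw thermograms.
* The additive free-energy estimate is bookkeeping over supplied
  components; correlation with experiment (slope ≈ 0.15 on the packaged
  series) shows rank agreement, not absolute accuracy.
* The empirical V→E relation is extrapolated beyond hydrogen bonds when
  tables apply it to fluorine contacts.
* The CIF reader handles a minimal subset: no symmetry expansion, no
  anisotropic displacement parameters, no hydrogen placement.
* Published pose-descriptor and hydrogen-bond tables are packaged as data
  for reporting, but reproducing them computationally requires the
  deposited crystal structures, which are external to this repository.
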