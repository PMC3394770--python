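# Methods

This note documents the models, conventions and defaults behind each module,
the choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Coordinates, cells and space groups

Atoms are kept in ångströms in the orthogonal frame; fractional coordinates
are produced on demand through the standard PDB orthogonalization matrix.
The unit-cell volume uses the general triclinic formula
`V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ)`, which reduces to
`abc` for orthorhombic and `abc·sinβ` for monoclinic cells; it agrees with
the determinant of the orthogonalization matrix to 1 part in 10⁶ (tested
against gemmi on random cells).

Space-group operators are hard-coded for the five groups this pipeline needs
(P1, P2₁, C222₁, I222, P2₁2₁2₁), generated from the International Tables
general positions with centering translations applied explicitly; the tables
are verified against gemmi in the test suite, and any other symbol raises an
error rather than guessing.  Operators are integer rotation matrices plus
fractional translations, closed under composition modulo lattice
translations.

The PDB reader is deliberately strict: malformed fixed-column fields raise an
error naming the line, a blank occupancy is an error, and a missing CRYST1
yields a structure that cell-dependent operations refuse.  Alternate
conformers keep the highest-occupancy copy (ties: first altloc label).

**Matthews coefficient.** `Vm = V/(n_total·M)` with `n_total` the chain count
for the whole cell (asymmetric-unit chains × multiplicity).  Solvent content
uses `1 − 1.66·0.74/Vm` with the unrounded constant 1.2284; the standard
partial specific volume 0.74 cm³/g reproduces printed solvent contents to
±0.3 percentage points.  The monomer mass is a user parameter defaulting to
the average mass of the longest chain (free-amino-acid masses minus one water
per peptide bond), because deposited headers rarely state the mass behind a
printed Vm.  For the ipomoelin crystals a 16.5 kDa monomer reproduces all
four printed Vm/solvent rows, while the His-tagged construct is quoted at
17.3 kDa on gel filtration — the two values are intentionally not conflated.

## Oligomer assembly

Symmetry mates are generated for every operator and every integer lattice
shift in −1..+1 per axis (sufficient to cover operators written with unit
offsets, e.g. `-x-1,-y,z`).  Two mates are in contact when any inter-chain
heavy-atom pair is closer than 5.0 Å — a single permissive threshold; the
biological significance of an interface is judged downstream by buried area,
not here.  Waters and free ions are excluded from the contact graph and
ligands follow their protein chain.  Assemblies are connected components of
the contact graph, deduplicated by a canonical signature (the sorted multiset
of member operators relative to a reference member, which is invariant under
any global symmetry operation).  Components whose signature is a sub-multiset
of a larger component's are discarded: they are copies whose partners fell
outside the finite shift search, not genuine smaller assemblies.

## Surface areas and interfaces

SASA uses the Shrake–Rupley point-counting construction: each atom's sphere
of radius `r_vdw + probe` (probe 1.4 Å) is sampled with a deterministic
Fibonacci lattice (default 960 points; no RNG) and a point is accessible when
outside every neighbour's expanded sphere.  Radii follow a NACCESS-style
table (C 1.70, N 1.55, O 1.52, S 1.80, Cd 1.58; unknown metals 1.70 Å;
anything else errors).  Points falling exactly on a neighbour boundary count
half — a measure-zero refinement in generic geometry that makes degenerate
configurations (coincident identical spheres) reproduce the analytic union
area.  Convergence between 960 and 4000 points is under 1 % on the fixtures,
and totals agree with biotite's independent implementation (same radii) to
well within 2 %.

Buried interfaces follow the PISA convention:
`(SASA_A + SASA_B − SASA_AB)/2`, protein heavy atoms only (waters, ions and
sugars excluded), and a residue is "interface" when it loses more than
0.1 Ų of SASA upon complexation — a threshold low enough to recover the
contiguous residue ranges typical of published interface lists.

## Contact geometry

Hydrogen bonds are called on heavy-atom distance alone (default 3.5 Å):
crystal structures at ~2 Å resolution carry no hydrogens, and angle terms
cannot be evaluated without placing them.  The donor/acceptor dictionary
gives every standard residue its backbone N donor and O acceptor plus the
usual side-chain roles; methyl pyranosides get hydroxyls O2/O3/O4/O6 as
donor+acceptor, the glycosidic O1 and ring O5 as acceptor only (recognized by
ligand code or, as a fallback, by atom-name pattern).  Residues within one
sequence position on the same chain are not paired — covalently linked
backbone N/O sit inside hydrogen-bond range by construction; the exclusion
can be disabled.  Unknown residues are warned about and skipped.

Methyl–π contacts require a methyl-carbon-to-ring-centroid distance ≤ 4.5 Å
and an elevation of ≥ 30° above the ring plane (standard CH–π survey
geometry); tryptophan contributes both its five- and six-membered ring
centroids, with the ring plane estimated by SVD.  Metal coordination counts
O/N atoms within 3.0 Å of each metal.  Distances are exact internally and
rounded to 0.1 Å only in reports.

## ITC

The forward model is the single-site (Wiseman) isotherm with the symmetric
Origin-style displacement corrections

    M_t = M₀ (1 − f)/(1 + f),   X_t = X_s (ΔV/V₀)/(1 + f),   f = ΔV/(2V₀),

bound complex from the one-site quadratic, and per-injection heat equal to
the change in `ΔH·V₀·[MX]` plus the standard displaced-volume term
`(dV/V₀)·(Q_i + Q_{i−1})/2`.  The exponential perfusion model differs by
under 0.5 % at the default 36 µl total injected into 280 µl, so the choice
of convention is immaterial at this protocol.  Default protocol: 280 µl
cell, 18 × 2 µl injections, 25 °C; heats are stored in µcal and fitted in
kcal per mole of injectant; R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹.

Fitting minimizes least squares over (log₁₀K_A, ΔH), with n fixed at 1.0 by
default (floatable) and multiple starting points.  The log parameterization
bars negative K_A trials.  A free per-injection baseline offset is available
for data without a subtracted dilution control but is **off** by default: at
moderate c the offset is nearly degenerate with ΔH and in simulation raises
the median K_A error at 2 % noise from ~4 % to ~15 %.  Derived quantities
satisfy ΔG = −RT ln K_A, −TΔS = ΔG − ΔH and c = n·K_A·[M] exactly by
construction, and the fit warns when c < 1 (fix n) or c > 1000.

Recovery behaviour, measured by simulate→fit: noise-free, K_A and ΔH return
to 0.1 % across K_A ∈ {10³,10⁴,10⁵} M⁻¹ and ΔH ∈ {−2,−6,−12} kcal/mol; with
Gaussian noise of 2 % of the first-injection heat, the median K_A error over
20 replicates is ≈2–4 % for c between 1 and 10.  Near the rectangular limit
the isotherm carries little information about K_A: at c = 100 the median
error is ≈10–13 %, i.e. at the edge of the 10 % band — a property of the
experiment design (18 injections, this noise), not of the optimizer, which
recovers noise-free data exactly there.

## SEC

Calibration is ordinary least squares of log₁₀(mass in kDa) on elution
volume; the kDa convention is fixed by back-computing the published line,
which yields 22.0 kDa at 89.6 ml only on that scale.  Mass estimates warn
beyond ±20 % of the calibrated volume range.  The oligomer call divides the
apparent mass by the monomer mass and rounds to the nearest integer (ties
up, floor 1); an apparent mass below half the monomer flags interaction with
the column matrix, the failure mode of a dextran-binding lectin run without
competing sugar.

## Synthetic fixtures

The toy-crystal generator builds an extended glycine chain (correct backbone
atom names, 3.8 Å residue spacing, idealized planar geometry) and places
designed features with exactly known ground truth: ligand oxygens at
specified distances from backbone amides (tilted off the chain plane so no
unintended polar pair comes within the 3.5 Å cutoff), a methyl probe above
the six-ring centroid of an idealized tryptophan indole (offset so the fused
five-ring centroid stays beyond the 4.5 Å cutoff), a Cd²⁺ site with up to
six waters at 2.3 Å, and crystal cells whose symmetry mates touch at a
designed separation — including a mini-chain near the intersection of three
two-fold axes in I222 whose three rotational mates assemble into a
222-symmetric tetramer, the packing motif of the apo crystal.  Designed
hydrogen-bond distances below (Σ vdW − 0.5 Å) are rejected as unphysical.
All generators are byte-reproducible under a fixed seed; noise is i.i.d.
Gaussian everywhere (ITC heteroscedasticity is out of scope).

What passing on these fixtures shows: the detectors implement their stated
geometry exactly, the assembler respects crystal symmetry, and the fitters
recover known parameters under realistic noise.  What it does not show:
performance on real β-prism folds with packing-level contact noise, sugar
ring conformers, or correlated ITC baselines — those are exercised only by
the optional benchmark tier on the deposited structures (placed under
`benchmarks/`, never downloaded by the package), where published interface
areas are matched to ±5 %, a tolerance that absorbs the unpublished radii
set and point density of the original web-service computation.

## Problem sizes

Defaults were chosen so the full test suite runs in seconds: toy chains of
8–20 residues (≈100–200 atoms), 960-point spheres (4000 for convergence
checks), 18-injection titrations with 20 noise replicates, 5-marker SEC
tables.  These are the sizes at which every published quantity reproduced
here is already stable to well inside its comparison tolerance.

## Known limitations

* mmCIF, anisotropic B-factors and refinement statistics are out of scope.
* Only the five space groups above are supported, by design.
* Hydrogen-bond calls are distance-only; no angular or energetic scoring,
  and water-mediated bridges are reported as separate contacts, not merged.
* The one-site model only; multi-site, sequential and competitive schemes,
  and raw thermogram peak integration, are not implemented.
* SEC works on calibrated elution volumes; no peak detection or Kav
  normalization.
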