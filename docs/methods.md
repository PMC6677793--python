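# Methods

This note documents the models, conventions and numerical choices behind
tpmkit, and what its synthetic-data round trips do and do not demonstrate
about real data.

## Ideal coiled-coil backbone (Crick parameterization)

The builder places CA atoms on a minor helix of radius R1 wound around a
superhelical path of radius R0:

    C(n)  = (R0 cos φ0, R0 sin φ0, h·n),   φ0 = σ0·2π·h·n/P + Δc
    CA(n) = C(n) + R1 (cos ψ · u + sin ψ · b)

with h the rise per residue along the superhelical axis, P the superhelical
pitch, Δc the per-chain phase offset, u the outward radial unit vector, t
the curve tangent and b = t×u.  σ0 = −1 encodes the left-handed superhelix.
The minor phase advances as ψ(n) = σ1·2π·n/ρ − (φ0(n) − Δc): the subtraction
removes the rotation of the local frame, so ρ is the *apparent* (lab-frame)
helical periodicity.  With the defaults — R0 = 4.9 Å, R1 = 2.26 Å,
h = 1.495 Å, ρ = 3.62, P = 140 Å, right-handed minor helix — consecutive CA
spacing is 3.78 Å; parameters implying spacing outside [3.6, 4.0] Å are
rejected.  These defaults are canonical parallel-dimer values chosen by this
package, not measurements of any particular structure.

Dimers are built with chain offsets {0°, 180°}, making the two chains exact
C2 partners about the superhelical axis.

## Local helix axes and coiled-coil radius

For residue i with neighbours i−1, i+1, the unit bisector A_i of the
CA(i−1)–CA(i)–CA(i+1) angle points toward the local helix axis.  Two
consecutive bisectors define a local axis segment; the local helix radius r
solves the pair of conditions (d + r(A_{i+1}−A_i))·A_{i,i+1} = 0 with
d = CA(i+1)−CA(i), in least squares.  The axis point of residue i is
CA(i) + r·A_i; terminal residues carry no axis point, so n CAs yield n−2
points.  Collinear CA triples are rejected as degenerate.

The central axis of a helix pair (or 4-helix bundle) is the per-residue mean
of the member axis points at aligned residue numbers (an explicit per-helix
numbering offset supports N-terminal chains numbered from 1 against
C-terminal chains numbered from 169).  The coiled-coil radius of helix k at
residue i is |axis_k(i) − central(i)|; multi-frame structures yield
per-residue mean and SD over a frame window, defaulting to the last third of
frames (the package's analogue of averaging the tail of a production run).

Accuracy, measured by round-trip against the builder: radius recovered
within 0.04 Å over R0 ∈ [3, 6] Å (a small inward bias of the bisector
construction on supercoiled helices), rise within 0.001 Å/residue.  The
axis points also carry a periodic sub-0.1 Å wobble at the minor-helix
period; it matters only for the twist extrapolation below.

## Overlap junction angles θ and ω

The junction is described by two chain pairs (C-terminal and N-terminal
coiled coils) and one flanking residue window per side, placed outside the
interdigitated span; windows must span ≥5 residues.  Per flank, a
total-least-squares line through the central-axis points gives the flank
axis, oriented along increasing residue number (both point the same way in
a head-to-tail junction).

* **ω (bend)** is the unsigned angle between the two flank axes.
* **θ (twist)** is the signed rotation of the N-flank's inter-helix vector
  (axis point of the first pair chain minus the second) relative to the
  C-flank's, right-hand rule about the junction axis (bisector of the flank
  directions, oriented C→N).  Because the inter-helix vector precesses with
  the superhelical phase (~3.8°/residue at the default pitch), comparing
  single-residue vectors at two different axial positions would mostly
  measure that phase advance.  The default therefore fits each flank's
  vector azimuth linearly against the axial coordinate and extrapolates
  both fits to the mutual closest-approach point of the two flank axes (the
  junction pivot); θ is the difference of the extrapolated azimuths,
  wrapped to (−180°, 180°].  Before the azimuth comparison each flank is
  de-tilted by the minimal rotation taking its axis onto the junction axis,
  which makes θ exactly the twist component of the rigid rotation between
  the flanks (verified analytically and by round-trip).  The literal
  single-residue variant (`reference="nearest"`) is available for
  comparison; it carries the phase-advance offset by construction.

Swapping the N/C roles of the junction specification negates θ and leaves ω
unchanged.  Round-trip accuracy on synthetic bundles: ω exact to <0.01°
across bends up to 30°; θ recovered within 0.26° across twists up to 45°.
The residual θ systematic (~0.25°) comes from the periodic axis-point
wobble biasing the linear azimuth extrapolation; it is constant across
imposed angles, so *differences* between conditions are unaffected.

For trajectories, θ and ω are measured per frame and summarized as mean ±
SD over the frame window (default last third).

## Superposition and RMSD

Kabsch least-squares superposition in its SVD form, with the proper-rotation
correction (det +1) so mirror solutions are never returned; RMSD is
computed over the paired atoms after applying the fit.  Range-restricted
comparisons select chains × inclusive author-numbered residue ranges ×
atom sets (CA or N/CA/C/O backbone); residues missing requested atoms are
errors by default, or skipped on request (crystal termini are often
unresolved).  The implementation is cross-checked in the test suite against
scipy's rotation alignment and a brute-force rotation-grid oracle.

## Ligand contacts

Every protein residue with a heavy atom within the cutoff (default 4.0 Å)
of a ligand heavy atom is reported once per ligand atom, at the minimum
distance, classified **hydrophobic** when the nearest protein atom is a
side-chain carbon/sulfur of Ala/Val/Leu/Ile/Met/Phe/Trp/Pro or a Tyr ring
carbon, **polar** otherwise (any N/O contact included).  Hydrogens are
ignored throughout.

## Model assembly

`assemble_overlap` superposes a fragment onto a scaffold over an
equal-length residue window (CA atoms of all mapped chains jointly),
renumbers the fragment into the scaffold frame, and splices it in from the
window outward on the stated side.  The window-fit RMSD is recorded in
metadata; a fit above 5 Å adds a warning rather than failing, and splice
discontinuities (CA–CA distance at the join) are reported by
`extend_termini` rather than regularized.  `thread_sequence` renames
residues to a target sequence at a stated register without moving any atom,
pruning side chains beyond CB.  Terminal extension builds an ideal segment
with given Crick parameters, superposes its first/last five CAs onto the
terminal five of the structure, splices with continuous numbering, and
rejects extensions whose CAs come within 2.5 Å of the body.  All modeling
is at the CA level; side-chain placement and any energetic refinement are
out of scope.

## CD thermal melts

Processing order is fixed: normalize → Savitzky–Golay smooth (default
window 5, polynomial order 2, uniform grid required) → differentiate
(central differences interior, one-sided ends) → fit df/dT with a sum of
Gaussians plus a constant baseline (lmfit).  Normalization fits linear pre-
and post-transition baselines over the first/last 10% of points and reports
fraction unfolded clipped to [−0.05, 1.05]; a min–max mode is provided for
curves without usable plateaus.  Component count is user-specified;
initialization takes the most prominent local maxima of the derivative.
Components are returned sorted by center; centers closer than 0.5 °C raise
a degeneracy warning.  Tm is the component center; ΔTm between two
conditions is the difference of matching centers with the two standard
errors combined in quadrature.  A derivative that is flat (range below
1e−12 per °C, or all fitted heights below 1e−9) is a fit error, not a
zero-amplitude "result".

The synthetic melt generator produces logistic transitions between linear
folded/unfolded baselines on a 20–65 °C, 0.5 °C grid by default, with
Gaussian noise expressed as a fraction of the transition amplitude and
optional replicates (averaged on a common grid by linear interpolation
before analysis).  Transition widths are stated as the SD of the derivative
peak in °C (converted internally to the logistic scale by √3/π), so
generator truth is directly comparable to fitted component sigmas.
Recovery: noiseless transitions that complete within the ramp (±3 widths)
are recovered within 0.003 °C; at 2% amplitude noise with three replicates,
within 0.2–0.5 °C.  The generator is a phenomenological stand-in — no
van't Hoff enthalpy, no heat-capacity baseline curvature, no instrument
drift — so passing round trips demonstrate the *analysis* is unbiased under
the stated noise model, not that real instrument artifacts are handled.

## Radioligand binding

Counts convert to molar amounts through the specific activity:
amount (mmol) = (cpm/efficiency) / (SA[mCi/mmol] × 2.22×10⁹ dpm/mCi), then
to concentration by the counted volume.  Isotopic dilution obeys
SA_mix = SA_hot/(1 + cold:hot), with the inverse mode returning the
required cold:hot ratio.  The one-site model B(L) = Bmax·L/(Kd+L) is fit by
nonlinear least squares on free ligand; a depletion-corrected total-ligand
form (the physical root of B² − B(Ltot+Bmax+Kd) + Ltot·Bmax = 0) is
provided because at ~5 µM sites against a ~2 µM Kd the free≈total
approximation is not negligible.  Fits with max(L) below the fitted Kd are
flagged ill-conditioned with a warning.  Stoichiometry is
Bmax/(dimer × junctions-per-dimer), junctions-per-dimer defaulting to 1 (a
continuous co-polymer; finite filaments of n dimers have (n−1)/n).  The
pre/post-incubation comparison merges the two isotherms on shared
concentrations and flags the post condition as background-level when its
bound values stay below 20% (configurable) of the pre-condition Bmax.  The
apparent Kd of a co-polymerization assay is reported as a fit parameter
only; no equilibrium interpretation is attached.

The isotherm generator mirrors the experimental design: 2-fold serial
dilutions 0.25–64 µM, 4 replicates, 125 mCi/mmol, 25 µL counted volume,
Poisson noise on expected dpm plus a constant background.  Under those
conditions the Kd estimator is unbiased to <1% over 200 simulations and
individual runs recover Kd within a few percent.

## Synthetic junction geometry

The bundle generator builds the C- and N-terminal dimers on one continuous
superhelical phase and axis, so the untransformed junction measures
θ = ω = 0 by construction.  The N-side dimer is built at R0 + 6.5 Å (a
radial "bulge") so its helices run just outside the C-side helices through
the 8-residue interdigitated span instead of colliding; a rigid twist about
the axis and bend about a perpendicular axis, both at the junction
midpoint, impose the ground-truth (θ, ω), and per-chain radial offsets are
realized by rebuilding the chain at R0 + δ.  Imposed-angle pairs across
bend ≤ 30° and twist ≤ 45° stay clash-free (no CA pair under 2 Å).  This is
a geometric test-bed: side-by-side coaxial dimers rather than the true
interleaved packing, rigid transformations rather than dynamics.  Round
trips therefore validate the measurement pipeline, not any physical model
of the junction.

Trajectories interpolate the angles linearly to their targets by a
convergence frame (default 10 of 35, one frame per nanosecond in spirit)
and fluctuate thereafter with Gaussian SD 2° — the few-degree
frame-to-frame variation typical of junction-angle traces.  The trajectory
check compares the measured window mean against the truth window mean over
the same frames, isolating measurement fidelity from the sampling noise of
a finite window.

## Determinism and degenerate inputs

Every generator is a pure function of its arguments including the seed;
writing the same seeded output twice is byte-identical, and the CLI
manifest records config and input checksums but no timestamps.  Degenerate
inputs fail loudly and specifically: collinear CA triples, flank windows
under 5 residues, empty frame windows, mismatched trajectory topologies,
baselines that cannot be separated, flat derivatives, all-zero isotherms,
insertion codes in PDB files.

## Known limitations

* All structural modeling is CA-trace level; no side chains, no sterics
  beyond a hard-sphere CA check.
* The local-axis construction has a small inward radius bias (<0.04 Å) and
  a ~0.25° θ systematic, both documented above and far inside the stated
  tolerances; condition *differences* cancel the θ systematic.
* The melt and isotherm generators are phenomenological; they do not
  emulate instrument-specific artifacts (thermal lag, quenching,
  scintillation efficiency drift).
* Comparisons against deposited crystal structures require the user to
  supply the coordinate files (see `data/structures/README.md`).
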