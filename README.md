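# tpmkit

Analysis toolkit for the head-to-tail **overlap junction** of tropomyosin
(Tpm) coiled coils — the 4-helix region where the C-terminus of one Tpm
dimer interdigitates with the N-terminus of the next as the polymer runs
along an actin filament.  The junction is the stability determinant of the
Tpm co-polymer and the binding site of anti-tropomyosin compounds such as
ATM-3507, which target the cancer-associated isoform Tpm3.1.

The package bundles the three quantitative workflows such a study needs,
each exercisable end-to-end on seeded synthetic data with known ground
truth:

1. **Coiled-coil geometry** — per-residue local helix axes from CA
   coordinates (three-point bisector construction), coiled-coil radius
   profiles r(i) = |axis_helix(i) − axis_central(i)|, overlap bend ω and
   signed twist θ of the junction (per frame and averaged over a trajectory
   window), Kabsch superposition with range-restricted RMSD, and ligand
   heavy-atom contact maps.  An ideal-backbone builder places CA atoms on
   the Crick parameterization (minor helix of radius R1 wound on a
   superhelix of radius R0 and pitch P), so every measurement can be
   round-tripped against known parameters.
2. **CD thermal melts** — normalize an ellipticity-vs-temperature curve to
   fraction unfolded, Savitzky–Golay smooth, differentiate, and fit df/dT
   with Gaussian components whose centers are the melting temperatures Tm;
   ΔTm between conditions with propagated fit uncertainties.
3. **Radioligand binding** — scintillation counts → concentration via
   specific activity (dpm = SA·2.22×10⁹ per mCi), one-site saturation fit
   B(L) = Bmax·L/(Kd+L) (free-ligand or depletion-corrected total-ligand
   form), stoichiometry per overlap junction, and the pre- vs
   post-incubation comparison that distinguishes incorporation during
   co-polymerization from binding to preformed filaments.

Model fits follow the statsmodels convention: `ThermalMeltModel(...).fit()`
and `OneSiteBindingModel(...).fit()` return results objects with estimates,
standard errors and a `summary()` table.  Geometry operations are plain
functions returning typed results.

## Worked example

Generate a synthetic 4-helix junction with an imposed twist of 15° and bend
of 8°, then measure both angles back, from the shell:

```sh
$ tpmkit simulate overlap-bundle --theta 15 --omega 8 --seed 7 --out-dir sim
sim/overlap_bundle.pdb
$ tpmkit angles --pdb sim/overlap_bundle.pdb --n-chains A,B --c-chains C,D \
    --n-flank 11-25 --c-flank 197-211 --out-dir ang
theta 15.26 deg, omega 8.00 deg
```

The ~0.25° excess on θ is the documented systematic of the axis-point
construction (see `docs/methods.md`); ω is recovered exactly.  The same
round trip in Python, plus a melt and a binding fit:

```python
>>> from tpmkit import synth, melt, binding
>>> df, truth = synth.gen_melt_curve(seed=0, tms=(52.0,), widths=(2.0,))
>>> res = melt.ThermalMeltModel.from_dataframe(df).fit(1)
>>> print(res.summary())
Thermal melt: Gaussian decomposition of d(fraction unfolded)/dT
  points: 91, replicates averaged: 1
  smoothing: Savitzky-Golay window 5, order 2
  components: 1  (rss = 0.000441)
    Tm[0] =  52.00 +/- 0.01 degC   (height 0.2162, sigma 1.78 degC)

>>> iso, truth = synth.gen_isotherm(seed=3)     # Kd 2 uM, Bmax 5 uM, n=4
>>> fit = binding.fit_one_site(binding.Isotherm(iso))
>>> print(fit.summary())
One-site specific binding: B(L) = Bmax * L / (Kd + L)
  observations: 36
  Kd   =          2 uM   (SE 0.0121)
  Bmax =      5.005      (SE 0.00722)
  residual sum of squares = 0.01501
>>> round(fit.molar_ratio_per_junction(tpm_dimer_uM=5.0), 3)
1.001
```

The Tm is the center of the Gaussian fitted to the derivative of the
unfolding curve; the stoichiometry of ~1 says that at saturation one ligand
molecule is bound per overlap junction (one junction per dimer in a
continuous co-polymer).

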