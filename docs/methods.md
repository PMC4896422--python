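# Methods

This note records the models behind `cdfragmap`, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and preprocessing

Raw CD is ellipticity θ in millidegrees. Repeated accumulations are averaged
pointwise and the buffer baseline subtracted. Conversion to mean-residue
molar circular dichroism uses

    Δε(λ) = θ(λ)[mdeg] · MRW / (32980 · c[mg/ml] · l[cm]),

i.e. normalisation by the *mean-residue* molar concentration
c_mr = c/MRW (MRW = protein mass / residue count, accepted range 80–200 Da).
This is the standard CD convention ([θ]_MRW = θ·MRW/(10·c·l) in
deg·cm²·dmol⁻¹, Δε = [θ]_MRW/3298). Pathlengths are entered in μm (vacuum-UV
cells are ~10 μm) and converted internally. All fitting happens on the
canonical 170–255 nm grid at 1 nm resolution; spectra on other grids are
linearly interpolated, never extrapolated.

## Six-component deconvolution

The model treats a spectrum as a linear combination of six component
contributions — regular α-helix (rH), distorted α-helix (dH), regular
β-strand (rS), distorted β-strand (dS), turn (T) and disordered (D) —
where "distorted" means the terminal residues of a segment (two per helix
end, one per strand end) whose optical activity differs from the segment
interior. Estimation follows the self-consistent SVD scheme of the SELCON
family:

1. Initial guess: the fractions of the spectrally closest reference protein
   (minimum RMSD between spectra).
2. The test spectrum and its current fraction guess are prepended to the
   reference spectrum/fraction matrices; a truncated SVD of the spectrum
   matrix at rank k gives the least-squares map from spectra to fractions;
   applying it to the test spectrum updates the guess. Iterate until the
   largest fraction change is < 1e-4 (at most 100 iterations; since the
   spectrum matrix is constant over the loop its SVD is computed once).
3. Rank sweep k = 2..8. A rank solution is retained when (a) every fraction
   exceeds −0.025, (b) the raw sum lies in [0.95, 1.05], and (c) its
   spectral reconstruction RMSD is within max(2× the best rank's RMSD,
   0.02 Δε). The RMSD is measured against the rank-k subspace of the
   *reference* spectra only: with the test column included, high ranks
   absorb the test spectrum's own noise and would always look best.
   Rule (c) is the package's formulation of the spectral-fit criterion the
   SELCON family applies; without it, low-rank solutions that satisfy (a)
   and (b) but fit the spectrum poorly would bias the average.
4. The final estimate is the mean of the retained solutions, clipped at
   zero and renormalised to sum to one. The dispersion across retained
   ranks is reported as a simple uncertainty proxy.

If no rank passes, the windows in (a)–(c) are widened progressively (×2,
then ×4), and the result flagged (`relaxed_selection`); only then does the
fit fail. All selection constants are user-overridable (`FitOptions`).

A diagnostic dS/rS ratio is exposed: an anomalously high distorted-strand
share signals content that cannot be cleanly distinguished from disorder.
The model does not reclassify such content.

## Segment counts

Each helix segment carries 4 distorted residues, each strand segment 2, so
for an N-residue protein

    n_α = round(N · f_dH / 4),    n_β = round(N · f_dS / 2),

with halves rounded up. (355 residues at f_dH = 0.22 give 19.525 → 20
helix segments — the arithmetic the acceptance script re-computes.) The
counts are homogeneous: doubling N while halving f_dH leaves them fixed.

## Localization

The published approach couples the CD-derived content to the sequence with
a trained neural network. `cdfragmap` substitutes a deterministic
propensity-constrained assignment with the same inputs, outputs and
fraction-preservation contract; it is a methodological stand-in, not a
reimplementation of any trained model. The CD content is a hard
constraint: exactly n_α helix segments (≥ 4 residues each) totalling
round(N·(f_rH+f_dH)) residues, n_β strand segments (≥ 2 residues)
totalling round(N·(f_rS+f_dS)), consecutive segments separated by at least
one coil residue. Among all feasible placements a dynamic program selects
the one maximising the summed per-residue propensity (helix propensity
over helix residues plus strand propensity over strand residues), using
the classic Chou–Fasman table (replaceable by TSV).

Design notes:

* The ≥1-coil separator makes segments coincide with label runs, so the
  distorted-end bookkeeping (2/end helix, 1/end strand) stays consistent
  with the segment counts. It also enables an O(N·|states|) DP: each
  segment transition consumes length+1 slots (a virtual trailing coil slot
  is appended at the sequence end), and with the state tracking *remaining*
  extra residues, all transitions collapse to contiguous-window maxima.
* The DP is exact; the test suite verifies score-optimality against
  exhaustive enumeration for small instances.
* Minimum lengths 4 (helix) and 2 (strand) keep the distorted-end
  convention self-consistent (a 4-residue helix is entirely distorted).
* Backtracking prefers, from the right: longest helix, longest strand,
  coil — a fixed rule that makes identical inputs give identical maps.
* Because residue totals are enforced exactly, the map-implied fractions
  differ from the CD input only by rounding (≲ 2.5/N per component, well
  under the 3-percentage-point contract at realistic N). When noisy CD
  estimates make counts and totals marginally inconsistent (e.g. two
  strand residues but zero strand segments), the pipeline reconciles them
  minimally (`strict=False`) instead of failing; the direct API raises by
  default.
* Turn and disorder are indistinguishable at the map level; both render as
  coil ('O'), and map-derived fraction sets report the lump as f_D.

A known limitation mirrored from NN-style localisers: methods free to merge
neighbouring segments underestimate segment counts. Here the counts are
fixed upstream by `estimate_segment_counts`, so merging cannot occur.

## Fragment consensus and difference spectroscopy

Fragment maps are computed in fragment coordinates and lifted to parent
numbering (1-based inclusive). The `trim` residues nearest each truncation
point (default 5, applied uniformly at both ends) are discarded as
structurally unreliable. The consensus label at a position is the majority
over the parent plus all covering trimmed fragments flagged native; ties —
including one-vs-one — resolve to the parent's label (majority voting is
the package's operationalisation of averaging categorical labels; each map
gets one vote). Fragments flagged non-native are excluded entirely. The
consensus distorted mask is recomputed from the consensus runs, capped by
run length where voting produces runs shorter than the minima.

The difference operator

    Δε_region = (Δε_parent·N_parent − Δε_frag·N_frag) / (N_parent − N_frag)

is the exact inverse of length-weighted mixing of region spectra (machine
precision; property-tested). Region fractions are obtained by deconvolving
the difference spectrum like any other. Validity requires both constructs
to retain native structure; a `NonNativeFragmentWarning` and an invalid
flag are attached otherwise. Non-nativeness is an *input* (the flag on the
fragment definition): detecting it automatically is out of scope.

## Construct QC

**Thermofluor.** Curves are sampled 25–99 °C at 0.5 °C (≥ 20 points and
≥ 30 °C span required). The default estimator smooths with a 5-point
centred moving average and takes Tm at the maximum of the first
derivative, refined sub-grid by a least-squares parabola over the peak ±5
points (±2.5 °C — wide enough to average point noise, narrow enough to
stay inside the transition). A curve is called "no clear melting point"
when the rising-phase amplitude is below 20% of the observed range, when
it does not exceed 5× a robust (MAD-based) noise estimate, or when the
derivative maximum sits on a scan boundary; the noise gate prevents pure
noise wiggles from being read as transitions. The estimator is invariant
to affine rescaling of the fluorescence. A Boltzmann sigmoid fit (lmfit)
is available behind `method="boltzmann"`; on clean sigmoids the two agree
within 0.3 °C. The derivative definition is preferred as default because
it needs no baseline model.

**SEC.** Column calibration is log-linear, log10(M) = a·V_el + b, fitted by
least squares from ≥ 3 standards with distinct elution volumes (slope
standard error and R² reported). Oligomer state: the ratio m_app/m_calc is
rounded half-up to an integer k; k ≤ 1 → monomer, k = 2 → dimer, k ≥ 3 →
multimer. Constructs eluting at or before a user-supplied void threshold
are flagged as soluble aggregates; no default threshold is asserted since
it depends on column geometry. Tables with European decimal commas are
parsed transparently. The packaged example table
(`data/construct_qc_example.tsv`) is the printed triage of a
355-residue uracil-DNA degrading factor's truncation constructs.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes; they define the study conditions for every test.

* **Basis spectra**: Gaussian band mixtures per component on the canonical
  grid. Band centers/amplitudes are phenomenological but sign-constrained:
  rH has negative bands at 222 and 208 nm, a positive band at 192 nm, and
  a vacuum-UV feature (negative near 170 nm, positive shoulder at 175 nm);
  dH is an attenuated red-shifted rH; dS leans polyproline-II-like, making
  it genuinely the hardest component to separate from disorder. Seeds
  jitter centers by ±0.5 nm and amplitudes by ±3%, small enough to
  preserve the sign pattern. The six components are well-conditioned as a
  basis (condition number ≈ 35 on the 86-point grid).
* **Reference set**: 31 proteins by default; fractions drawn from Dirichlet
  archetypes cycling helix-rich, strand-rich, mixed and disordered corners
  so the library brackets test compositions; spectra are F·basis plus
  Gaussian noise, default σ = 0.02 Δε (a carefully measured library is
  substantially cleaner than a single-construct spectrum).
* **Protein + truncation library**: defaults mirror a helix-rich
  355-residue protein — 20 helices, 62% helix, 11 strands, 8% strand, nine
  fragments alternating C- and N-terminal truncations, one flagged
  non-native with a freshly drawn (structurally transformed) arrangement.
  Segment lengths are multinomial above the minima; coil content is split
  30% turn / 70% disordered for spectrum synthesis. Sequences are sampled
  per label with propensity-softmax weights (β = 5), i.e. strongly
  propensity-consistent sequences: the idealised case where sequence and
  CD evidence agree. Native fragment maps inherit parent labels except
  that segment stubs clipped below their minimum length at a truncation
  point revert to coil — always within min_length−1 (< trim) residues of
  the cut, so fragment interiors match the parent exactly.
* **QC fixtures**: Boltzmann melt curves on the 25–99 °C grid (noise
  relative to amplitude; `flat=True` for transition-free constructs) and
  log-linear SEC standards.

What the generators do *not* emulate: wavelength-correlated instrument
noise, baseline drifts, concentration errors, exciton-coupling fine
structure, fragments that misfold subtly rather than grossly, and real
sequences' ambiguous propensity signal. Passing tests therefore show the
algorithms are correct and well-conditioned under the stated model, not
that any particular real protein will reach the same accuracies.

## Problem sizes used in validation

The recovery studies run at the study's natural scale: 31-protein
reference sets, 50 spectra per deconvolution study, 100 seeded proteins
(355 residues each) for the localization contract, 50 melt-curve
replicates, 100 random difference-operator trials, and five seeded
full-pipeline consensus runs. These sizes give stable averages while
keeping a complete validation run to a few minutes on one CPU.

## Known limitations

* The localization stage is a deterministic stand-in for a trained
  sequence model; on real proteins a modern predictor constrained the same
  way would place segments better.
* Turn content is not localised (lumped with disorder in maps).
* The SELCON-style fit inherits the reference-set dependence of all
  basis-set CD methods: compositions outside the library's span (e.g.
  polyproline II-rich) degrade gracefully but measurably.
* The oligomer classifier assumes globular elution behaviour; elongated
  monomers with m_app/m_calc ≈ 1.5 are genuinely ambiguous and will round
  to dimer.
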