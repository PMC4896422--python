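# cdfragmap

Spatially resolved protein secondary structure from circular dichroism (CD)
spectra of a full-length protein and a library of its truncation fragments.

## The problem

Vacuum-UV CD spectroscopy (λ down to 170 nm) resolves a protein's spectrum
into six secondary-structure components — regular and distorted α-helix
(rH, dH), regular and distorted β-strand (rS, dS), turn (T) and disordered
(D) — but a single spectrum only yields *global* fractions. When a
truncation library (e.g. from exonuclease-based incremental truncation
screening) provides soluble, folded fragments whose interiors retain the
parent's native structure, the per-fragment spectra can localise that
content along the sequence. `cdfragmap` implements the full analysis for
structural biologists running such screens:

1. **Deconvolution** — a self-consistent SVD method of the SELCON family
   estimates the six fractions `f` of a mean-residue Δε spectrum against a
   reference set of proteins with known structures.
2. **Segment counts** — distorted residues sit at segment ends (2 per helix
   end, 1 per strand end), so `n_α = round(N·f_dH/4)` and
   `n_β = round(N·f_dS/2)`.
3. **Localization** — a deterministic dynamic program places exactly those
   segments and residue totals on the sequence, maximising summed
   Chou–Fasman propensity; the implied fractions stay within 3 percentage
   points of the CD-derived input.
4. **Fragment consensus** — fragment maps are lifted to parent coordinates,
   the 5 residues nearest each truncation point are discarded, and a
   per-position majority vote (ties to the parent) yields the consensus map.
5. **Difference spectroscopy** — the region present in the parent but not a
   nested fragment has spectrum
   `(Δε_p·N_p − Δε_f·N_f)/(N_p − N_f)`,
   which is deconvolved like any other spectrum.
6. **Construct QC** — thermofluor melt curves give melting points
   (derivative maximum of the smoothed curve, or a Boltzmann fit) or a
   "no clear melting point" verdict; size-exclusion chromatography is
   calibrated log-linearly and the apparent/sequence mass ratio classifies
   monomer / dimer / multimer.

Because measured spectra for such studies are generally not deposited, a
first-class synthetic-data module generates every input — six-component
basis spectra with the canonical helix band signs (negative 222 and 208 nm,
positive 192 nm), a 31-protein reference set, parent + fragment libraries
with planted structure, melt curves and SEC standards — so the entire
pipeline is testable end to end.

## Worked example

```python
from cdfragmap import (CDSpectrumModel, estimate_segment_counts,
                       make_basis, make_reference_set, make_protein)

basis = make_basis(seed=0)
refs = make_reference_set(31, basis, seed=1)
protein = make_protein(basis=basis, seed=0, noise_sigma=0.05)  # 355 aa, 20 helices

result = CDSpectrumModel(protein.spectrum, refs).fit()
print(result.summary())
counts = result.segment_counts(n_residues=355)
print(f"n_alpha = {counts.n_alpha}, n_beta = {counts.n_beta}")
```

Output:

```
CD secondary-structure deconvolution
====================================================
sample:            parent
reference proteins: 31
kept SVD ranks:    [3, 4, 6, 8]
spectral RMSD:     0.0498 Δε
----------------------------------------------------
component     fraction   sd(ranks)
rH               0.407      0.0060
dH               0.197      0.0204
rS               0.022      0.0129
dS               0.060      0.0214
T                0.101      0.0145
D                0.213      0.0049
----------------------------------------------------
helix total      0.604
strand total     0.081
n_alpha = 18, n_beta = 11
```

The fit recovers the planted composition (62% helix / 8% strand, planted
true fractions rH 0.40, dH 0.23) from a spectrum carrying 0.05 Δε of
noise; the distorted-helix fraction implies 18 helix segments against the
planted 20 — the residual uncertainty a single noisy spectrum leaves, and
exactly what the fragment-consensus stage is there to tighten.

The same analysis is scriptable from the shell:

```sh
cdfragmap simulate --seed 0 --out fixture/        # write a synthetic study
cdfragmap fit --spectrum fixture/spectra/parent.txt \
              --refs fixture/reference_set --n-residues 355
cdfragmap run --config fixture/config.yaml        # full pipeline + report
cdfragmap qc  --sec-samples constructs.tsv        # Tm / oligomer triage
```

## Layout

```
src/cdfragmap/
  spectra.py        Spectrum container, I/O, preprocessing, Δε conversion
  deconvolution.py  CDSpectrumModel / DeconvolutionResult, reference sets,
                    segment counts, spectrum reconstruction
  localization.py   ResidueMap, propensity-guided segment placement (DP)
  consensus.py      fragment trimming, majority-vote consensus,
                    difference spectra and region fits
  qc.py             MeltCurveModel, SEC calibration, oligomer classification
  synthetic.py      generators for every input the analysis consumes
  evaluate.py       recovery self-benchmarks used by tests and scripts
  pipeline.py       YAML-driven end-to-end orchestration
  cli.py            `cdfragmap` command-line interface
docs/methods.md     modelling assumptions, parameter choices, limitations
```
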