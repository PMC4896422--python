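"""Self-benchmarks: recovery studies on the synthetic generators.

Each routine plants known structure with the generators, runs the analysis
exactly as the pipeline would, and reports how well the truth is recovered.
They are used by the test suite and by the reproduction script; all are
pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import consensus_map, difference_spectrum
from .deconvolution import (FractionSet, ReferenceSet, estimate_segment_counts,
                            fit_fractions)
from .localization import (assign_segments, fractions_from_map,
                           max_component_shift)
from .qc import estimate_tm
from .spectra import CANONICAL_GRID, Spectrum
from .synthetic import (BasisSet, make_basis, make_melt_curve, make_protein,
                        make_reference_set)

__all__ = [
    "deconvolution_recovery",
    "localization_contract",
    "difference_inversion_error",
    "tm_recovery",
    "end_to_end_agreement",
]

_ARCHETYPE = np.array([3.0, 2.0, 1.5, 1.0, 1.5, 2.5])


def deconvolution_recovery(n_spectra: int = 50, noise_sigma: float = 0.1,
                           seed: int = 0,
                           refs: ReferenceSet | None = None,
                           basis: BasisSet | None = None) -> dict:
    """Fit synthetic spectra with planted fractions; returns mean/max per-
    component absolute error over ``n_spectra`` draws."""
    basis = basis or make_basis(seed)
    if refs is None:
        # an idealised (noise-free) library for the noiseless study, the
        # default library quality otherwise
        ref_noise = 0.0 if noise_sigma == 0 else 0.02
        refs = make_reference_set(31, basis, noise_sigma=ref_noise,
                                  seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    B = basis.matrix()
    maes, worst = [], 0.0
    for _ in range(n_spectra):
        truth = rng.dirichlet(_ARCHETYPE)
        vals = B @ truth
        if noise_sigma:
            vals = vals + rng.normal(0.0, noise_sigma, vals.size)
        spec = Spectrum(CANONICAL_GRID.copy(), vals, units="delta_epsilon")
        est, _ = fit_fractions(spec, refs)
        err = np.abs(est.as_array() - truth)
        maes.append(err.mean())
        worst = max(worst, err.max())
    return {"mean_mae": float(np.mean(maes)), "max_mae": float(np.max(maes)),
            "worst_component_error": worst, "n": n_spectra}


def localization_contract(n_proteins: int = 100, noise_sigma: float = 0.1,
                          seed: int = 0) -> dict:
    """CD-derived fractions vs map-implied fractions after localization, on
    full pipeline runs over seeded synthetic proteins; returns the largest
    per-component shift observed."""
    basis = make_basis(seed)
    refs = make_reference_set(31, basis, seed=seed + 1)
    shifts = []
    for k in range(n_proteins):
        prot = make_protein(basis=basis, seed=seed + 10 + k,
                            noise_sigma=noise_sigma)
        est, _ = fit_fractions(prot.spectrum, refs)
        counts = estimate_segment_counts(est, len(prot.sequence))
        rmap = assign_segments(prot.sequence, est, counts, strict=False)
        shifts.append(max_component_shift(est, fractions_from_map(rmap)))
    return {"max_shift": float(np.max(shifts)),
            "mean_shift": float(np.mean(shifts)), "n": n_proteins}


def difference_inversion_error(n_trials: int = 100, seed: int = 13) -> dict:
    """Machine-precision check that the length-weighted difference operator
    inverts region mixing; returns the worst absolute error."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        n_parent = int(rng.integers(100, 400))
        n_frag = int(rng.integers(20, n_parent - 20))
        s_frag = rng.normal(0, 8, CANONICAL_GRID.size)
        s_region = rng.normal(0, 8, CANONICAL_GRID.size)
        mixed = (n_frag * s_frag + (n_parent - n_frag) * s_region) / n_parent
        parent = Spectrum(CANONICAL_GRID.copy(), mixed, units="delta_epsilon")
        frag = Spectrum(CANONICAL_GRID.copy(), s_frag, units="delta_epsilon")
        out = difference_spectrum(parent, n_parent, frag, n_frag)
        worst = max(worst, float(np.max(np.abs(out.values - s_region))))
    return {"max_abs_error": worst, "n": n_trials}


def tm_recovery(planted_tm: float = 51.3, n_reps: int = 50,
                noise_sigma: float = 0.01, seed: int = 19) -> dict:
    """Planted-Tm recovery from noisy sigmoids plus the flat-curve verdict
    rate (both phases of the thermal-shift validation)."""
    errs = []
    for rep in range(n_reps):
        curve = make_melt_curve(planted_tm, noise_sigma=noise_sigma,
                                seed=seed + rep)
        res = estimate_tm(curve)
        if res.has_transition:
            errs.append(res.tm - planted_tm)
    flat_correct = 0
    for rep in range(n_reps):
        res = estimate_tm(make_melt_curve(55.0, noise_sigma=noise_sigma,
                                          seed=seed + 1000 + rep, flat=True))
        flat_correct += int(not res.has_transition)
    return {
        "n_detected": len(errs),
        "mean_abs_error": float(np.mean(np.abs(errs))) if errs else np.inf,
        "max_abs_error": float(np.max(np.abs(errs))) if errs else np.inf,
        "flat_no_transition_rate": flat_correct / n_reps,
        "n": n_reps,
    }


@dataclass
class EndToEndResult:
    agreement: float
    n_covered: int
    n_residues: int
    parent_n_alpha: int


def end_to_end_agreement(seed: int = 31, noise_sigma: float = 0.1,
                         trim: int = 5,
                         basis: BasisSet | None = None,
                         refs: ReferenceSet | None = None) -> EndToEndResult:
    """Full pipeline on one seeded synthetic protein: per-residue label
    agreement between the consensus map and the planted truth, over
    positions covered by at least one trimmed native fragment."""
    basis = basis or make_basis(seed)
    refs = refs or make_reference_set(31, basis, seed=seed + 1)
    prot = make_protein(basis=basis, seed=seed, noise_sigma=noise_sigma)

    est, _ = fit_fractions(prot.spectrum, refs)
    counts = estimate_segment_counts(est, len(prot.sequence))
    pmap = assign_segments(prot.sequence, est, counts, strict=False)

    pairs = []
    for frag in prot.fragments:
        fest, _ = fit_fractions(frag.spectrum, refs)
        fcounts = estimate_segment_counts(fest, frag.definition.n_residues)
        fmap = assign_segments(frag.sequence, fest, fcounts, strict=False)
        pairs.append((frag.definition, fmap))

    cons, coverage = consensus_map(pmap, pairs, trim)
    covered = coverage >= 2
    truth = prot.residue_map.labels
    agreement = float(np.mean(cons.labels[covered] == truth[covered]))
    return EndToEndResult(agreement, int(covered.sum()), len(truth),
                          counts.n_alpha)
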