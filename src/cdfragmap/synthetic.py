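"""Synthetic data with the statistical structure the analysis assumes.

No public repository holds the measured spectra this kind of study produces,
so every pipeline stage is exercised on generated data instead:

* six phenomenological component basis spectra (Gaussian band mixtures on
  the 170–255 nm grid) honouring the canonical sign pattern of protein CD —
  the regular-helix component has negative bands near 222 and 208 nm and a
  positive band near 192 nm, plus a vacuum-UV feature (negative band near
  170 nm with a positive shoulder at 175 nm);
* a reference set of proteins with known fractions spanning helix-rich,
  strand-rich, mixed and disordered compositions, with spectra that are
  noisy linear combinations of the basis;
* a parent protein with a planted per-residue structure, a
  propensity-consistent sequence, a spectrum, and a nested truncation
  library whose native fragments inherit the parent's labels on their
  interiors (one fragment is optionally flagged non-native with a
  structurally transformed map, emulating a construct whose truncation
  destroys the fold);
* sigmoidal thermofluor melt curves on the 25–99 °C, 0.5 °C grid and
  log-linear SEC calibration standards.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .consensus import FragmentDef
from .deconvolution import (COMPONENTS, FractionSet, ReferenceSet,
                            reconstruct_spectrum)
from .localization import (CHOU_FASMAN, MIN_HELIX, MIN_STRAND, ResidueMap,
                           distorted_from_labels, fractions_from_map)
from .qc import MeltCurve, boltzmann
from .spectra import CANONICAL_GRID, Spectrum, save_spectrum

__all__ = [
    "BasisSet",
    "SyntheticFragment",
    "SyntheticProtein",
    "make_basis",
    "make_reference_set",
    "make_protein",
    "make_melt_curve",
    "make_sec_standards",
    "write_fixture_tree",
]

#: Default band parameters (center nm, width nm, amplitude Δε) per component.
#: Amplitudes follow the canonical magnitudes of protein CD basis spectra;
#: the distorted-helix component is an attenuated, red-shifted copy of the
#: regular helix, and the distorted-strand component leans toward the
#: polyproline-II-like shapes that make it hard to separate from disorder.
DEFAULT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "rH": ((169.0, 3.0, -3.5), (175.0, 2.5, 2.0), (192.0, 6.5, 12.5),
           (208.0, 5.5, -9.5), (222.0, 6.5, -11.0)),
    "dH": ((172.0, 3.0, -1.6), (178.0, 2.5, 0.9), (195.0, 6.5, 5.6),
           (211.0, 5.5, -4.3), (225.0, 6.5, -5.0)),
    "rS": ((175.0, 5.0, -2.5), (196.0, 6.0, 7.5), (217.0, 6.5, -5.5)),
    "dS": ((180.0, 5.0, 2.0), (200.0, 6.0, -3.5), (222.0, 7.0, 1.5)),
    "T":  ((178.0, 5.0, 3.0), (188.0, 5.0, -2.5), (205.0, 6.0, 2.2),
           (225.0, 8.0, -1.0)),
    "D":  ((178.0, 5.0, -6.0), (198.0, 6.0, -4.5), (217.0, 7.0, 1.2)),
}


@dataclass(frozen=True)
class BasisSet:
    """Six component basis spectra and their band parameters."""

    spectra: dict[str, Spectrum]
    bands: dict[str, tuple[tuple[float, float, float], ...]]

    def matrix(self) -> np.ndarray:
        """(n_wavelengths, 6) basis matrix in component order."""
        return np.column_stack([self.spectra[c].values for c in COMPONENTS])


def _gaussian_mixture(grid: np.ndarray,
                      bands: tuple[tuple[float, float, float], ...]) -> np.ndarray:
    vals = np.zeros_like(grid)
    for center, width, amp in bands:
        vals = vals + amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return vals


def make_basis(seed: int = 0, jitter: float = 1.0) -> BasisSet:
    """Component basis spectra: seeded small perturbations of the default
    Gaussian band parameters (center ±0.5·jitter nm, amplitude ±3%·jitter),
    small enough that the sign pattern of the helix bands is preserved."""
    rng = np.random.default_rng(seed)
    grid = CANONICAL_GRID
    spectra = {}
    bands_out = {}
    for comp in COMPONENTS:
        bands = []
        for center, width, amp in DEFAULT_BANDS[comp]:
            bands.append((
                center + jitter * rng.normal(0.0, 0.5),
                width,
                amp * (1.0 + jitter * rng.normal(0.0, 0.03)),
            ))
        bands_out[comp] = tuple(bands)
        spectra[comp] = Spectrum(grid.copy(), _gaussian_mixture(grid, bands_out[comp]),
                                 sample_id=f"basis_{comp}", units="delta_epsilon")
    return BasisSet(spectra, bands_out)


# Dirichlet concentration archetypes: helix-rich, strand-rich, mixed α/β,
# disordered — cycled so the reference set spans the composition simplex.
_ARCHETYPES = (
    np.array([8.0, 3.2, 0.6, 0.7, 1.6, 2.4]),
    np.array([0.8, 0.8, 6.0, 3.0, 2.2, 2.6]),
    np.array([3.5, 1.8, 3.0, 1.6, 1.8, 2.4]),
    np.array([0.7, 0.6, 0.8, 0.8, 2.2, 7.0]),
)


def make_reference_set(n: int = 31, basis: BasisSet | None = None,
                       noise_sigma: float = 0.02, seed: int = 0) -> ReferenceSet:
    """A reference set of ``n`` proteins: Dirichlet-sampled fractions across
    helix-rich / strand-rich / mixed / disordered archetypes, with spectra
    F·basis plus Gaussian noise of standard deviation ``noise_sigma`` Δε."""
    if n < 8:
        raise ValueError(f"reference set needs n >= 8, got {n}")
    rng = np.random.default_rng(seed)
    basis = basis or make_basis(seed)
    B = basis.matrix()
    grid = CANONICAL_GRID
    proteins = []
    for i in range(n):
        alpha = _ARCHETYPES[i % len(_ARCHETYPES)]
        f = rng.dirichlet(alpha)
        vals = B @ f + rng.normal(0.0, noise_sigma, size=grid.size)
        pid = f"ref{i + 1:02d}"
        spec = Spectrum(grid.copy(), vals, sample_id=pid, units="delta_epsilon")
        proteins.append((pid, spec, FractionSet.from_array(f)))
    return ReferenceSet(proteins)


@dataclass(frozen=True)
class SyntheticFragment:
    definition: FragmentDef
    residue_map: ResidueMap
    fractions: FractionSet
    spectrum: Spectrum
    sequence: str


@dataclass(frozen=True)
class SyntheticProtein:
    sequence: str
    residue_map: ResidueMap
    fractions: FractionSet
    spectrum: Spectrum
    fragments: tuple[SyntheticFragment, ...]
    basis: BasisSet


_AA = np.array(list(CHOU_FASMAN.keys()))
_PA = np.array([CHOU_FASMAN[a][0] for a in _AA])
_PB = np.array([CHOU_FASMAN[a][1] for a in _AA])

#: Sharpness of the propensity-weighted residue sampler; larger values give
#: sequences whose helix/strand segments carry a clearer propensity signal.
#: The default produces strongly propensity-consistent (low-complexity)
#: sequences, emulating the idealised case where sequence and CD evidence
#: agree about segment placement.
SEQUENCE_BETA = 5.0

_W_H = np.exp(SEQUENCE_BETA * _PA)
_W_S = np.exp(SEQUENCE_BETA * _PB)
_W_O = np.exp(SEQUENCE_BETA * (2.0 - _PA - _PB))
for _w in (_W_H, _W_S, _W_O):
    _w /= _w.sum()

#: Fraction of coil content counted as turn (the remainder is disordered)
#: when converting a residue map to a six-component fraction set.
TURN_SHARE_OF_COIL = 0.3


def _sample_sequence(labels: np.ndarray, rng: np.random.Generator) -> str:
    seq = np.empty(labels.size, dtype="<U1")
    for lab, weights in (("H", _W_H), ("S", _W_S), ("O", _W_O)):
        idx = np.where(labels == lab)[0]
        if idx.size:
            seq[idx] = rng.choice(_AA, size=idx.size, p=weights)
    return "".join(seq)


def _split_coil(mapped: FractionSet, turn_share: float = TURN_SHARE_OF_COIL,
                ) -> FractionSet:
    """Split the lumped coil fraction of a map-derived fraction set into
    turn and disordered parts."""
    coil = mapped.f_T + mapped.f_D
    return FractionSet(mapped.f_rH, mapped.f_dH, mapped.f_rS, mapped.f_dS,
                       turn_share * coil, (1.0 - turn_share) * coil)


def _place_segments(n: int, n_helices: int, h_tot: int, n_strands: int,
                    s_tot: int, rng: np.random.Generator) -> np.ndarray:
    """Random non-adjacent segment placement honouring minimum lengths."""
    h_extra = h_tot - MIN_HELIX * n_helices
    s_extra = s_tot - MIN_STRAND * n_strands
    if h_extra < 0 or s_extra < 0:
        raise ValueError("content below the per-segment minimum lengths")
    lengths = []
    if n_helices:
        extras = rng.multinomial(h_extra, np.full(n_helices, 1.0 / n_helices))
        lengths += [("H", MIN_HELIX + int(e)) for e in extras]
    if n_strands:
        extras = rng.multinomial(s_extra, np.full(n_strands, 1.0 / n_strands))
        lengths += [("S", MIN_STRAND + int(e)) for e in extras]
    rng.shuffle(lengths)
    n_seg = len(lengths)
    o_tot = n - h_tot - s_tot
    interior = max(n_seg - 1, 0)
    if o_tot < interior:
        raise ValueError(
            f"cannot separate {n_seg} segments with only {o_tot} coil residues"
        )
    spare = o_tot - interior
    gaps = rng.multinomial(spare, np.full(n_seg + 1, 1.0 / (n_seg + 1)))
    labels = np.full(n, "O", dtype="<U1")
    pos = int(gaps[0])
    for k, (lab, length) in enumerate(lengths):
        labels[pos:pos + length] = lab
        pos += length + int(gaps[k + 1]) + (1 if k < n_seg - 1 else 0)
    return labels


def _fragment_map(parent_labels: np.ndarray, frag: FragmentDef) -> ResidueMap:
    """Slice the parent map; segment stubs clipped below their minimum
    length at the truncation points lose their structure (relabelled coil),
    so only the first/last few residues can differ from the parent."""
    labels = parent_labels[frag.start - 1:frag.end].copy()
    n = labels.size
    runs = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((i, j, str(labels[i])))
        i = j
    for start, end, lab in (runs[0], runs[-1]):
        min_len = {"H": MIN_HELIX, "S": MIN_STRAND}.get(lab)
        if min_len is not None and end - start < min_len:
            labels[start:end] = "O"
    return ResidueMap(labels, distorted_from_labels(labels))


def make_protein(n_residues: int = 355, n_helices: int = 20,
                 n_strands: int = 11, helix_fraction: float = 0.62,
                 strand_fraction: float = 0.08, n_fragments: int = 9,
                 noise_sigma: float = 0.05, non_native_fragment: int | None = 6,
                 basis: BasisSet | None = None, seed: int = 0,
                 ) -> SyntheticProtein:
    """A parent protein with planted structure plus its truncation library.

    Defaults mirror the scale of a helix-rich, 355-residue protein with 20
    helix segments, ~62% helix / 8% strand content, and nine nested
    truncation fragments, one of which (index ``non_native_fragment``) is
    structurally transformed and flagged non-native.
    """
    rng = np.random.default_rng(seed)
    h_tot = int(round(helix_fraction * n_residues))
    s_tot = int(round(strand_fraction * n_residues))
    if MIN_HELIX * n_helices > h_tot:
        raise ValueError(
            f"{n_helices} helices need >= {MIN_HELIX * n_helices} residues, "
            f"but helix content is {h_tot}"
        )
    if MIN_STRAND * n_strands > s_tot:
        raise ValueError(
            f"{n_strands} strands need >= {MIN_STRAND * n_strands} residues, "
            f"but strand content is {s_tot}"
        )
    basis = basis or make_basis(seed)
    labels = _place_segments(n_residues, n_helices, h_tot, n_strands, s_tot, rng)
    parent_map = ResidueMap(labels, distorted_from_labels(labels))
    sequence = _sample_sequence(labels, rng)
    fractions = _split_coil(fractions_from_map(parent_map))
    spec_vals = basis.matrix() @ fractions.as_array()
    spec_vals = spec_vals + rng.normal(0.0, noise_sigma, size=spec_vals.size)
    spectrum = Spectrum(CANONICAL_GRID.copy(), spec_vals, sample_id="parent",
                        units="delta_epsilon")

    fragments = []
    min_len = max(40, 2 * MIN_HELIX + 2)
    for k in range(n_fragments):
        if k % 2 == 0:   # N-terminally intact, C-terminally truncated
            start = 1
            end = int(rng.integers(min_len, n_residues - 10 + 1))
        else:            # C-terminally intact, N-terminally truncated
            start = int(rng.integers(11, n_residues - min_len + 2))
            end = n_residues
        native = (non_native_fragment is None) or (k != non_native_fragment)
        frag = FragmentDef(f"frag{k + 1:02d}", start, end, native_flag=native)
        if native:
            fmap = _fragment_map(labels, frag)
        else:
            # structural transformation on truncation: a fresh, unrelated
            # arrangement with altered content
            sub_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
            m = frag.n_residues
            fh = int(round(0.35 * m))
            fn = max(1, fh // 8)
            flabels = _place_segments(m, fn, max(fh, MIN_HELIX * fn), 0, 0, sub_rng)
            fmap = ResidueMap(flabels, distorted_from_labels(flabels))
        ffracs = _split_coil(fractions_from_map(fmap))
        fvals = basis.matrix() @ ffracs.as_array()
        fvals = fvals + rng.normal(0.0, noise_sigma, size=fvals.size)
        fspec = Spectrum(CANONICAL_GRID.copy(), fvals, sample_id=frag.id,
                         units="delta_epsilon")
        fragments.append(SyntheticFragment(
            frag, fmap, ffracs, fspec, sequence[frag.start - 1:frag.end]))
    return SyntheticProtein(sequence, parent_map, fractions, spectrum,
                            tuple(fragments), basis)


def make_melt_curve(tm: float, slope: float = 2.0, noise_sigma: float = 0.0,
                    seed: int = 0, baseline: float = 100.0,
                    amplitude: float = 1000.0, flat: bool = False,
                    sample_id: str = "melt") -> MeltCurve:
    """A thermofluor curve on the 25–99 °C grid at 0.5 °C steps.

    ``noise_sigma`` is relative to the transition amplitude.  ``flat=True``
    produces a transition-free curve (baseline plus noise only), emulating
    constructs without a defined melting point.
    """
    if not (25.0 < tm < 99.0):
        raise ValueError(f"tm {tm} outside the scanned range (25, 99) °C")
    t = np.arange(25.0, 99.0 + 0.25, 0.5)
    rng = np.random.default_rng(seed)
    if flat:
        f = np.full(t.size, baseline)
    else:
        f = boltzmann(t, baseline, amplitude, tm, slope)
    f = f + rng.normal(0.0, noise_sigma * amplitude, size=t.size)
    return MeltCurve(t, f, sample_id=sample_id)


def make_sec_standards(a: float = -0.04, b: float = 4.2, n: int = 6,
                       noise: float = 0.0, seed: int = 0,
                       v_range: tuple[float, float] = (45.0, 75.0),
                       ) -> list[tuple[float, float]]:
    """SEC calibration standards from log10(mass) = a·v_el + b plus Gaussian
    noise (in log10 mass units); returns (mass kDa, v_el) pairs."""
    rng = np.random.default_rng(seed)
    v = np.linspace(*v_range, n)
    logm = a * v + b + rng.normal(0.0, noise, size=n)
    return [(float(10.0 ** lm), float(ve)) for lm, ve in zip(logm, v)]


def write_fixture_tree(out_dir: str | Path, seed: int = 0,
                       noise_sigma: float = 0.05, **protein_kwargs) -> Path:
    """Write a complete, self-contained input tree for the pipeline:
    spectra, FASTA, fragment table, reference set, melt curves, SEC tables
    and a truth file recording the planted structure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    basis = make_basis(seed)
    refs = make_reference_set(31, basis, noise_sigma=min(noise_sigma, 0.05),
                              seed=seed + 1)
    protein = make_protein(basis=basis, seed=seed, noise_sigma=noise_sigma,
                           **protein_kwargs)

    refs.to_directory(out / "reference_set")
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    save_spectrum(protein.spectrum, spectra_dir / "parent.txt")
    for frag in protein.fragments:
        save_spectrum(frag.spectrum, spectra_dir / f"{frag.definition.id}.txt")

    with (out / "sequences.fasta").open("w") as fh:
        fh.write(">parent\n")
        fh.write(protein.sequence + "\n")
        for frag in protein.fragments:
            fh.write(f">{frag.definition.id}\n{frag.sequence}\n")

    with (out / "fragments.tsv").open("w") as fh:
        fh.write("id\tstart\tend\tnative_flag\n")
        for frag in protein.fragments:
            d = frag.definition
            fh.write(f"{d.id}\t{d.start}\t{d.end}\t{int(d.native_flag)}\n")

    melts_dir = out / "melt_curves"
    melts_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed + 2)
    melt_truth = {}
    for i, frag in enumerate(protein.fragments):
        fid = frag.definition.id
        flat = not frag.definition.native_flag
        tm = float(rng.uniform(45.0, 65.0))
        curve = make_melt_curve(tm, noise_sigma=0.01,
                                seed=int(rng.integers(0, 2 ** 31)),
                                flat=flat, sample_id=fid)
        melt_truth[fid] = None if flat else tm
        with (melts_dir / f"{fid}.tsv").open("w") as fh:
            fh.write("temperature\tfluorescence\n")
            for tt, ff in zip(curve.temperatures, curve.fluorescence):
                fh.write(f"{tt:.1f}\t{ff:.4f}\n")

    standards = make_sec_standards(noise=0.01, seed=seed + 3)
    with (out / "sec_standards.tsv").open("w") as fh:
        fh.write("mass_kda\tv_el\n")
        for mass, v in standards:
            fh.write(f"{mass:.3f}\t{v:.3f}\n")

    truth = {
        "seed": seed,
        "fractions": protein.fractions.as_dict(),
        "labels": "".join(protein.residue_map.labels.tolist()),
        "fragment_labels": {
            f.definition.id: "".join(f.residue_map.labels.tolist())
            for f in protein.fragments
        },
        "melt_tm": melt_truth,
    }
    with (out / "truth.json").open("w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out
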