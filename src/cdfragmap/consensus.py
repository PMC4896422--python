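"""Fragment-overlap consensus and difference spectroscopy.

A truncation library yields fragments whose interiors retain the parent
protein's native structure.  Each construct (parent and fragments) gets its
own per-residue map from the CD-driven localization stage; this module

* maps fragment results back onto parent coordinates, discarding a fixed
  number of edge residues (default 5) where truncation perturbs structure;
* combines parent and fragment maps by per-position majority vote (ties go
  to the parent) into a consensus map with a coverage track;
* computes region spectra by the length-weighted difference operator

      Δε_region(λ) = (Δε_parent·N_parent − Δε_frag·N_frag) / (N_parent − N_frag)

  which exactly inverts the length-weighted mixing of region contributions,
  so the spectrum of the residues present in the parent but absent from the
  fragment can be deconvolved on its own.  The operator is only meaningful
  when both constructs retain native structure; a warning is attached
  otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .deconvolution import (FitOptions, FractionSet, ReferenceSet,
                            fit_fractions)
from .localization import ResidueMap, distorted_from_labels
from .spectra import Spectrum

__all__ = [
    "FragmentDef",
    "PartialMap",
    "trim_edges",
    "consensus_map",
    "difference_spectrum",
    "region_fractions",
    "RegionFit",
    "load_fragment_table",
    "NonNativeFragmentWarning",
]

DEFAULT_EDGE_TRIM = 5


class NonNativeFragmentWarning(UserWarning):
    """Raised when a difference-spectrum comparison involves a construct
    whose native structure is not conserved."""


@dataclass(frozen=True)
class FragmentDef:
    """A truncation construct's span in 1-based inclusive parent coordinates.

    ``native_flag`` is False for constructs whose structure is transformed
    by truncation; such fragments are excluded from the consensus and make
    difference-spectrum comparisons invalid.
    """

    id: str
    start: int
    end: int
    native_flag: bool = True

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"fragment {self.id!r}: need 1 <= start <= end, got "
                f"[{self.start}, {self.end}]"
            )

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    def check_within(self, parent_length: int) -> None:
        if self.end > parent_length:
            raise ValueError(
                f"fragment {self.id!r} ends at {self.end}, beyond parent "
                f"length {parent_length}"
            )


@dataclass(frozen=True)
class PartialMap:
    """Labels on a contiguous window of parent coordinates.

    ``start`` is the 1-based parent position of ``labels[0]``; the window may
    be empty (tiny fragments trimmed away entirely).
    """

    start: int
    labels: np.ndarray

    def positions(self) -> np.ndarray:
        """1-based parent positions covered."""
        return np.arange(self.start, self.start + self.labels.size)


def trim_edges(residue_map: ResidueMap, frag: FragmentDef,
               trim: int = DEFAULT_EDGE_TRIM) -> PartialMap:
    """Place a fragment's map on parent coordinates, dropping ``trim``
    residues from each end (structure near truncation points is unreliable).

    An empty partial map is returned when the fragment is shorter than
    2·trim; that is not an error.
    """
    if trim < 0:
        raise ValueError(f"trim must be >= 0, got {trim}")
    if len(residue_map) != frag.n_residues:
        raise ValueError(
            f"fragment {frag.id!r} spans {frag.n_residues} residues but its "
            f"map has {len(residue_map)}"
        )
    labels = residue_map.labels[trim:frag.n_residues - trim]
    if labels.size == 0:
        labels = np.empty(0, dtype="<U1")
    return PartialMap(frag.start + trim, labels)


def consensus_map(parent: ResidueMap,
                  fragments: Sequence[tuple[FragmentDef, ResidueMap]],
                  trim: int = DEFAULT_EDGE_TRIM,
                  ) -> tuple[ResidueMap, np.ndarray]:
    """Majority-vote consensus of the parent map and trimmed fragment maps.

    Per position, the votes are the parent's label plus the labels of every
    covering, edge-trimmed fragment with ``native_flag`` True; the consensus
    is the majority label, with ties resolved in favour of the parent.
    Returns the consensus map and the per-position vote count (coverage).
    The distorted mask is recomputed from the consensus label runs.
    """
    n = len(parent)
    order = {"H": 0, "S": 1, "O": 2}
    votes = np.zeros((n, 3), dtype=int)
    for i, lab in enumerate(parent.labels):
        votes[i, order[str(lab)]] += 1
    coverage = np.ones(n, dtype=int)
    for frag, fmap in fragments:
        frag.check_within(n)
        if not frag.native_flag:
            continue
        partial = trim_edges(fmap, frag, trim)
        for pos, lab in zip(partial.positions(), partial.labels):
            votes[pos - 1, order[str(lab)]] += 1
            coverage[pos - 1] += 1
    inv = {v: k for k, v in order.items()}
    labels = np.empty(n, dtype="<U1")
    for i in range(n):
        parent_lab = str(parent.labels[i])
        top = votes[i].max()
        winners = [inv[c] for c in range(3) if votes[i, c] == top]
        labels[i] = parent_lab if parent_lab in winners else winners[0]
    return ResidueMap(labels, distorted_from_labels(labels)), coverage


def difference_spectrum(parent: Spectrum, n_parent: int,
                        frag: Spectrum, n_frag: int,
                        sample_id: str | None = None) -> Spectrum:
    """Length-weighted difference spectrum of the region present in the
    parent but absent from the fragment:

        (Δε_parent·N_parent − Δε_frag·N_frag) / (N_parent − N_frag)

    The result represents ``n_parent − n_frag`` residues and exactly inverts
    length-weighted mixing of region spectra.
    """
    if n_frag <= 0:
        raise ValueError("fragment residue count must be positive")
    if n_parent == n_frag:
        raise ValueError(
            "parent and fragment have equal residue counts; the difference "
            "operator divides by N_parent - N_frag"
        )
    if n_frag > n_parent:
        raise ValueError(
            f"fragment ({n_frag} aa) is larger than parent ({n_parent} aa)"
        )
    if not frag.on_grid(parent.wavelengths):
        raise ValueError("parent and fragment spectra are on different grids")
    if parent.units != frag.units:
        raise ValueError("parent and fragment spectra have different units")
    vals = (parent.values * n_parent - frag.values * n_frag) / (n_parent - n_frag)
    sid = sample_id or f"{parent.sample_id}-minus-{frag.sample_id}"
    return Spectrum(parent.wavelengths.copy(), vals, sample_id=sid,
                    units=parent.units)


@dataclass
class RegionFit:
    """Deconvolution of a difference-spectrum region."""

    spectrum: Spectrum
    fractions: FractionSet
    n_region: int
    valid: bool
    warnings: list[str]


def region_fractions(parent: Spectrum, n_parent: int,
                     frag: Spectrum, n_frag: int,
                     refs: ReferenceSet,
                     parent_native: bool = True,
                     frag_native: bool = True,
                     options: FitOptions | None = None) -> RegionFit:
    """Secondary-structure fractions of the region covered by the parent but
    not the fragment, via the difference spectrum.

    Conservation of native structure is required of both constructs; when
    either ``*_native`` flag is False the result is marked invalid and a
    :class:`NonNativeFragmentWarning` is emitted.
    """
    diff = difference_spectrum(parent, n_parent, frag, n_frag)
    fractions, _ = fit_fractions(diff, refs, options)
    notes = []
    for name, ok in (("parent", parent_native), ("fragment", frag_native)):
        if not ok:
            msg = (
                f"{name} construct does not conserve native structure; the "
                "difference-spectrum comparison is unreliable"
            )
            notes.append(msg)
            warnings.warn(msg, NonNativeFragmentWarning, stacklevel=2)
    return RegionFit(diff, fractions, n_parent - n_frag, not notes, notes)


def load_fragment_table(path: str | Path) -> list[FragmentDef]:
    """Read a fragment table TSV: columns id, start, end, native_flag."""
    frags = []
    with Path(path).open() as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if parts[0].lower() == "id":
                continue
            native = parts[3].strip().lower() in ("1", "true", "yes")
            frags.append(FragmentDef(parts[0], int(parts[1]), int(parts[2]), native))
    if not frags:
        raise ValueError(f"{path}: empty fragment table")
    return frags
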