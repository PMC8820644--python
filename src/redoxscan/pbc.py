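"""Minimum-image geometry for orthorhombic periodic boxes.

``box`` arguments accept a 3-vector of edge lengths (nm) or ``None`` for a
non-periodic system; all functions broadcast over leading axes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


def _box_lengths(box) -> Optional[np.ndarray]:
    if box is None:
        return None
    lengths = getattr(box, "lengths", box)
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape[-1] != 3:
        raise ValueError("box must supply three edge lengths")
    if not np.all(lengths > 0):
        raise ValueError("box lengths must be positive")
    return lengths


def min_image_displacement(a, b, box=None) -> np.ndarray:
    """Shortest periodic displacement a - b."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    lengths = _box_lengths(box)
    if lengths is not None:
        d = d - lengths * np.round(d / lengths)
    return d


def min_image_distance(a, b, box=None):
    """Euclidean distance under the minimum-image convention."""
    return np.linalg.norm(min_image_displacement(a, b, box), axis=-1)


def unwrap_group(coords: np.ndarray, box=None) -> np.ndarray:
    """Shift each atom by whole box vectors to sit nearest the first atom.

    Makes a molecule that straddles the boundary contiguous; the reference-atom
    strategy matches common trajectory tools.
    """
    coords = np.asarray(coords, dtype=float)
    if box is None:
        return coords.copy()
    ref = coords[0]
    return ref + min_image_displacement(coords, ref, box)


def wrap_point(p: np.ndarray, box=None) -> np.ndarray:
    lengths = _box_lengths(box)
    if lengths is None:
        return np.asarray(p, dtype=float)
    return np.mod(p, lengths)


def mass_weighted_com(coords: np.ndarray, masses: np.ndarray, box=None) -> np.ndarray:
    """Mass-weighted centre of mass of an atom set, unwrapped then re-wrapped.

    For a group split across the periodic boundary the atoms are first made
    contiguous around the first atom, so the COM lies within the molecule's
    unwrapped extent (e.g. equal masses at x=0.5 and x=9.5 in a 10 nm box
    give x=0, not x=5).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty atom set")
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    unwrapped = unwrap_group(coords, box)
    com = (unwrapped * masses[:, None]).sum(axis=0) / total
    return wrap_point(com, box)
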