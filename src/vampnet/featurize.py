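"""Input featurization: coordinate centering and residue contact maps.

Two featurizations are provided.  For low-dimensional inputs, per-series
mean removal (the instantaneous and lagged series are centred with their
own means).  For protein structures, the exponential contact map: for
each residue pair (i, j) the feature is exp(-d_ij) with d_ij the minimum
distance between heavy atoms of the two residues, a value in (0, 1] that
decays smoothly with separation.  Distances carry whatever unit the
coordinates use; nanometres are recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "StructureFrame",
    "center_coordinates",
    "enumerate_pairs",
    "contact_features",
    "contact_feature_matrix",
    "load_pdb_frames",
]

#: Residue pairs closer in sequence than this are considered redundant
#: (trivially in contact) and excluded.  With 3, a 39-residue chain yields
#: 666 features.
DEFAULT_MIN_SEPARATION = 3


def center_coordinates(
    frames: np.ndarray, lagged_frames: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Remove each series' own time mean.

    Returns ``(centered, centered_lagged, mean, mean_lagged)``; the means
    allow mapping centred values back.
    """
    a = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    b = np.atleast_2d(np.asarray(lagged_frames, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot center an empty series")
    if a.shape[1] != b.shape[1]:
        raise ValueError("series must share a dimension")
    mu1 = a.mean(axis=0)
    mu2 = b.mean(axis=0)
    return a - mu1, b - mu2, mu1, mu2


def enumerate_pairs(
    n_residues: int, min_separation: int = DEFAULT_MIN_SEPARATION
) -> list[tuple[int, int]]:
    """All residue pairs (i, j), 1-based, with i < j and j - i >= min_separation,
    in lexicographic order."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    return [
        (i, j)
        for i in range(1, n_residues + 1)
        for j in range(i + min_separation, n_residues + 1)
    ]


@dataclass
class StructureFrame:
    """Atom coordinates with residue labels and a heavy-atom mask.

    ``residue_index`` is 1-based and contiguous; ``heavy_mask`` defaults to
    all atoms (use it to exclude hydrogens).
    """

    coords: np.ndarray
    residue_index: np.ndarray
    heavy_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if self.residue_index.shape != (len(self.coords),):
            raise ValueError("one residue index per atom required")
        if self.heavy_mask is None:
            self.heavy_mask = np.ones(len(self.coords), dtype=bool)
        else:
            self.heavy_mask = np.asarray(self.heavy_mask, dtype=bool)
        present = np.unique(self.residue_index)
        if present.min(initial=1) < 1 or not np.array_equal(
            present, np.arange(present.min(), present.max() + 1)
        ):
            raise ValueError("residue indices must be 1-based and contiguous")

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max())

    def heavy_coords(self, residue: int) -> np.ndarray:
        sel = (self.residue_index == residue) & self.heavy_mask
        out = self.coords[sel]
        if len(out) == 0:
            raise ValueError(f"residue {residue} has no heavy atoms")
        return out


def contact_features(
    frame: StructureFrame, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Exponential contact map exp(-d_ij) over the given residue pairs.

    d_ij is the minimum Euclidean distance between heavy atoms of residues
    i and j; features are ordered as the pairs are.
    """
    per_res = {r: frame.heavy_coords(r) for r in {r for p in pairs for r in p}}
    feats = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        feats[k] = np.exp(-cdist(per_res[i], per_res[j]).min())
    return feats


def contact_feature_matrix(
    frames: list[StructureFrame], pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Stack contact features over frames into an (n_frames, n_pairs) array."""
    return np.array([contact_features(f, pairs) for f in frames])


def load_pdb_frames(path: str) -> list[StructureFrame]:
    """Read a PDB file (one model per frame) into StructureFrame objects.

    Heavy atoms are everything but hydrogen.  Residues are renumbered
    contiguously from 1 in order of first appearance.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure()  # AtomArrayStack: models x atoms
    frames = []
    for model in stack:
        res_ids = model.res_id
        _, contiguous = np.unique(res_ids, return_inverse=True)
        frames.append(
            StructureFrame(
                coords=np.asarray(model.coord, dtype=np.float64),
                residue_index=contiguous + 1,
                heavy_mask=model.element != "H",
            )
        )
    return frames
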