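"""Essential-dynamics conformational analysis.

The chromophore trajectory is first mass-weighted rigid-body fitted to a
reference structure, removing roto-translation.  Principal-component analysis
of the all-atom Cartesian covariance matrix then yields eigenvectors ranked
by mean-squared fluctuation; for flexible monosaccharide-like molecules the
motion concentrates in the first two ("the essential plane").  Projecting the
trajectory onto that plane gives an occupancy histogram, hence a Helmholtz
free-energy surface dA = -kB T ln(P/Pmax), whose basins define the
conformations from which representative reference configurations (RCs) are
extracted and weighted.

The hydroxymethyl rotamer convention used throughout: the designated
dihedral near 180 deg is GT, near 60 or 240 deg GG, near 0 deg TG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from . import units
from .electronic import ValidationError

__all__ = [
    "EssentialSpace",
    "FreeEnergyGrid",
    "ReferenceConfiguration",
    "fit_trajectory",
    "covariance_eigendecomposition",
    "free_energy_landscape",
    "dihedral_series",
    "classify_rotamer",
    "locate_basins_and_extract",
]

KB = units.KB_KJ_MOL_K


@dataclass
class EssentialSpace:
    """Covariance eigendecomposition of a fitted trajectory."""

    mean_structure: np.ndarray   # (3N,), nm
    eigenvalues: np.ndarray      # (3N,), nm^2, descending
    eigenvectors: np.ndarray     # (3N, 3N), columns orthonormal
    projections: np.ndarray      # (F, n_select), nm


@dataclass
class FreeEnergyGrid:
    """2D occupancy histogram and free-energy surface on the essential plane.

    ``free_energy`` is NaN on unsampled cells; ``sampled`` is the explicit
    mask.  ``dihedral_mean`` (circular mean, degrees) is NaN where unsampled
    or not requested.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray           # (nx, ny) ints
    free_energy: np.ndarray     # (nx, ny) kJ/mol, min exactly 0
    temperature: float           # K
    sampled: np.ndarray          # (nx, ny) bool
    dihedral_mean: np.ndarray | None = None

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
                0.5 * (self.y_edges[:-1] + self.y_edges[1:]))


@dataclass
class ReferenceConfiguration:
    """Representative chromophore structure extracted from one basin cell."""

    label: str
    coordinates: np.ndarray      # (N, 3), nm
    essential_coords: np.ndarray  # (2,), nm
    basin_id: int
    probability: float
    frame_index: int
    rotamer: str | None = None


# --------------------------------------------------------------------------
# fitting and PCA


def fit_trajectory(frames: np.ndarray,
                   masses: np.ndarray,
                   reference: np.ndarray) -> np.ndarray:
    """Mass-weighted rigid-body superposition of every frame on a reference.

    Each frame is translated and rotated to minimize the mass-weighted RMSD
    to ``reference`` (Kabsch optimal superposition); internal geometry is
    untouched.  ``frames`` is (F, N, 3), nm.
    """
    frames = np.asarray(frames, float)
    reference = np.asarray(reference, float)
    masses = np.asarray(masses, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValidationError("need at least 2 frames of shape (N, 3)")
    if frames.shape[1:] != reference.shape:
        raise ValidationError(
            f"atom count mismatch: frames {frames.shape[1]}, "
            f"reference {reference.shape[0]}")
    w = masses / masses.sum()
    ref_c = reference - w @ reference
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        x = frames[f]
        xc = x - w @ x
        rot, _ = Rotation.align_vectors(ref_c, xc, weights=masses)
        out[f] = rot.apply(xc) + w @ reference
    return out


def covariance_eigendecomposition(fitted: np.ndarray,
                                  n_select: int = 2) -> EssentialSpace:
    """PCA of the 3N Cartesian coordinates of a fitted trajectory."""
    fitted = np.asarray(fitted, float)
    F = fitted.shape[0]
    if F < 2:
        raise ValidationError("need at least 2 frames")
    X = fitted.reshape(F, -1)
    dof = X.shape[1]
    if not (1 <= n_select <= dof):
        raise ValidationError(f"n_select={n_select} outside 1..{dof}")
    mean = X.mean(axis=0)
    dX = X - mean
    cov = dX.T @ dX / F
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|.| component positive
    for k in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    proj = dX @ evecs[:, :n_select]
    return EssentialSpace(mean_structure=mean, eigenvalues=evals,
                          eigenvectors=evecs, projections=proj)


# --------------------------------------------------------------------------
# free-energy landscape


def free_energy_landscape(projections: np.ndarray,
                          bins: int | tuple[int, int] = 60,
                          temperature: float = 300.0,
                          dihedrals: np.ndarray | None = None,
                          pad_fraction: float = 0.05) -> FreeEnergyGrid:
    """Occupancy histogram on the essential plane -> dA = -kB T ln(P/Pmax).

    The grid spans the sampled range per axis, padded by ``pad_fraction``.
    The most populated cell defines the zero of free energy.  If a per-frame
    dihedral series (degrees) is supplied, its circular mean per cell is
    recorded alongside.
    """
    proj = np.asarray(projections, float)
    if proj.ndim != 2 or proj.shape[1] != 2:
        raise ValidationError("projections must be (n_frames, 2)")
    if proj.shape[0] == 0:
        raise ValidationError("empty projection set")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if isinstance(bins, int):
        bins = (bins, bins)
    edges = []
    for ax in range(2):
        lo, hi = proj[:, ax].min(), proj[:, ax].max()
        pad = (hi - lo) * pad_fraction or 1e-12
        edges.append(np.linspace(lo - pad, hi + pad, bins[ax] + 1))
    counts, xe, ye = np.histogram2d(proj[:, 0], proj[:, 1], bins=edges)
    counts = counts.astype(int)
    sampled = counts > 0
    dA = np.full(counts.shape, np.nan)
    cmax = counts.max()
    dA[sampled] = -KB * temperature * np.log(counts[sampled] / cmax)

    dmean = None
    if dihedrals is not None:
        dihedrals = np.asarray(dihedrals, float)
        ix = np.clip(np.digitize(proj[:, 0], xe) - 1, 0, counts.shape[0] - 1)
        iy = np.clip(np.digitize(proj[:, 1], ye) - 1, 0, counts.shape[1] - 1)
        rad = np.deg2rad(dihedrals)
        sin_acc = np.zeros(counts.shape)
        cos_acc = np.zeros(counts.shape)
        np.add.at(sin_acc, (ix, iy), np.sin(rad))
        np.add.at(cos_acc, (ix, iy), np.cos(rad))
        dmean = np.full(counts.shape, np.nan)
        dmean[sampled] = np.rad2deg(
            np.arctan2(sin_acc[sampled], cos_acc[sampled])) % 360.0
    return FreeEnergyGrid(x_edges=xe, y_edges=ye, counts=counts,
                          free_energy=dA, temperature=temperature,
                          sampled=sampled, dihedral_mean=dmean)


# --------------------------------------------------------------------------
# dihedrals and rotamers


def dihedral_series(frames: np.ndarray,
                    indices: tuple[int, int, int, int]) -> np.ndarray:
    """Signed dihedral i-j-k-l per frame, degrees in [0, 360).

    Standard convention: looking down the j-k bond, the angle from the
    i-j bond projection to the k-l bond projection, positive clockwise.
    """
    i, j, k, l = indices
    if len({i, j, k, l}) != 4:
        raise ValidationError("dihedral needs four distinct atom indices")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    b1 = frames[:, j] - frames[:, i]
    b2 = frames[:, k] - frames[:, j]
    b3 = frames[:, l] - frames[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    bad = (norm1 < 1e-12) | (norm2 < 1e-12)
    if np.any(bad):
        raise ValidationError(
            f"collinear atoms in dihedral at frame {int(np.argmax(bad))}")
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    deg = np.rad2deg(np.arctan2(y, x)) % 360.0
    deg[deg >= 360.0] = 0.0  # guard the -0.0 % 360 -> 360.0 edge
    return deg


#: rotamer class centers on the circle (degrees)
ROTAMER_CENTERS = {"TG": (0.0,), "GG": (60.0, 240.0), "GT": (180.0,)}
#: circular midpoints between adjacent centers
ROTAMER_BOUNDARIES = (30.0, 120.0, 210.0, 300.0)


def classify_rotamer(dihedral_deg: float) -> str:
    """Nearest-center rotamer class of a hydroxymethyl-type dihedral.

    Centers: TG at 0 deg, GG at 60 and 240 deg, GT at 180 deg; boundaries at
    the circular midpoints 30, 120, 210 and 300 deg.  Total on [0, 360).
    """
    d = float(dihedral_deg) % 360.0
    if d < 30.0 or d >= 300.0:
        return "TG"
    if d < 120.0:
        return "GG"
    if d < 210.0:
        return "GT"
    return "GG"


# --------------------------------------------------------------------------
# basin detection and RC extraction


def _label_basins(grid: FreeEnergyGrid, threshold: float) -> np.ndarray:
    """Watershed-by-persistence basin labels over sampled cells.

    Cells are flooded in order of increasing free energy; a cell touching no
    labelled 8-neighbor seeds a new basin (a local minimum), otherwise it
    joins the deepest adjacent basin.  When a cell bridges several basins,
    any basin whose depth below the bridge is less than ``threshold`` kJ/mol
    is merged into the deepest one — so every surviving basin is at least
    ``threshold`` deep.
    Returns an int array, -1 for unsampled cells.
    """
    dA = grid.free_energy
    labels = np.full(dA.shape, -1, int)
    minima: dict[int, float] = {}
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    order = np.argsort(dA[grid.sampled], kind="stable")
    cells = np.argwhere(grid.sampled)[order]
    nx, ny = dA.shape
    next_label = 0
    for cx, cy in cells:
        neigh = set()
        for ddx in (-1, 0, 1):
            for ddy in (-1, 0, 1):
                if ddx == ddy == 0:
                    continue
                ax, ay = cx + ddx, cy + ddy
                if 0 <= ax < nx and 0 <= ay < ny and labels[ax, ay] >= 0:
                    neigh.add(find(labels[ax, ay]))
        h = dA[cx, cy]
        if not neigh:
            labels[cx, cy] = next_label
            minima[next_label] = h
            parent[next_label] = next_label
            next_label += 1
            continue
        deepest = min(neigh, key=lambda b: (minima[b], b))
        labels[cx, cy] = deepest
        for b in neigh:
            if b != deepest and h - minima[b] < threshold:
                parent[b] = deepest
    # resolve merges
    out = np.full(dA.shape, -1, int)
    roots = sorted({find(b) for b in minima}, key=lambda b: minima[b])
    remap = {b: i for i, b in enumerate(roots)}
    for cx, cy in np.argwhere(labels >= 0):
        out[cx, cy] = remap[find(labels[cx, cy])]
    return out


def locate_basins_and_extract(grid: FreeEnergyGrid,
                              fitted_frames: np.ndarray,
                              projections: np.ndarray,
                              n_rc: int,
                              threshold: float = 3.0,
                              dihedrals: np.ndarray | None = None,
                              min_occupancy: float = 0.01,
                              ) -> list[ReferenceConfiguration]:
    """Extract reference configurations (RCs) from free-energy basins.

    Basins are watershed catchments around free-energy minima separated by
    ridges at least ``threshold`` kJ/mol high; catchments holding less than
    ``min_occupancy`` of the frames are treated as sampling noise, not
    conformations.  ``n_rc`` RCs are allocated to basins proportionally to
    occupancy (every basin gets at least one; a single RC may not describe a
    whole basin).  Within a basin, RC cells are its lowest-free-energy
    cells; each RC is the trajectory frame nearest (in the essential plane)
    to its cell center, and carries the occupancy of the basin cells nearest
    to it, renormalized over all RCs to sum to 1.  Probabilities are summed
    over each basin's full catchment, so they are unbiased estimates of the
    basin Boltzmann weights.
    """
    if not np.any(grid.sampled):
        raise ValidationError("free-energy grid has no sampled cells")
    labels = _label_basins(grid, threshold)
    # drop noise islands
    total_frames = grid.counts[grid.sampled].sum()
    for b in np.unique(labels):
        if b < 0:
            continue
        if grid.counts[labels == b].sum() < min_occupancy * total_frames:
            labels[labels == b] = -1
    basin_ids = [b for b in np.unique(labels) if b >= 0]
    if not basin_ids:
        raise ValidationError("no basin exceeds the minimum occupancy")
    n_basins = len(basin_ids)
    if n_rc < n_basins:
        raise ValidationError(
            f"n_rc={n_rc} < {n_basins} basins: every basin must be "
            "represented by at least one RC")

    occ = np.array([grid.counts[labels == b].sum() for b in basin_ids], float)
    # proportional allocation, each basin >= 1 (largest remainder)
    alloc = np.ones(n_basins, int)
    remaining = n_rc - n_basins
    if remaining > 0:
        quota = occ / occ.sum() * remaining
        alloc += quota.astype(int)
        frac = quota - quota.astype(int)
        for i in np.argsort(frac)[::-1][: n_rc - alloc.sum()]:
            alloc[i] += 1

    xc, yc = grid.cell_centers
    proj = np.asarray(projections, float)
    rcs: list[ReferenceConfiguration] = []
    for b, n_b in zip(basin_ids, alloc):
        cells = np.argwhere(labels == b)
        dA_cells = grid.free_energy[cells[:, 0], cells[:, 1]]
        pick = cells[np.argsort(dA_cells, kind="stable")[:n_b]]
        centers = np.column_stack([xc[pick[:, 0]], yc[pick[:, 1]]])
        # partition basin cells among this basin's RC cells by nearness
        cell_centers = np.column_stack([xc[cells[:, 0]], yc[cells[:, 1]]])
        nearest_rc = np.argmin(
            np.linalg.norm(cell_centers[:, None, :] - centers[None], axis=2),
            axis=1)
        cell_counts = grid.counts[cells[:, 0], cells[:, 1]]
        for r in range(len(pick)):
            frame = int(np.argmin(np.linalg.norm(proj - centers[r], axis=1)))
            rot = None
            if dihedrals is not None:
                rot = classify_rotamer(float(np.asarray(dihedrals)[frame]))
            rcs.append(ReferenceConfiguration(
                label=f"B{b}R{r}",
                coordinates=np.asarray(fitted_frames)[frame],
                essential_coords=centers[r],
                basin_id=int(b),
                probability=float(cell_counts[nearest_rc == r].sum()),
                frame_index=frame,
                rotamer=rot))
    total = sum(rc.probability for rc in rcs)
    for rc in rcs:
        rc.probability /= total
    return rcs
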