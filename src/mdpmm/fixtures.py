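"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators stand in for the external data the workflow consumes:

* :func:`mock_unperturbed_set` — a randomized but physically consistent
  gas-phase electronic set (ascending energies, symmetric electric-dipole
  matrices, purely imaginary antisymmetric magnetic-dipole matrices);
* :func:`mock_solvent_frames` — shells of neutral three-point charge groups
  emulating water around the quantum center (net charge zero per frame, so
  far-field behavior matches a polar solvent);
* :func:`mock_conformational_trajectory` — a small chain molecule with one
  soft torsion sampled from a mixture of von Mises basins at known weights,
  wrapped in random rigid-body motion, with true basin labels returned.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .electronic import UnperturbedSet, ValidationError
from .pmm import PerturbingFrame

__all__ = [
    "FixtureSpec",
    "mock_unperturbed_set",
    "mock_solvent_frames",
    "mock_conformational_trajectory",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system.

    Defaults emulate the aqueous-monosaccharide conditions the pipeline
    targets: 17 electronic states with the lowest vertical excitation near
    6.5 eV (so the UV onset sits just above 190 nm), 951 neutral water-like
    charge triplets in a first-shell region clear of the chromophore, and a
    two-basin torsional landscape with GG:GT = 60:40 weights at 300 K.
    """

    n_states: int = 17
    energy_range: tuple[float, float] = (6.5, 9.5)  # eV, excitation span
    dipole_scale: float = 0.5          # a.u., typical transition dipole
    n_env_charges: int = 951           # water-like neutral triplets per frame
    env_shell_radii: tuple[float, float] = (0.65, 1.3)  # nm
    n_frames: int = 100
    seed: int = 0
    basin_centers: tuple[float, ...] = (60.0, 180.0)   # deg (GG, GT)
    basin_kappas: tuple[float, ...] = (40.0, 40.0)     # von Mises widths
    basin_weights: tuple[float, ...] = (0.6, 0.4)
    temperature: float = 300.0

    def validate(self) -> "FixtureSpec":
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if not np.isclose(sum(self.basin_weights), 1.0):
            raise ValidationError("basin weights must sum to 1")
        if len(self.basin_centers) != len(self.basin_weights):
            raise ValidationError("one weight per basin center required")
        return self


# a light 10-atom chain used both as QC skeleton and as ED test molecule
_CHAIN_ELEMENTS = ["C", "C", "O", "C", "C", "O", "C", "O", "C", "O"]
_CHAIN_MASSES = np.array(
    [12.011, 12.011, 15.999, 12.011, 12.011, 15.999, 12.011, 15.999,
     12.011, 15.999])
_CHAIN_CHARGES = np.array(
    [0.15, 0.15, -0.4, 0.2, 0.2, -0.4, 0.15, -0.4, 0.15, 0.2])  # neutral
_BOND_NM = 0.15
_ANGLE_DEG = 111.0
#: atom quadruple whose torsion is the soft degree of freedom
SOFT_DIHEDRAL = (2, 3, 4, 5)


def mock_unperturbed_set(spec: FixtureSpec) -> UnperturbedSet:
    """Random electronic set passing all validation, seeded and reproducible."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    lo, hi = spec.energy_range
    exc_ev = np.sort(lo + (hi - lo) * rng.random(n - 1))
    exc_ev[0] = lo  # pin the onset at the stated floor
    energies = np.concatenate([[0.0], exc_ev]) / units.HARTREE_EV

    elec = np.empty((3, n, n))
    mag = np.empty((3, n, n), complex)
    for p in range(3):
        a = rng.normal(scale=spec.dipole_scale, size=(n, n))
        elec[p] = 0.5 * (a + a.T)
        b = rng.normal(scale=spec.dipole_scale, size=(n, n))
        mag[p] = 1j * 0.5 * (b - b.T)  # purely imaginary, antisymmetric

    qc_pos = _chain_geometry(np.full(len(_CHAIN_ELEMENTS) - 3, 180.0))
    return UnperturbedSet(
        state_energies=energies, elec_dipole=elec, mag_dipole=mag,
        qc_charges=_CHAIN_CHARGES, qc_masses=_CHAIN_MASSES,
        qc_positions=qc_pos, total_charge=float(_CHAIN_CHARGES.sum().round(6)),
        label=f"mock-{spec.seed}").validate()


def mock_solvent_frames(spec: FixtureSpec,
                        qc_positions: np.ndarray,
                        ) -> list[PerturbingFrame]:
    """Frames of neutral water-like charge triplets in a spherical shell.

    Each triplet is (-2q, +q, +q) with q = 0.41 e (SPC-like magnitudes),
    the two positive charges at symmetric offsets +/-d from the central one
    so the group is dipole-free: the frame is exactly neutral and its
    far-field potential decays as a quadrupole, while the randomized
    placement still produces solvent-scale field fluctuations at first-shell
    distances.  The shell is centered on the QC center of mass.
    """
    spec.validate()
    qc_positions = np.atleast_2d(np.asarray(qc_positions, float))
    r_in, r_out = spec.env_shell_radii
    w = _CHAIN_MASSES[: len(qc_positions)]
    com = (w / w.sum()) @ qc_positions
    extent = np.linalg.norm(qc_positions - com, axis=1).max()
    if r_in <= extent:
        raise ValidationError(
            f"shell inner radius {r_in} nm must exceed QC extent "
            f"{extent:.3f} nm")
    rng = np.random.default_rng(spec.seed + 1)
    q = 0.41
    frames = []
    for f in range(spec.n_frames):
        m = spec.n_env_charges
        if m == 0:
            frames.append(PerturbingFrame(
                env_positions=np.zeros((0, 3)), env_charges=np.zeros(0),
                qc_positions=qc_positions, frame_index=f))
            continue
        u = rng.random(m)
        radii = (r_in**3 + u * (r_out**3 - r_in**3)) ** (1.0 / 3.0)
        dirs = rng.normal(size=(m, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        centers = com + radii[:, None] * dirs
        offsets = rng.normal(scale=0.06, size=(m, 3))
        pos = np.concatenate(
            [centers, centers + offsets, centers - offsets])
        charges = np.concatenate(
            [np.full(m, -2 * q), np.full(m, q), np.full(m, q)])
        frames.append(PerturbingFrame(env_positions=pos, env_charges=charges,
                                      qc_positions=qc_positions,
                                      frame_index=f))
    return frames


def _chain_geometry(torsions_deg: np.ndarray) -> np.ndarray:
    """Cartesian chain from fixed bonds/angles and per-bond torsions.

    Atom i >= 3 is placed from atoms i-1, i-2, i-3 using bond length
    ``_BOND_NM``, bond angle ``_ANGLE_DEG`` and torsion ``torsions_deg[...,
    i-3]`` (natural extension of internal coordinates).  Accepts a single
    torsion vector (n_tor,) or a batch (F, n_tor); vectorized over frames.
    """
    torsions_deg = np.asarray(torsions_deg, float)
    single = torsions_deg.ndim == 1
    tors = np.atleast_2d(torsions_deg)
    F, n_tor = tors.shape
    n = n_tor + 3
    pos = np.zeros((F, n, 3))
    ang = np.deg2rad(_ANGLE_DEG)
    pos[:, 1] = [_BOND_NM, 0.0, 0.0]
    pos[:, 2] = pos[:, 1] + _BOND_NM * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(3, n):
        tor = np.deg2rad(tors[:, i - 3])
        b1 = pos[:, i - 2] - pos[:, i - 3]
        b2 = pos[:, i - 1] - pos[:, i - 2]
        b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
        nvec = np.cross(b1, b2)
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        mvec = np.cross(nvec, b2n)
        pos[:, i] = (pos[:, i - 1]
                     - _BOND_NM * np.cos(ang) * b2n
                     + (_BOND_NM * np.sin(ang) * np.cos(tor))[:, None] * mvec
                     + (_BOND_NM * np.sin(ang) * np.sin(tor))[:, None] * nvec)
    return pos[0] if single else pos


def mock_conformational_trajectory(spec: FixtureSpec
                                   ) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray, tuple[int, ...]]:
    """Two-basin chain trajectory with known per-frame state labels.

    Returns ``(frames, labels, masses, dihedral_indices)``: frames is
    (n_frames, n_atoms, 3) in nm with random rigid-body motion applied;
    labels[i] is the index of the basin the soft torsion of frame i was
    drawn from; the designated torsion is ``SOFT_DIHEDRAL``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    F = spec.n_frames
    n_tor = len(_CHAIN_ELEMENTS) - 3
    labels = rng.choice(len(spec.basin_weights), size=F,
                        p=np.asarray(spec.basin_weights))
    centers = np.asarray(spec.basin_centers)
    kappas = np.asarray(spec.basin_kappas)
    soft = np.rad2deg(rng.vonmises(np.deg2rad(centers[labels]),
                                   kappas[labels])) % 360.0
    soft_slot = SOFT_DIHEDRAL[3] - 3  # torsion slot placing the last atom
    torsions = 180.0 + rng.normal(scale=5.0, size=(F, n_tor))  # stiff jitter
    torsions[:, soft_slot] = soft
    frames = _chain_geometry(torsions)
    # random rigid motion to exercise the fitting step
    from scipy.spatial.transform import Rotation
    rots = Rotation.random(num=F, rng=rng)
    shifts = rng.normal(scale=0.5, size=(F, 3))
    frames = np.einsum("fij,faj->fai", rots.as_matrix(), frames) \
        + shifts[:, None, :]
    return frames, labels, _CHAIN_MASSES.copy(), SOFT_DIHEDRAL
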