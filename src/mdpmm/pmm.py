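"""Perturbed matrix method (PMM) engine.

Per MD frame, the environment point charges generate an electrostatic
potential V(r0) and field E(r0) at the quantum-center (QC) center of mass.
In the unperturbed eigenstate basis the multipolar perturbation, truncated at
dipole order, collapses exactly to

    H = H0 + q_tot * V(r0) * I - E(r0) . mu0

where H0 is diagonal (the unperturbed energies), q_tot the net molecular
charge and mu0 the electric-dipole matrices.  Diagonalizing H gives the
perturbed states; transition dipoles follow by rotating the unperturbed
dipole matrices with the eigenvectors, and the rotational strength of each
ground-to-k transition is R_k = Im{mu_0k . m_0k}.

All electronic quantities are in Hartree atomic units; coordinates enter in
nm and are converted internally.  Rotational strengths are returned in cgs
(erg esu cm / G), the convention the molar-CD prefactor expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import units
from .electronic import UnperturbedSet, ValidationError

__all__ = [
    "PerturbingFrame",
    "PerturbedRecord",
    "FrameClashError",
    "field_at_center",
    "build_perturbed_hamiltonian",
    "diagonalize",
    "perturbed_transition_dipoles",
    "rotational_strength",
    "process_frame",
    "process_trajectory",
]

logger = logging.getLogger(__name__)

#: environment points closer than this to the expansion center abort the frame
DEFAULT_MIN_DIST_NM = 0.05


class FrameClashError(RuntimeError):
    """An environment charge sits unphysically close to the expansion center."""


@dataclass
class PerturbingFrame:
    """One MD frame of the perturbing environment around the QC.

    Positions are nm, charges elementary charges.  ``qc_positions`` are the
    QC nuclear coordinates at this frame (for a frozen chromophore they equal
    the reference-conformation coordinates).
    """

    env_positions: np.ndarray
    env_charges: np.ndarray
    qc_positions: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.env_positions = np.atleast_2d(np.asarray(self.env_positions, float))
        self.env_charges = np.atleast_1d(np.asarray(self.env_charges, float))
        self.qc_positions = np.atleast_2d(np.asarray(self.qc_positions, float))
        if self.env_positions.shape[0] != self.env_charges.shape[0]:
            raise ValidationError(
                f"frame {self.frame_index}: {self.env_positions.shape[0]} "
                f"positions vs {self.env_charges.shape[0]} charges")


@dataclass
class PerturbedRecord:
    """Perturbed electronic properties of the QC at one frame."""

    frame_index: int
    eigenvalues: np.ndarray          # Hartree, ascending
    eigenvectors: np.ndarray         # columns = perturbed states
    excitation_freqs: np.ndarray     # E_k - E_0, Hartree, k = 1..n-1
    elec_tdm: np.ndarray             # (n-1, 3) complex, ground->k, a.u.
    mag_tdm: np.ndarray              # (n-1, 3) complex, ground->k, a.u.
    rot_strengths: np.ndarray        # (n-1,) cgs
    dipole_strengths: np.ndarray     # (n-1,) |mu_0k|^2, cgs
    v0: float                        # a.u. potential at r0
    efield: np.ndarray               # (3,) a.u.


def field_at_center(frame: PerturbingFrame,
                    masses: np.ndarray,
                    min_dist_nm: float = DEFAULT_MIN_DIST_NM,
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """Electrostatic potential and field at the QC center of mass.

    Returns ``(v0, efield, r0)`` with v0 and efield in atomic units and r0 in
    nm.  Direct O(N_env) Coulomb sum, no cutoff:

        V(r0) = sum_j q_j / |r_j - r0|
        E(r0) = sum_j q_j (r0 - r_j) / |r_j - r0|^3
    """
    masses = np.asarray(masses, float)
    if np.any(masses <= 0):
        raise ValidationError("masses must be positive")
    r0 = (masses / masses.sum()) @ frame.qc_positions  # nm
    if frame.env_charges.size == 0:
        return 0.0, np.zeros(3), r0
    d = frame.env_positions - r0  # nm
    dist_nm = np.linalg.norm(d, axis=1)
    if np.any(dist_nm < min_dist_nm):
        j = int(np.argmin(dist_nm))
        raise FrameClashError(
            f"frame {frame.frame_index}: environment charge {j} at "
            f"{dist_nm[j]:.4f} nm from QC center (min {min_dist_nm} nm)")
    dist = dist_nm * units.NM_TO_BOHR
    q = frame.env_charges
    v0 = float(np.sum(q / dist))
    efield = -(q / dist**3) @ (d * units.NM_TO_BOHR)
    return v0, efield, r0


def build_perturbed_hamiltonian(uset: UnperturbedSet,
                                v0: float,
                                efield: np.ndarray) -> np.ndarray:
    """Assemble H = diag(E0) + q_tot V(r0) I - E(r0).mu0 (Hermitian)."""
    efield = np.asarray(efield, float)
    H = np.diag(uset.state_energies + uset.total_charge * v0).astype(float)
    H -= np.einsum("p,pij->ij", efield, uset.elec_dipole)
    return H


def diagonalize(H: np.ndarray, herm_tol: float = 1e-10
                ) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with a deterministic phase convention.

    Eigenvalues ascending; each eigenvector is rescaled by a unit phase so
    that its largest-magnitude component is real and positive (ties resolved
    to the lowest index, which is what argmax gives).
    """
    H = np.asarray(H)
    scale = max(np.abs(H).max(), 1.0)
    if np.abs(H - H.conj().T).max() > herm_tol * scale:
        raise ValidationError("Hamiltonian is not Hermitian within tolerance")
    evals, evecs = np.linalg.eigh(H)
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        i = int(np.argmax(np.abs(col)))
        pivot = col[i]
        if np.abs(pivot) > 0:
            evecs[:, k] = col * (np.conj(pivot) / np.abs(pivot))
    return evals, evecs


def perturbed_transition_dipoles(uset: UnperturbedSet,
                                 eigenvectors: np.ndarray,
                                 i: int, j: int
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Electric and magnetic transition dipoles between perturbed states.

    For each Cartesian component p: mu_ij[p] = c_i^dag mu0_p c_j and
    m_ij[p] = c_i^dag m0_p c_j, with the phase-fixed eigenvectors.
    """
    n = uset.n_states
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"state indices ({i}, {j}) out of range for n={n}")
    ci = eigenvectors[:, i]
    cj = eigenvectors[:, j]
    mu = np.einsum("i,pij,j->p", ci.conj(), uset.elec_dipole, cj)
    m = np.einsum("i,pij,j->p", ci.conj(), uset.mag_dipole, cj)
    return mu, m


def rotational_strength(mu_0k: np.ndarray, m_0k: np.ndarray) -> float:
    """R_k = Im{mu_0k . m_0k}, converted from atomic units to cgs."""
    return float(np.imag(np.sum(np.asarray(mu_0k) * np.asarray(m_0k)))
                 ) * units.R_AU_CGS


def process_frame(uset: UnperturbedSet,
                  frame: PerturbingFrame,
                  min_dist_nm: float = DEFAULT_MIN_DIST_NM) -> PerturbedRecord:
    """Full PMM evaluation of one frame: field, H, eigenstates, R_k."""
    v0, efield, _ = field_at_center(frame, uset.qc_masses, min_dist_nm)
    H = build_perturbed_hamiltonian(uset, v0, efield)
    evals, evecs = diagonalize(H)
    n = uset.n_states
    exc = evals[1:] - evals[0]
    mus = np.empty((n - 1, 3), complex)
    ms = np.empty((n - 1, 3), complex)
    rs = np.empty(n - 1)
    ds = np.empty(n - 1)
    for k in range(1, n):
        mu, m = perturbed_transition_dipoles(uset, evecs, 0, k)
        mus[k - 1] = mu
        ms[k - 1] = m
        rs[k - 1] = rotational_strength(mu, m)
        ds[k - 1] = float(np.sum(np.abs(mu) ** 2)) * units.D_AU_CGS
    return PerturbedRecord(
        frame_index=frame.frame_index,
        eigenvalues=evals, eigenvectors=evecs, excitation_freqs=exc,
        elec_tdm=mus, mag_tdm=ms, rot_strengths=rs, dipole_strengths=ds,
        v0=v0, efield=efield)


def process_trajectory(uset: UnperturbedSet,
                       frames: Iterable[PerturbingFrame],
                       min_dist_nm: float = DEFAULT_MIN_DIST_NM,
                       permissive: bool = False,
                       log_every: int = 500,
                       ) -> Iterator[PerturbedRecord]:
    """Lazily yield one :class:`PerturbedRecord` per frame.

    Streaming: memory use is independent of trajectory length.  A per-frame
    failure aborts unless ``permissive`` is set, in which case the frame is
    logged and skipped (a corrupted trajectory should not silently thin out).
    """
    uset.validate()
    count = 0
    for frame in frames:
        try:
            rec = process_frame(uset, frame, min_dist_nm)
        except (FrameClashError, ValidationError) as exc:
            if not permissive:
                raise
            logger.warning("skipping frame %d: %s", frame.frame_index, exc)
            continue
        count += 1
        if log_every and count % log_every == 0:
            logger.info("processed %d frames", count)
        yield rec
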