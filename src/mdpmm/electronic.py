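"""Unperturbed electronic sets and conformer weight tables.

An :class:`UnperturbedSet` holds the gas-phase electronic structure of the
quantum center (QC) at one reference conformation: the unperturbed state
energies (eigenvalues of the isolated-molecule Hamiltonian) together with the
electric and magnetic transition-dipole matrices expressed in that eigenstate
basis, plus the QC nuclear charges, masses and coordinates.  These are the
ingredients the perturbed-matrix machinery mixes per MD frame.

The on-disk format is a JSON document with an explicit units header; energies
are converted to Hartree atomic units on load regardless of the units the file
declares, so downstream code never sees mixed conventions.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import units

__all__ = [
    "UnperturbedSet",
    "ConformerWeightTable",
    "WeightEntry",
    "SchemaError",
    "ValidationError",
    "load_unperturbed_set",
    "write_unperturbed_set",
    "normalize_weights",
    "load_weight_table",
    "load_packaged_weight_table",
    "load_packaged_anomer_ratio",
]

_SYM_TOL = 1e-8  # relative tolerance for dipole-matrix symmetry checks

_ENERGY_FACTORS = {"hartree": 1.0, "au": 1.0, "ev": 1.0 / units.HARTREE_EV,
                   "cm-1": 1.0 / units.HARTREE_CM1}
_LENGTH_FACTORS = {"nm": 1.0, "angstrom": units.ANGSTROM_NM,
                   "bohr": units.BOHR_NM}


class SchemaError(ValueError):
    """A required field is missing or malformed in an input file."""


class ValidationError(ValueError):
    """Numerically well-formed input that violates a physical invariant."""


@dataclass
class UnperturbedSet:
    """Gas-phase electronic structure of the quantum center.

    Attributes
    ----------
    state_energies : (n_states,) float array
        Unperturbed state energies in Hartree, ascending; index 0 is the
        ground state.
    elec_dipole : (3, n_states, n_states) float array
        Electric-dipole matrices (x, y, z components) in the unperturbed
        eigenstate basis, atomic units.  Real symmetric.
    mag_dipole : (3, n_states, n_states) complex array
        Magnetic-dipole matrices, atomic units.  Purely imaginary and
        antisymmetric (the Hermitian matrix of an imaginary operator in a
        real basis).
    qc_charges, qc_masses : (n_atoms,) float arrays
        Nuclear partial charges (e) and masses (amu).
    qc_positions : (n_atoms, 3) float array
        Nuclear coordinates, nm, at the conformation the set was computed at.
    total_charge : float
        Net molecular charge in elementary charges; multiplies the
        environment potential on the Hamiltonian diagonal.
    label : str
        Conformation identifier, e.g. ``"Alpha-Glu/A"``.
    """

    state_energies: np.ndarray
    elec_dipole: np.ndarray
    mag_dipole: np.ndarray
    qc_charges: np.ndarray
    qc_masses: np.ndarray
    qc_positions: np.ndarray
    total_charge: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.state_energies = np.asarray(self.state_energies, dtype=float)
        self.elec_dipole = np.asarray(self.elec_dipole, dtype=float)
        self.mag_dipole = np.asarray(self.mag_dipole, dtype=complex)
        self.qc_charges = np.asarray(self.qc_charges, dtype=float)
        self.qc_masses = np.asarray(self.qc_masses, dtype=float)
        self.qc_positions = np.asarray(self.qc_positions, dtype=float)

    @property
    def n_states(self) -> int:
        return self.state_energies.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.qc_charges.shape[0]

    def validate(self) -> "UnperturbedSet":
        n = self.n_states
        if n < 2:
            raise ValidationError("need at least 2 electronic states")
        if np.any(np.diff(self.state_energies) <= 0):
            raise ValidationError("state energies must be strictly ascending")
        for name, arr in (("elec_dipole", self.elec_dipole),
                          ("mag_dipole", self.mag_dipole)):
            if arr.shape != (3, n, n):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected (3, {n}, {n})")
        scale = max(np.abs(self.elec_dipole).max(), 1.0)
        for p in range(3):
            m = self.elec_dipole[p]
            if np.abs(m - m.T).max() > _SYM_TOL * scale:
                raise ValidationError(
                    f"elec_dipole[{'xyz'[p]}] not symmetric within tolerance")
        mscale = max(np.abs(self.mag_dipole).max(), 1.0)
        for p in range(3):
            m = self.mag_dipole[p]
            if np.abs(m.real).max() > _SYM_TOL * mscale:
                raise ValidationError(
                    f"mag_dipole[{'xyz'[p]}] must be purely imaginary")
            if np.abs(m + m.T).max() > _SYM_TOL * mscale:
                raise ValidationError(
                    f"mag_dipole[{'xyz'[p]}] not antisymmetric within tolerance")
        if not (self.qc_charges.shape == self.qc_masses.shape
                and self.qc_positions.shape == (self.n_atoms, 3)):
            raise ValidationError("QC charge/mass/position arrays inconsistent")
        if np.any(self.qc_masses <= 0):
            raise ValidationError("QC masses must be positive")
        return self

    def center_of_mass(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted mean position, nm."""
        pos = self.qc_positions if positions is None else np.asarray(positions)
        w = self.qc_masses / self.qc_masses.sum()
        return w @ pos


@dataclass(frozen=True)
class WeightEntry:
    label: str
    probability: float
    rotamer: str | None = None


@dataclass
class ConformerWeightTable:
    """Per-conformer probabilities plus the anomer mixing ratio."""

    entries: list[WeightEntry]
    anomer_ratio: tuple[float, float] = (1.0, 1.0)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([e.probability for e in self.entries])

    def rotamer_sums(self) -> dict[str, float]:
        """Sum of probabilities per rotamer label, un-renormalized."""
        out: dict[str, float] = {}
        for e in self.entries:
            key = e.rotamer or "?"
            out[key] = out.get(key, 0.0) + e.probability
        return out


def normalize_weights(table: ConformerWeightTable) -> ConformerWeightTable:
    """Renormalize conformer probabilities and the anomer ratio to sum to 1."""
    p = table.probabilities
    if np.any(p < 0):
        raise ValidationError("probabilities must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("at least one probability must be positive")
    entries = [replace(e, probability=e.probability / total)
               for e in table.entries]
    a, b = table.anomer_ratio
    s = a + b
    if s <= 0:
        raise ValidationError("anomer ratio must have positive sum")
    return ConformerWeightTable(entries=entries, anomer_ratio=(a / s, b / s))


# --------------------------------------------------------------------------
# serialization


def _require(doc: dict, key: str):
    if key not in doc:
        raise SchemaError(f"missing field '{key}' in unperturbed-set file")
    return doc[key]


def load_unperturbed_set(path: str | Path) -> UnperturbedSet:
    """Read and validate an unperturbed-set JSON file.

    The file's units header is honored on input; the returned object is in
    internal units (Hartree, atomic-unit dipoles, nm coordinates).
    """
    with open(path) as fh:
        doc = json.load(fh)
    n = int(_require(doc, "n_states"))
    u = _require(doc, "units")
    e_unit = str(u.get("energy", "hartree")).lower()
    l_unit = str(u.get("length", "nm")).lower()
    if e_unit not in _ENERGY_FACTORS:
        raise SchemaError(f"unknown energy unit '{e_unit}'")
    if l_unit not in _LENGTH_FACTORS:
        raise SchemaError(f"unknown length unit '{l_unit}'")

    energies = np.asarray(_require(doc, "energies"), float) * _ENERGY_FACTORS[e_unit]
    if energies.shape != (n,):
        raise ValidationError(
            f"energies has length {energies.shape[0]}, expected n_states={n}")

    ed = _require(doc, "elec_dipole")
    md = _require(doc, "mag_dipole")
    elec = np.empty((3, n, n))
    mag = np.empty((3, n, n), complex)
    for p, ax in enumerate("xyz"):
        m = np.asarray(_require(ed, ax), float)
        if m.shape != (n, n):
            raise ValidationError(
                f"elec_dipole {ax}-matrix has shape {m.shape}, expected ({n}, {n})")
        elec[p] = m
        raw = np.asarray(_require(md, ax), float)
        if raw.shape != (n, n, 2):
            raise ValidationError(
                f"mag_dipole {ax}-matrix has shape {raw.shape}, "
                f"expected ({n}, {n}, 2) [re,im] pairs")
        mag[p] = raw[..., 0] + 1j * raw[..., 1]

    qc = _require(doc, "qc")
    out = UnperturbedSet(
        state_energies=energies,
        elec_dipole=elec,
        mag_dipole=mag,
        qc_charges=np.asarray(_require(qc, "charges"), float),
        qc_masses=np.asarray(_require(qc, "masses"), float),
        qc_positions=np.asarray(_require(qc, "positions"), float)
        * _LENGTH_FACTORS[l_unit],
        total_charge=float(_require(doc, "total_charge")),
        label=str(doc.get("label", "")),
    )
    return out.validate()


def write_unperturbed_set(uset: UnperturbedSet, path: str | Path) -> None:
    """Write an unperturbed set in internal units (round-trips bit-exactly)."""
    doc = {
        "n_states": uset.n_states,
        "units": {"energy": "hartree", "dipole": "au", "length": "nm"},
        "energies": uset.state_energies.tolist(),
        "elec_dipole": {ax: uset.elec_dipole[p].tolist()
                        for p, ax in enumerate("xyz")},
        "mag_dipole": {ax: np.stack([uset.mag_dipole[p].real,
                                     uset.mag_dipole[p].imag], axis=-1).tolist()
                       for p, ax in enumerate("xyz")},
        "qc": {"charges": uset.qc_charges.tolist(),
               "masses": uset.qc_masses.tolist(),
               "positions": uset.qc_positions.tolist()},
        "total_charge": uset.total_charge,
        "label": uset.label,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_weight_table(path: str | Path,
                      anomer_ratio: Sequence[float] = (1.0, 1.0),
                      ) -> ConformerWeightTable:
    """Read a delimited weight table: ``label [rotamer] probability`` rows.

    Lines starting with ``#`` are comments.  The rotamer column is optional.
    """
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 2:
            label, rot, prob = parts[0], None, parts[1]
        elif len(parts) == 3:
            label, rot, prob = parts
        else:
            raise SchemaError(f"bad weight-table row: {line!r}")
        entries.append(WeightEntry(label, float(prob), rot))
    if not entries:
        raise SchemaError(f"empty weight table: {path}")
    return ConformerWeightTable(entries=entries,
                                anomer_ratio=(float(anomer_ratio[0]),
                                              float(anomer_ratio[1])))


_PACKAGED = {
    ("glucose", "alpha"): "glucose_alpha_rc_weights.tsv",
    ("glucose", "beta"): "glucose_beta_rc_weights.tsv",
    ("galactose", "alpha"): "galactose_alpha_rc_weights.tsv",
    ("galactose", "beta"): "galactose_beta_rc_weights.tsv",
}


def load_packaged_weight_table(sugar: str, anomer: str) -> ConformerWeightTable:
    """Load one of the shipped monosaccharide RC probability tables."""
    try:
        name = _PACKAGED[(sugar.lower(), anomer.lower())]
    except KeyError:
        raise KeyError(f"no packaged table for {sugar}/{anomer}") from None
    ref = importlib.resources.files("mdpmm").joinpath("data", name)
    with importlib.resources.as_file(ref) as p:
        table = load_weight_table(p)
    table.anomer_ratio = load_packaged_anomer_ratio(sugar)
    return table


def load_packaged_anomer_ratio(sugar: str) -> tuple[float, float]:
    """Experimental (alpha, beta) population ratio for a shipped sugar."""
    ref = importlib.resources.files("mdpmm").joinpath("data", "anomer_ratios.tsv")
    with importlib.resources.as_file(ref) as p:
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, a, b = line.split()
            if name == sugar.lower():
                return (float(a), float(b))
    raise KeyError(f"no anomer ratio for '{sugar}'")
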