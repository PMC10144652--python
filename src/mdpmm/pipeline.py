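"""File-based orchestration of the full workflow.

Stages mirror the computational procedure: conformational (essential
dynamics) analysis of the free chromophore trajectory -> extraction of
weighted reference configurations -> per-frame PMM over the solvated
(frozen-chromophore) trajectory of each reference configuration -> binned,
broadened per-conformer spectra -> probability-weighted conformer sum ->
anomer mixing.  Every stage reads and writes plain-text files so stages can
be rerun independently; all outputs carry a provenance header (tool version,
config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import yaml

from . import __version__, units
from . import ed as ed_mod
from . import fixtures as fx
from . import io as trj_io
from . import pmm as pmm_mod
from . import spectra as sp
from .electronic import (ConformerWeightTable, SchemaError, ValidationError,
                         load_unperturbed_set, load_weight_table,
                         normalize_weights, write_unperturbed_set)

__all__ = ["RunConfig", "run_fixtures", "run_ed", "run_pmm", "run_spectrum",
           "run_all"]

_MASS_TABLE = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "S": 32.06, "P": 30.974}


@dataclass
class RunConfig:
    """Flat key-value run configuration (YAML on disk, flags override)."""

    outdir: str = "mdpmm_out"
    seed: int = 0
    # fixture generation
    n_states: int = 17
    n_md_frames: int = 2000       # chromophore sampling frames
    n_env_frames: int = 200       # solvent frames per reference configuration
    n_env_charges: int = 951
    # ED / landscape
    n_rc: int = 4
    bins: int = 60
    temperature: float = 300.0
    basin_threshold: float = 3.0
    min_basin_occupancy: float = 0.01
    # spectra
    bin_width: float = 200.0      # cm^-1
    sigma: float = 0.15 * units.EV_TO_CM1  # cm^-1 (0.15 eV)
    grid_lo_nm: float = 120.0
    grid_hi_nm: float = 260.0
    grid_points: int = 600
    window_lo_nm: float = 160.0
    window_hi_nm: float = 220.0
    k_max: int = 0                # 0 = all excited states
    intensity_floor: float = 1.0  # M^-1 cm^-1, per-transition report
    # explicit inputs (filled by run_fixtures if absent)
    chromophore_trajectory: str = ""
    env_trajectory: str = ""
    unperturbed_set: str = ""
    weight_table: str = ""
    anomer_ratio: tuple[float, float] = (32.0, 68.0)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise SchemaError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**doc)
        if isinstance(cfg.anomer_ratio, list):
            cfg.anomer_ratio = tuple(cfg.anomer_ratio)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return (f"# mdpmm {__version__} config={self.config_hash()} "
                f"seed={self.seed}\n")

    def grid(self) -> np.ndarray:
        lo = units.nm_to_cm1(self.grid_hi_nm)
        hi = units.nm_to_cm1(self.grid_lo_nm)
        return np.linspace(lo, hi, self.grid_points)


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _masses_for(elements: list[str]) -> np.ndarray:
    try:
        return np.array([_MASS_TABLE[e] for e in elements])
    except KeyError as exc:
        raise SchemaError(f"no mass for element {exc.args[0]!r}") from None


# --------------------------------------------------------------------------


def run_fixtures(cfg: RunConfig) -> dict[str, Path]:
    """Generate synthetic inputs on disk (exercising the real file formats)."""
    out = _outdir(cfg)
    spec = fx.FixtureSpec(n_states=cfg.n_states, seed=cfg.seed,
                          n_frames=cfg.n_md_frames,
                          n_env_charges=cfg.n_env_charges,
                          temperature=cfg.temperature)
    uset = fx.mock_unperturbed_set(spec)
    uset_path = out / "unperturbed_set.json"
    write_unperturbed_set(uset, uset_path)

    frames, _, masses, _ = fx.mock_conformational_trajectory(spec)
    chromo_path = out / "chromophore.xyz"
    trj_io.write_xyz_frames(chromo_path, fx._CHAIN_ELEMENTS, frames,
                            fx._CHAIN_CHARGES)

    env_spec = fx.FixtureSpec(n_states=cfg.n_states, seed=cfg.seed,
                              n_frames=cfg.n_env_frames,
                              n_env_charges=cfg.n_env_charges)
    env_frames = fx.mock_solvent_frames(env_spec, uset.qc_positions)
    env_path = out / "environment.xyz"
    n_env = env_frames[0].env_positions.shape[0]
    trj_io.write_xyz_frames(
        env_path, ["X"] * n_env,
        np.stack([f.env_positions for f in env_frames]),
        env_frames[0].env_charges)
    qc_path = out / "qc_frozen.xyz"
    trj_io.write_xyz_frames(qc_path, fx._CHAIN_ELEMENTS,
                            uset.qc_positions[None], fx._CHAIN_CHARGES)

    cfg.chromophore_trajectory = str(chromo_path)
    cfg.env_trajectory = str(env_path)
    cfg.unperturbed_set = str(uset_path)
    return {"unperturbed_set": uset_path, "chromophore": chromo_path,
            "environment": env_path, "qc_frozen": qc_path}


def run_ed(cfg: RunConfig) -> dict[str, Path]:
    """ED analysis: eigenvalue spectrum, free-energy grid, RC extraction."""
    out = _outdir(cfg)
    blocks = list(trj_io.read_xyz_frames(cfg.chromophore_trajectory))
    if len(blocks) < 2:
        raise ValidationError("ED analysis needs at least 2 frames")
    elements = blocks[0][0]
    frames = np.stack([b[1] for b in blocks])
    masses = _masses_for(elements)

    fitted = ed_mod.fit_trajectory(frames, masses, frames[0])
    space = ed_mod.covariance_eigendecomposition(fitted, n_select=2)
    dihedrals = ed_mod.dihedral_series(fitted, fx.SOFT_DIHEDRAL)
    grid = ed_mod.free_energy_landscape(space.projections, bins=cfg.bins,
                                        temperature=cfg.temperature,
                                        dihedrals=dihedrals)
    rcs = ed_mod.locate_basins_and_extract(grid, fitted, space.projections,
                                           n_rc=cfg.n_rc,
                                           threshold=cfg.basin_threshold,
                                           dihedrals=dihedrals,
                                           min_occupancy=cfg.min_basin_occupancy)

    eig_path = out / "ed_eigenvalues.tsv"
    with open(eig_path, "w") as fh:
        fh.write(cfg.header())
        fh.write("index\teigenvalue_nm2\n")
        for i, ev in enumerate(space.eigenvalues):
            fh.write(f"{i}\t{ev:.10e}\n")

    grid_path = out / "free_energy_grid.tsv"
    xc, yc = grid.cell_centers
    with open(grid_path, "w") as fh:
        fh.write(cfg.header())
        fh.write(f"# temperature_K={grid.temperature}\n")
        fh.write("x_nm\ty_nm\tcounts\tfree_energy_kJ_mol\tdihedral_mean_deg\n")
        for i in range(len(xc)):
            for j in range(len(yc)):
                da = (f"{grid.free_energy[i, j]:.6f}"
                      if grid.sampled[i, j] else "unsampled")
                dm = (f"{grid.dihedral_mean[i, j]:.2f}"
                      if grid.sampled[i, j] else "unsampled")
                fh.write(f"{xc[i]:.6f}\t{yc[j]:.6f}\t{grid.counts[i, j]}"
                         f"\t{da}\t{dm}\n")

    rc_path = out / "rc_coordinates.xyz"
    trj_io.write_xyz_frames(rc_path, elements,
                            np.stack([rc.coordinates for rc in rcs]),
                            np.zeros(len(elements)),
                            extra_comment="stage=rc")
    weights_path = out / "rc_weights.tsv"
    with open(weights_path, "w") as fh:
        fh.write(cfg.header())
        fh.write("# label\trotamer\tprobability\n")
        for rc in rcs:
            fh.write(f"{rc.label}\t{rc.rotamer or '?'}\t"
                     f"{rc.probability:.6f}\n")
    cfg.weight_table = str(weights_path)
    return {"eigenvalues": eig_path, "grid": grid_path,
            "rc_coordinates": rc_path, "rc_weights": weights_path}


def run_pmm(cfg: RunConfig, rc_label: str = "RC") -> Path:
    """Per-frame PMM over the environment trajectory -> record table."""
    out = _outdir(cfg)
    if not Path(cfg.unperturbed_set).exists():
        raise SchemaError(
            f"missing unperturbed-set file for {rc_label}: "
            f"{cfg.unperturbed_set!r}")
    uset = load_unperturbed_set(cfg.unperturbed_set)

    # the chromophore is frozen at the unperturbed-set geometry during the
    # constrained solvent-sampling run, so the QC coordinates come from there
    def frame_iter():
        for i, (_, pos, chg) in enumerate(
                trj_io.read_xyz_frames(cfg.env_trajectory)):
            yield pmm_mod.PerturbingFrame(env_positions=pos, env_charges=chg,
                                          qc_positions=uset.qc_positions,
                                          frame_index=i)

    rec_path = out / f"records_{rc_label}.tsv"
    with open(rec_path, "w") as fh:
        fh.write(cfg.header())
        fh.write("frame\tk\texcitation_cm1\tR_cgs\tD_cgs\n")
        for rec in pmm_mod.process_trajectory(uset, frame_iter()):
            for k, (nu, R, D) in enumerate(
                    zip(rec.excitation_freqs * units.HARTREE_CM1,
                        rec.rot_strengths, rec.dipole_strengths), start=1):
                fh.write(f"{rec.frame_index}\t{k}\t{nu:.6f}\t{R:.10e}"
                         f"\t{D:.10e}\n")
    return rec_path


def _records_from_table(path: str | Path):
    """Rebuild minimal per-frame records from a record TSV."""
    rows = np.loadtxt(path, skiprows=2)
    if rows.ndim == 1:
        rows = rows[None]
    for f in np.unique(rows[:, 0]):
        sel = rows[rows[:, 0] == f]
        order = np.argsort(sel[:, 1])
        sel = sel[order]
        yield SimpleNamespace(
            frame_index=int(f),
            excitation_freqs=sel[:, 2] / units.HARTREE_CM1,
            rot_strengths=sel[:, 3],
            dipole_strengths=sel[:, 4])


def _write_curve(path: Path, curve: sp.SpectrumCurve, cfg: RunConfig) -> None:
    col = "delta_epsilon" if curve.kind == "cd" else "epsilon"
    with open(path, "w") as fh:
        fh.write(cfg.header())
        fh.write(f"wavelength_nm\tfrequency_cm1\t{col}\n")
        for lam, nu, v in zip(curve.wavelength_nm, curve.grid, curve.values):
            fh.write(f"{lam:.4f}\t{nu:.4f}\t{v:.8e}\n")


def run_spectrum(cfg: RunConfig,
                 record_tables: dict[str, Path] | None = None
                 ) -> dict[str, Path]:
    """Per-RC spectra, weighted conformer sum and anomer mixing."""
    out = _outdir(cfg)
    if record_tables is None:
        found = sorted(out.glob("records_*.tsv"))
        if not found:
            raise SchemaError(f"no record tables under {out}")
        record_tables = {p.stem.removeprefix("records_"): p for p in found}

    table = load_weight_table(cfg.weight_table, cfg.anomer_ratio) \
        if cfg.weight_table else ConformerWeightTable(
            entries=[], anomer_ratio=cfg.anomer_ratio)
    if table.entries:
        weights = {e.label: e.probability for e in
                   normalize_weights(table).entries}
    else:
        weights = {lab: 1.0 / len(record_tables) for lab in record_tables}
    missing = [lab for lab in record_tables if lab not in weights]
    if missing:
        raise SchemaError(
            f"no weight-table entry for record table(s): {missing}")

    grid = cfg.grid()
    k_max = cfg.k_max or None
    outputs: dict[str, Path] = {}
    curves, ws = [], []
    for lab, rec_path in record_tables.items():
        bt_cd = sp.bin_transitions(_records_from_table(rec_path),
                                   cfg.bin_width, k_max, "R")
        bt_uv = sp.bin_transitions(_records_from_table(rec_path),
                                   cfg.bin_width, k_max, "D")
        cd = sp.cd_curve(bt_cd, cfg.sigma, grid, label=lab)
        uv = sp.uv_curve(bt_uv, cfg.sigma, grid, label=lab)
        p_cd = out / f"cd_{lab}.tsv"
        p_uv = out / f"uv_{lab}.tsv"
        _write_curve(p_cd, sp.wavelength_window(cd, cfg.window_lo_nm,
                                                cfg.window_hi_nm), cfg)
        _write_curve(p_uv, sp.wavelength_window(uv, cfg.window_lo_nm,
                                                cfg.window_hi_nm), cfg)
        outputs[f"cd_{lab}"] = p_cd
        outputs[f"uv_{lab}"] = p_uv
        curves.append(cd)
        ws.append(weights[lab])

    combined = sp.combine_spectra(curves, np.asarray(ws) / np.sum(ws),
                                  label="conformer-weighted")
    windowed = sp.wavelength_window(combined, cfg.window_lo_nm,
                                    cfg.window_hi_nm)
    p_comb = out / "cd_combined.tsv"
    _write_curve(p_comb, windowed, cfg)
    outputs["cd_combined"] = p_comb

    report_path = out / "transition_weights.tsv"
    with open(report_path, "w") as fh:
        fh.write(cfg.header())
        fh.write(f"# per-transition max |intensity| above "
                 f"{cfg.intensity_floor} M^-1 cm^-1, window "
                 f"{cfg.window_lo_nm}-{cfg.window_hi_nm} nm\n")
        fh.write("conformer\ttransition\tmax_intensity\n")
        for curve in curves:
            wcurve = sp.wavelength_window(curve, cfg.window_lo_nm,
                                          cfg.window_hi_nm)
            for k, peak in sp.transition_weight_report(
                    wcurve, cfg.intensity_floor):
                fh.write(f"{curve.label}\t{k}\t{peak:.6f}\n")
    outputs["transition_weights"] = report_path
    return outputs


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Fixtures -> ED -> per-RC PMM -> spectra, sharing one config."""
    outputs = dict(run_fixtures(cfg))
    outputs.update(run_ed(cfg))
    rc_weights = load_weight_table(cfg.weight_table, cfg.anomer_ratio)
    tables: dict[str, Path] = {}
    for i, entry in enumerate(rc_weights.entries):
        # each RC gets its own solvent sampling, deterministically seeded
        sub = RunConfig(**asdict(cfg))
        sub.seed = cfg.seed + 1000 + i
        env = fx.mock_solvent_frames(
            fx.FixtureSpec(n_states=cfg.n_states, seed=sub.seed,
                           n_frames=cfg.n_env_frames,
                           n_env_charges=cfg.n_env_charges),
            load_unperturbed_set(cfg.unperturbed_set).qc_positions)
        env_path = Path(cfg.outdir) / f"environment_{entry.label}.xyz"
        trj_io.write_xyz_frames(
            env_path, ["X"] * env[0].env_positions.shape[0],
            np.stack([f.env_positions for f in env]), env[0].env_charges)
        sub.env_trajectory = str(env_path)
        tables[entry.label] = run_pmm(sub, rc_label=entry.label)
    outputs.update(run_spectrum(cfg, tables))
    return outputs
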