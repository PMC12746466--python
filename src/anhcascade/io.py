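"""File formats: system JSON, spectra/configs/matrices as TSV, spectral
matrices as HDF5, geometries as XYZ, normal modes as JSON.

Every writer/reader pair round-trips the in-memory object to full precision;
text outputs carry a comment header naming units and conventions.  HDF5
datasets are written with ``track_times=False`` so that reruns of a seeded
pipeline are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .initial_conditions import Geometry, NormalModeSet
from .muca_sampler import SpectralMatrix
from .vib_model import Spectrum, VibrationalSystem

__all__ = [
    "write_system_json", "read_system_json",
    "write_spectrum_tsv", "read_spectrum_tsv",
    "write_configs_tsv", "read_configs_tsv",
    "write_matrix_h5", "read_matrix_h5",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_xyz", "read_xyz",
    "write_modes_json", "read_modes_json",
]


# ---------------------------------------------------------------- systems

def write_system_json(system: VibrationalSystem, path: str | Path) -> None:
    doc = {
        "frequencies_cm1": system.frequencies.tolist(),
        "x_matrix_cm1": system.x_matrix.tolist(),
        "intensities_fund": system.intensities_fund.tolist(),
        "freq_scale": system.freq_scale,
    }
    if system.intensities_overtone is not None:
        doc["intensities_overtone"] = system.intensities_overtone.tolist()
    if system.intensities_comb is not None:
        doc["intensities_comb"] = system.intensities_comb.tolist()
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_system_json(path: str | Path) -> VibrationalSystem:
    doc = json.loads(Path(path).read_text())
    return VibrationalSystem(
        frequencies=np.array(doc["frequencies_cm1"], dtype=float),
        x_matrix=np.array(doc["x_matrix_cm1"], dtype=float),
        intensities_fund=np.array(doc["intensities_fund"], dtype=float),
        intensities_overtone=(
            np.array(doc["intensities_overtone"], dtype=float)
            if "intensities_overtone" in doc else None
        ),
        intensities_comb=(
            np.array(doc["intensities_comb"], dtype=float)
            if "intensities_comb" in doc else None
        ),
        freq_scale=float(doc.get("freq_scale", 1.0)),
    )


# ---------------------------------------------------------------- spectra

def write_spectrum_tsv(
    spectrum: Spectrum, path: str | Path, comment: str = ""
) -> None:
    lines = ["# wavenumber_cm1\tintensity"]
    if comment:
        lines.insert(0, f"# {comment}")
    for g, v in zip(spectrum.grid, spectrum.values):
        lines.append(f"{g:.10g}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_tsv(path: str | Path) -> Spectrum:
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    return Spectrum(data[:, 0], data[:, 1])


# ---------------------------------------------------------------- configs

def write_configs_tsv(configs: list[np.ndarray], path: str | Path) -> None:
    lines = ["# occupation configurations; one row per configuration"]
    for c in configs:
        lines.append("\t".join(str(int(v)) for v in c))
    Path(path).write_text("\n".join(lines) + "\n")


def read_configs_tsv(path: str | Path) -> list[np.ndarray]:
    data = np.loadtxt(path, comments="#", dtype=int, ndmin=2)
    return [row for row in data]


# ------------------------------------------------------- spectral matrices

def write_matrix_h5(matrix: SpectralMatrix, path: str | Path, meta: dict | None = None) -> None:
    with h5py.File(path, "w", track_order=False) as fh:
        for name, arr in (
            ("row_axis", matrix.row_axis),
            ("col_axis", matrix.col_axis),
            ("values", matrix.values),
            ("samples", np.asarray(matrix.samples, dtype=np.int64)),
        ):
            fh.create_dataset(name, data=arr, track_times=False)
        if meta:
            for key, val in sorted(meta.items()):
                fh.attrs[key] = val


def read_matrix_h5(path: str | Path) -> SpectralMatrix:
    with h5py.File(path, "r") as fh:
        return SpectralMatrix(
            row_axis=fh["row_axis"][()],
            col_axis=fh["col_axis"][()],
            values=fh["values"][()],
            samples=fh["samples"][()],
        )


def write_matrix_tsv(matrix: SpectralMatrix, path: str | Path) -> None:
    """Time/energy x wavenumber matrix: first row = wavenumber axis, first
    column = row axis (the transient-spectra exchange format)."""
    with open(path, "w") as fh:
        fh.write("# rows: time (fs) or energy (cm^-1); cols: wavenumber (cm^-1)\n")
        fh.write("\t".join(["axis"] + [f"{c:.10g}" for c in matrix.col_axis]) + "\n")
        for r, row in zip(matrix.row_axis, matrix.values):
            fh.write("\t".join([f"{r:.10g}"] + [f"{v:.10g}" for v in row]) + "\n")


def read_matrix_tsv(path: str | Path) -> SpectralMatrix:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    col_axis = np.array([float(v) for v in rows[0][1:]])
    row_axis = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return SpectralMatrix(
        row_axis, col_axis, values, samples=np.ones(row_axis.size, dtype=int)
    )


# -------------------------------------------------------------- geometries

def write_xyz(geometry: Geometry, path: str | Path, comment: str = "") -> None:
    lines = [str(geometry.n_atoms), comment]
    for sym, (x, y, z) in zip(geometry.symbols, geometry.coords):
        lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> tuple[Geometry, float | None]:
    """Read an XYZ file; if the comment line contains ``delta_e_cm1=<x>``
    the released electronic energy is returned alongside the geometry."""
    text = Path(path).read_text().splitlines()
    n = int(text[0].split()[0])
    comment = text[1] if len(text) > 1 else ""
    symbols, coords = [], []
    for line in text[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    delta_e = None
    for token in comment.replace(",", " ").split():
        if token.startswith("delta_e_cm1="):
            delta_e = float(token.split("=", 1)[1])
    return Geometry(symbols, np.array(coords)), delta_e


# ------------------------------------------------------------ normal modes

def write_modes_json(modeset: NormalModeSet, path: str | Path) -> None:
    doc = {
        "symbols": modeset.reference.symbols,
        "coords_angstrom": modeset.reference.coords.tolist(),
        "masses_amu": modeset.reference.masses.tolist(),
        "frequencies_cm1": modeset.frequencies.tolist(),
        "vectors_mass_weighted": modeset.vectors.tolist(),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_modes_json(path: str | Path) -> NormalModeSet:
    doc = json.loads(Path(path).read_text())
    ref = Geometry(
        doc["symbols"],
        np.array(doc["coords_angstrom"]),
        np.array(doc["masses_amu"]),
    )
    return NormalModeSet(
        reference=ref,
        frequencies=np.array(doc["frequencies_cm1"]),
        vectors=np.array(doc["vectors_mass_weighted"]),
    )
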