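"""CSV/JSON conventions for signals, decompositions and spectra.

Signals are single-column CSV (or whitespace-delimited) numeric text;
decompositions are CSV with columns ``imf1..imfK,residue``; spectra
datasets are CSV with ``sample_id, concentration`` then one absorbance
column per wavelength (numeric headers, nm).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emd import Decomposition
from .synthetic import SpectraDataset

__all__ = [
    "read_signal", "write_signal",
    "read_decomposition", "write_decomposition",
    "read_spectra", "write_spectra",
    "write_json",
]


def read_signal(path) -> np.ndarray:
    """Read a 1-D signal from single-column CSV or whitespace text."""
    text = Path(path).read_text()
    sep = "," if "," in text else None
    values = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token = line.split(sep)[0] if sep else line.split()[0]
        try:
            values.append(float(token))
        except ValueError:
            if values:
                raise
            continue  # header line
    return np.asarray(values, dtype=float)


def write_signal(path, signal) -> None:
    np.savetxt(path, np.asarray(signal, dtype=float), fmt="%.12g")


def write_decomposition(path, dec: Decomposition) -> None:
    cols = {f"imf{i+1}": dec.imfs[i] for i in range(dec.n_modes)}
    cols["residue"] = dec.residue
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_decomposition(path, method: str = "EMD") -> Decomposition:
    df = pd.read_csv(path)
    imf_cols = [c for c in df.columns if c.startswith("imf")]
    imf_cols.sort(key=lambda c: int(c[3:]))
    if "residue" not in df.columns:
        raise ValueError("decomposition CSV must contain a 'residue' column")
    imfs = df[imf_cols].to_numpy().T if imf_cols else np.empty((0, len(df)))
    return Decomposition(imfs=imfs, residue=df["residue"].to_numpy(),
                         method=method)


def write_spectra(path, ds: SpectraDataset) -> None:
    df = pd.DataFrame(ds.absorbance,
                      columns=[f"{w:.4f}" for w in ds.wavelengths])
    df.insert(0, "concentration", ds.concentrations)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, index=False, float_format="%.8g")


def read_spectra(path) -> SpectraDataset:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id" or df.columns[1] != "concentration":
        raise ValueError("spectra CSV must start with sample_id,concentration")
    wl = np.array([float(c) for c in df.columns[2:]])
    return SpectraDataset(wavelengths=wl,
                          absorbance=df.iloc[:, 2:].to_numpy(dtype=float),
                          concentrations=df["concentration"].to_numpy(dtype=float),
                          sample_ids=[str(s) for s in df["sample_id"]])


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
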