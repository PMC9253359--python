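"""Plain-text readers and writers for the pipeline's tabular formats.

Formats are deliberately simple, diff-able text: CSV for plate-reader
traces, titrations, calibrants and result tables; two-column
whitespace-delimited text (``#`` comments) for spectra; FASTA for protein
sequences; YAML for configs and ground-truth sidecars.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .kinetics import ThTTrace
from .mobility import CalibrantEntry
from .motifs import ProteinSequence
from .spectra import MassSpectrum

__all__ = [
    "read_tht_csv",
    "write_tht_csv",
    "read_spectrum_txt",
    "write_spectrum_txt",
    "read_calibrants_csv",
    "write_calibrants_csv",
    "read_titration_csv",
    "read_fasta",
    "write_truth_yaml",
    "read_truth_yaml",
]


def read_tht_csv(path: str | Path) -> list[ThTTrace]:
    """Read plate-reader traces: columns time_h, fluorescence[, replicate, condition].

    One trace per (condition, replicate) group; a bare two-column file
    yields a single trace.
    """
    df = pd.read_csv(path)
    required = {"time_h", "fluorescence"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    group_cols = [c for c in ("condition", "replicate") if c in df.columns]
    traces = []
    groups = df.groupby(group_cols, sort=True) if group_cols else [((), df)]
    for key, g in groups:
        meta = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        traces.append(
            ThTTrace(
                time=g["time_h"].to_numpy(),
                fluorescence=g["fluorescence"].to_numpy(),
                metadata=meta,
            )
        )
    return traces


def write_tht_csv(path: str | Path, traces: Iterable[ThTTrace]) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tr.time,
                    "fluorescence": tr.fluorescence,
                    "replicate": tr.metadata.get("replicate", 0),
                    "condition": tr.metadata.get("condition", ""),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectrum_txt(path: str | Path) -> MassSpectrum:
    """Two-column (mz, intensity) whitespace-delimited text; '#' comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (mz, intensity)")
    return MassSpectrum(mz=data[:, 0], intensity=data[:, 1])


def write_spectrum_txt(path: str | Path, spectrum: MassSpectrum) -> None:
    header = "mz intensity"
    np.savetxt(
        path,
        np.column_stack([spectrum.mz, spectrum.intensity]),
        header=header,
        fmt="%.6f %.8e",
    )


def read_calibrants_csv(path: str | Path) -> list[CalibrantEntry]:
    """Calibrant table: mass_da, charge, drift_ms, ccs_ref_A2."""
    df = pd.read_csv(path)
    required = {"mass_da", "charge", "drift_ms", "ccs_ref_A2"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        CalibrantEntry(
            mass=row.mass_da,
            charge=int(row.charge),
            drift_time=row.drift_ms,
            reference_ccs=row.ccs_ref_A2,
        )
        for row in df.itertuples()
    ]


def write_calibrants_csv(path: str | Path, calibrants: Iterable[CalibrantEntry]) -> None:
    pd.DataFrame(
        [
            {
                "mass_da": c.mass,
                "charge": c.charge,
                "drift_ms": c.drift_time,
                "ccs_ref_A2": c.reference_ccs,
            }
            for c in calibrants
        ]
    ).to_csv(path, index=False)


def read_titration_csv(path: str | Path) -> pd.DataFrame:
    """Titration table: replicate, p1_0_uM, p2_0_uM, ab_p1, ab_complex[, ab_p2]."""
    df = pd.read_csv(path)
    required = {"replicate", "p1_0_uM", "p2_0_uM", "ab_p1", "ab_complex"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_truth_yaml(path: str | Path, truth: dict) -> None:
    """Ground-truth sidecar for synthetic datasets."""
    Path(path).write_text(yaml.safe_dump(truth, sort_keys=False))


def read_truth_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
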