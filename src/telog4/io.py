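"""Plain-text readers and writers for the pipeline's file formats.

Spectra and melting curves travel as two-column CSV with '#'-prefixed
metadata header lines; traces as long-format TSV (molecule_id, frame, donor,
acceptor) with the frame interval in a metadata line; cleavage data as TSV
(construct, cation, replicate, time_min, intensity_cleaved,
intensity_uncleaved).  Reports are TSV and JSON; every CLI run also writes a
provenance record (config hash, seed, package versions) sufficient to
reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cd import CDSpectrum, MeltingCurve
from .cleavage import CleavageMeasurement, CleavageTimecourse
from .fret import FretTrace

__all__ = [
    "read_cd_spectrum",
    "write_cd_spectrum",
    "read_melting_curve",
    "write_melting_curve",
    "read_traces",
    "write_traces",
    "read_labels",
    "write_labels",
    "read_cleavage_table",
    "write_cleavage_table",
    "write_json",
    "provenance_record",
]


def _read_metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if value:
                meta[key.strip()] = value.strip()
    return meta


def write_cd_spectrum(spectrum: CDSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name = {spectrum.name}\n")
        fh.write(f"# cation = {spectrum.cation}\n")
        fh.write(f"# temperature_C = {spectrum.temperature}\n")
        fh.write("wavelength_nm,ellipticity_mdeg\n")
        for wl, el in zip(spectrum.wavelengths, spectrum.ellipticity):
            fh.write(f"{wl:.6g},{el:.10g}\n")


def read_cd_spectrum(path) -> CDSpectrum:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    return CDSpectrum(
        df["wavelength_nm"].to_numpy(float),
        df["ellipticity_mdeg"].to_numpy(float),
        name=meta.get("name", Path(path).stem),
        cation=meta.get("cation", "K"),
        temperature=float(meta.get("temperature_C", 23.0)),
    )


def write_melting_curve(curve: MeltingCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wavelength_nm = {curve.wavelength}\n")
        fh.write(f"# direction = {curve.direction}\n")
        fh.write("temperature_C,ellipticity_mdeg\n")
        for t, y in zip(curve.temperatures, curve.ellipticity):
            fh.write(f"{t:.6g},{y:.10g}\n")


def read_melting_curve(path) -> MeltingCurve:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    return MeltingCurve(
        df["temperature_C"].to_numpy(float),
        df["ellipticity_mdeg"].to_numpy(float),
        wavelength=float(meta.get("wavelength_nm", 265.0)),
        direction=meta.get("direction", "melt"),
    )


def write_traces(traces: Sequence[FretTrace], path) -> None:
    """Long-format TSV; the shared frame interval travels in a '#' line."""
    if not traces:
        raise ValueError("no traces to write")
    dt = traces[0].frame_interval
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s = {dt}\n")
        fh.write("molecule_id\tframe\tdonor\tacceptor\n")
        for tr in traces:
            for j in range(tr.n_frames):
                fh.write(f"{tr.molecule_id}\t{j}\t{tr.donor[j]:.10g}\t{tr.acceptor[j]:.10g}\n")


def read_traces(path) -> list[FretTrace]:
    meta = _read_metadata(path)
    dt = float(meta.get("frame_interval_s", 0.1))
    df = pd.read_csv(path, sep="\t", comment="#")
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        traces.append(
            FretTrace(
                molecule_id=str(mol),
                frame_interval=dt,
                donor=grp["donor"].to_numpy(float),
                acceptor=grp["acceptor"].to_numpy(float),
            )
        )
    return traces


def write_labels(labels: Mapping[str, str], path) -> None:
    """Ground-truth (or predicted) label sidecar TSV."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tlabel\n")
        for mol, lab in labels.items():
            fh.write(f"{mol}\t{lab}\n")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["molecule_id"].astype(str), df["label"].astype(str)))


def write_cleavage_table(timecourses: Iterable[CleavageTimecourse], path) -> None:
    rows = []
    for tc in timecourses:
        for m in tc.measurements:
            rows.append(
                {
                    "construct": tc.construct,
                    "cation": tc.cation,
                    "replicate": tc.replicate,
                    "time_min": m.time,
                    "intensity_cleaved": m.intensity_cleaved,
                    "intensity_uncleaved": m.intensity_uncleaved,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cleavage_table(path) -> list[CleavageTimecourse]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    keys = ["construct", "cation", "replicate"]
    for (construct, cation, replicate), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_min")
        measurements = tuple(
            CleavageMeasurement(
                time=float(r.time_min),
                intensity_cleaved=float(r.intensity_cleaved),
                intensity_uncleaved=float(r.intensity_uncleaved),
            )
            for r in grp.itertuples()
        )
        out.append(
            CleavageTimecourse(
                construct=str(construct), cation=str(cation),
                replicate=int(replicate), measurements=measurements,
            )
        )
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, frozenset):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def provenance_record(config: Mapping, seed: int) -> dict:
    """Reproducibility record: parameter hash, seed, versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": dict(config),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "versions": {
            "telog4": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
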