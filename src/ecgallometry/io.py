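"""Plain-text serialization: two-column signal CSV, template CSV + JSON
sidecar, fiducial JSON, TSV tables.  All sample indices are 0-based."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .delineate import FiducialSet
from .preprocess import BeatTemplate, ECGSignal

__all__ = [
    "write_signal_csv", "read_signal_csv",
    "write_template", "read_template",
    "write_fiducials_json", "write_table",
]


def write_signal_csv(sig: ECGSignal, path: str | Path) -> Path:
    """Two-column CSV: time in seconds, amplitude in mV."""
    path = Path(path)
    t = np.arange(len(sig.samples)) / sig.fs
    pd.DataFrame({"time_s": t, "amplitude_mV": sig.samples}).to_csv(path, index=False)
    return path


def read_signal_csv(path: str | Path, lead: str = "I") -> ECGSignal:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    if len(t) < 2:
        raise ValueError("signal file needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGSignal(df.iloc[:, 1].to_numpy(float), fs=fs, lead=lead)


def write_template(tpl: BeatTemplate, path: str | Path) -> Path:
    """Template samples as CSV plus a JSON sidecar with the metadata."""
    path = Path(path)
    pd.DataFrame({"amplitude_mV": tpl.samples}).to_csv(path, index=False)
    meta = {"fs": tpl.fs, "n_averaged": tpl.n_averaged,
            "n_rejected": tpl.n_rejected, "r_index": tpl.r_index,
            "lead": tpl.lead}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_template(path: str | Path) -> BeatTemplate:
    path = Path(path)
    samples = pd.read_csv(path)["amplitude_mV"].to_numpy(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return BeatTemplate(samples=samples, fs=meta["fs"],
                        n_averaged=meta["n_averaged"],
                        n_rejected=meta["n_rejected"],
                        r_index=meta["r_index"], lead=meta.get("lead", "I"))


def write_fiducials_json(fids: FiducialSet, fs: float, path: str | Path) -> Path:
    """FiducialSet as JSON: 0-based indices, times additionally in ms."""
    path = Path(path)
    d = fids.as_dict()
    out = {k: (None if v is None else int(v)) for k, v in d.items()
           if k != "isoelectric_level"}
    out["isoelectric_level_mV"] = fids.isoelectric_level
    out["times_ms"] = {k: (None if v is None else v * 1000.0 / fs)
                       for k, v in out.items()
                       if k not in ("isoelectric_level_mV",) and not isinstance(v, dict)}
    path.write_text(json.dumps(out, indent=1))
    return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """TSV with header; floats at full precision."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=bool(df.index.name))
    return path
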