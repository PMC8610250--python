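"""Readers and writers for every artifact the pipeline produces.

Respiration traces travel as two-column delimited text (time_s, value)
with a header; multi-subject datasets live in an HDF5 container with
groups /subject_<i>/{respiration, signals, meta}; result tables are
TSV with '.' decimals and UTF-8; ground truth and run configuration
round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import (
    Coupling,
    MultiSubjectDataset,
    RespirationTrace,
    SubjectDataset,
    SyntheticGroundTruth,
)

__all__ = [
    "read_trace",
    "write_trace",
    "read_container",
    "write_container",
    "read_table",
    "write_table",
    "read_ground_truth",
    "write_ground_truth",
    "TraceParseError",
]


class TraceParseError(ValueError):
    """Malformed trace file; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


def write_trace(path: str | Path, trace: RespirationTrace) -> None:
    t = trace.times_s
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s\tvalue\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{ti:.9g}\t{vi:.12g}\n")


def read_trace(path: str | Path) -> RespirationTrace:
    times, values = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if "time_s" not in header:
            raise TraceParseError("missing 'time_s' header", 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceParseError("expected two columns", lineno)
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise TraceParseError("non-numeric field", lineno) from None
    t = np.asarray(times)
    if t.size < 2:
        raise TraceParseError("fewer than 2 samples", 1)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9)))
        raise TraceParseError("non-uniform sampling interval", bad + 3)
    return RespirationTrace(
        samples=np.asarray(values), rate_hz=1.0 / dt[0], t0_s=float(t[0])
    )


def write_container(path: str | Path, dataset: MultiSubjectDataset) -> None:
    with h5py.File(path, "w") as f:
        for subj in dataset.subjects:
            g = f.create_group(f"subject_{subj.subject_id}")
            g.create_dataset("respiration", data=subj.respiration.samples)
            g.create_dataset("signals", data=subj.signals)
            meta = g.create_group("meta")
            meta.attrs["rate_hz"] = subj.respiration.rate_hz
            meta.attrs["t0_s"] = subj.respiration.t0_s
            meta.attrs["subject_id"] = subj.subject_id


def read_container(path: str | Path) -> MultiSubjectDataset:
    subjects = []
    with h5py.File(path, "r") as f:
        names = sorted(
            (k for k in f if k.startswith("subject_")),
            key=lambda k: int(k.split("_")[1]),
        )
        for name in names:
            g = f[name]
            meta = g["meta"].attrs
            trace = RespirationTrace(
                samples=g["respiration"][()],
                rate_hz=float(meta["rate_hz"]),
                t0_s=float(meta["t0_s"]),
            )
            subjects.append(
                SubjectDataset(
                    respiration=trace,
                    signals=g["signals"][()],
                    subject_id=int(meta["subject_id"]),
                )
            )
    return MultiSubjectDataset(
        subjects=subjects, ground_truth=SyntheticGroundTruth()
    )


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_ground_truth(path: str | Path, gt: SyntheticGroundTruth) -> None:
    doc = {
        "breath_period_mean_s": float(gt.breath_period_mean_s),
        "breath_period_jitter_s": float(gt.breath_period_jitter_s),
        "noise_exponent": float(gt.noise_exponent),
        "snr": float(gt.snr),
        "subject_sd": float(gt.subject_sd),
        "seed": int(gt.seed),
        "couplings": [
            {
                "carrier_freq_hz": float(c.carrier_freq_hz),
                "modulation_depth": float(c.modulation_depth),
                "preferred_phase_rad": float(c.preferred_phase_rad),
                "entity_ids": [int(e) for e in c.entity_ids],
            }
            for c in gt.couplings
        ],
        "spatial_maps": (
            None if gt.spatial_maps is None else np.asarray(gt.spatial_maps).tolist()
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    couplings = [
        Coupling(
            carrier_freq_hz=c["carrier_freq_hz"],
            modulation_depth=c["modulation_depth"],
            preferred_phase_rad=c["preferred_phase_rad"],
            entity_ids=tuple(c["entity_ids"]),
        )
        for c in doc.get("couplings", [])
    ]
    maps = doc.get("spatial_maps")
    return SyntheticGroundTruth(
        breath_period_mean_s=doc["breath_period_mean_s"],
        breath_period_jitter_s=doc["breath_period_jitter_s"],
        couplings=couplings,
        noise_exponent=doc["noise_exponent"],
        spatial_maps=None if maps is None else np.asarray(maps, dtype=float),
        snr=doc["snr"],
        subject_sd=doc["subject_sd"],
        seed=doc["seed"],
    )
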