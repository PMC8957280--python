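#!/usr/bin/env python
"""Optional benchmark on the PhysioNet Fantasia ECG database.

Not part of the test suite: it needs ~1 GB of external data. Download the
records yourself (https://physionet.org/content/fantasia/1.0.0/), convert
each record to a single-column CSV at 250 Hz (e.g. with the wfdb package:
``wfdb.rdrecord(...).p_signal``), and point --data-dir at a directory of
``<record>.csv`` files named f1y01..f1y10/f2y01..f2y10 (young) and
f1o01..f1o10/f2o01..f2o10 (old).

Reported: mean heart rate by age group, and Cohen's d of cleaned RMSSD
between age groups (young vs old).
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

from pulseline import io as plio
from pulseline.detection import DetectionSettings
from pulseline.pipeline import AnalysisSettings, analyze, cleaned_series
from pulseline.preprocess import preprocess

SAMPLING_RATE_HZ = 250.0


def analyze_record(path: Path) -> dict:
    raw = plio.read_signal(path, sampling_rate=SAMPLING_RATE_HZ)
    prepared = preprocess(raw)
    results = analyze(
        prepared,
        AnalysisSettings(
            detection=DetectionSettings(ecg_prt_clustering=True),
            outliers="liberal",
        ),
    )
    clean = cleaned_series(results)
    return {"bpm": clean["bpm"].mean(), "rmssd": clean["rmssd"].mean()}


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    args = parser.parse_args(argv)

    records = sorted(args.data_dir.glob("f*.csv")) if args.data_dir.is_dir() else []
    if not records:
        print(
            f"No Fantasia CSVs found under {args.data_dir}.\n"
            "This benchmark requires an external download; see the module "
            "docstring for instructions.",
            file=sys.stderr,
        )
        return 2

    groups: dict[str, list[dict]] = {"young": [], "old": []}
    for path in records:
        group = "young" if "y" in path.stem[:4] else "old"
        summary = analyze_record(path)
        groups[group].append(summary)
        print(f"{path.stem} ({group}): BPM {summary['bpm']:.2f}, "
              f"RMSSD {summary['rmssd']:.2f} ms")

    for name, rows in groups.items():
        if rows:
            bpm = np.array([r["bpm"] for r in rows])
            print(f"{name}: mean HR {bpm.mean():.2f} (SD {bpm.std(ddof=1):.2f}), n={len(rows)}")
    young = np.array([r["rmssd"] for r in groups["young"]])
    old = np.array([r["rmssd"] for r in groups["old"]])
    if len(young) >= 2 and len(old) >= 2:
        pooled = np.sqrt(
            ((len(young) - 1) * young.var(ddof=1) + (len(old) - 1) * old.var(ddof=1))
            / (len(young) + len(old) - 2)
        )
        print(f"age effect on RMSSD, Cohen's d = {(young.mean() - old.mean()) / pooled:.2f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
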