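"""Plain-text dataset layout: readers and writers.

One dataset directory holds a manifest CSV mapping each subject to its files,
a parcellation CSV, the generator config YAML, and per-subject tracking,
CORT, EPM, ROI-matrix, motion and nuisance files. Everything is uncompressed
CSV/TSV so datasets are diffable and portable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import Arena, EPMResult, TrackingTrace
from .config import SyntheticConfig
from .connectome import RoiRun
from .endocrine import CortProfile
from .simulate import make_parcellation, simulate_cohort

__all__ = [
    "write_trace",
    "read_trace",
    "write_cort",
    "read_cort",
    "write_epm",
    "read_epm",
    "write_roi_run",
    "read_roi_run",
    "generate_dataset",
]

_FLOAT_FMT = "%.6g"


def write_trace(trace: TrackingTrace, path) -> None:
    header = (
        f"# rate_hz={trace.rate:g} length_cm={trace.arena.length_cm:g} "
        f"width_cm={trace.arena.width_cm:g} pad_position={trace.arena.pad_position:g} "
        f"subject={trace.subject_id}\n"
    )
    df = pd.DataFrame({"t_s": trace.t, "x_cm": trace.x, "y_cm": trace.y, "phase": trace.phase})
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _parse_header(path) -> dict[str, str]:
    with open(path) as fh:
        line = fh.readline()
    if not line.startswith("#"):
        return {}
    return dict(tok.split("=", 1) for tok in line[1:].split() if "=" in tok)


def read_trace(path) -> TrackingTrace:
    meta = _parse_header(path)
    df = pd.read_csv(path, comment="#")
    arena = Arena(
        length_cm=float(meta.get("length_cm", 45)),
        width_cm=float(meta.get("width_cm", 20)),
        pad_position=float(meta.get("pad_position", 45)),
    )
    return TrackingTrace(
        subject_id=meta.get("subject", Path(path).stem),
        rate=float(meta.get("rate_hz", 10)),
        x=df["x_cm"].to_numpy(),
        y=df["y_cm"].to_numpy(),
        phase=df["phase"].to_numpy(dtype=object),
        arena=arena,
    )


def write_cort(profile: CortProfile, path) -> None:
    pd.DataFrame(
        {
            "subject": profile.subject_id,
            "t_min": list(profile.t_min),
            "cort_ng_ml": list(profile.conc_ng_ml),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cort(path) -> CortProfile:
    df = pd.read_csv(path, comment="#").sort_values("t_min")
    return CortProfile(
        subject_id=str(df["subject"].iloc[0]),
        conc_ng_ml=tuple(df["cort_ng_ml"].astype(float)),
        t_min=tuple(df["t_min"].astype(int)),
    )


def write_epm(result: EPMResult, path) -> None:
    pd.DataFrame(
        [
            {
                "subject": result.subject_id,
                "open_s": result.open_s,
                "closed_s": result.closed_s,
                "center_s": result.center_s,
            }
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_epm(path) -> EPMResult:
    row = pd.read_csv(path, comment="#").iloc[0]
    return EPMResult(
        subject_id=str(row["subject"]),
        open_s=float(row["open_s"]),
        closed_s=float(row["closed_s"]),
        center_s=float(row["center_s"]),
    )


def write_roi_run(run: RoiRun, data_path, motion_path, nuisance_path) -> None:
    labels = run.region_labels or [f"r{i}" for i in range(run.data.shape[1])]
    pd.DataFrame(run.data, columns=list(labels)).to_csv(
        data_path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(run.motion, columns=["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]).to_csv(
        motion_path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        run.nuisance, columns=[f"nuis{i}" for i in range(run.nuisance.shape[1])]
    ).to_csv(nuisance_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_roi_run(
    data_path, motion_path, nuisance_path, subject_id: str, tr: float, batch_id: str = "batch0"
) -> RoiRun:
    data = pd.read_csv(data_path, sep="\t")
    motion = pd.read_csv(motion_path, sep="\t").to_numpy(dtype=float)
    nuisance = pd.read_csv(nuisance_path, sep="\t").to_numpy(dtype=float)
    return RoiRun(
        subject_id=subject_id,
        run_id=Path(data_path).stem,
        batch_id=batch_id,
        tr=tr,
        data=data.to_numpy(dtype=float),
        motion=motion,
        nuisance=nuisance,
        region_labels=tuple(data.columns),
    )


def generate_dataset(config: SyntheticConfig, outdir, seed: int | None = None) -> Path:
    """Simulate a full cohort and write it as a plain-text dataset directory.

    Layout: ``manifest.csv``, ``parcellation.csv``, ``config.yaml`` and a
    ``subjects/`` tree with one file set per animal. Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "subjects").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config, seed=seed)
    runs = {r.subject_id: r for r in cohort.runs}

    rows = []
    for _, row in cohort.subjects.iterrows():
        sid = row.subject_id
        rel = {
            "trace_file": f"subjects/{sid}_trace.csv",
            "cort_file": f"subjects/{sid}_cort.csv",
            "epm_file": f"subjects/{sid}_epm.csv",
            "roi_file": f"subjects/{sid}_bold.tsv",
            "motion_file": f"subjects/{sid}_motion.tsv",
            "nuisance_file": f"subjects/{sid}_nuisance.tsv",
        }
        write_trace(cohort.traces[sid], outdir / rel["trace_file"])
        write_cort(cohort.cort[sid], outdir / rel["cort_file"])
        write_epm(cohort.epm[sid], outdir / rel["epm_file"])
        if sid in runs:
            write_roi_run(
                runs[sid],
                outdir / rel["roi_file"],
                outdir / rel["motion_file"],
                outdir / rel["nuisance_file"],
            )
        rows.append({"subject_id": sid, "group": row.group, "batch": row.batch, **rel})

    manifest = pd.DataFrame(rows)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    make_parcellation(config.roi.n_regions).to_csv(outdir / "parcellation.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    return manifest_path
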