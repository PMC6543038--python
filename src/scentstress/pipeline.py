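"""End-to-end orchestration: dataset in, result tables out.

Stage order is fixed (behavior -> phenotyping -> endocrine -> connectome) and
logged; every output table carries a one-line provenance header with the
package version, the pipeline-config hash and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import hashlib
import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import connectome as conn
from . import io as sio
from .endocrine import cort_behavior_correlations
from .phenotyping import assign_phenotype, fit_gmm_series
from .stats import two_sample_t

log = logging.getLogger("scentstress")

ALL_STAGES = ("behavior", "phenotype", "cort", "connectome")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]


class PipelineError(RuntimeError):
    """Raised on manifest/parcellation inconsistencies; names file and row."""


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str
    parcellation: str
    out_dir: str
    freeze_threshold_cm_s: float = bhv.FREEZE_SPEED_THRESHOLD
    freeze_min_bout_s: float = bhv.FREEZE_MIN_BOUT_S
    phenotype_method: str = "tertile"
    k_max: int = 3
    gmm_restarts: int = 20
    fd_threshold_mm: float = conn.FD_THRESHOLD_MM
    fd_radius_mm: float = conn.FD_RADIUS_MM
    drop_first: int = conn.DROP_FIRST
    max_removed_frac: float = conn.MAX_REMOVED_FRAC
    band_hz: tuple[float, float] = conn.BAND_HZ
    tr_s: float = 1.0
    screen_alpha: float = 0.05
    group_alpha: float = 0.01
    seed_regions: tuple[str, ...] = ("ACC", "AON", "PBn")
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.screen_alpha, self.group_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        if "seed_regions" in d:
            d["seed_regions"] = tuple(d["seed_regions"])
        return cls(**d)

    def digest(self) -> str:
        # hash the analysis parameters, not where the results are written
        payload = yaml.safe_dump(
            {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.__dict__.items()
                if k != "out_dir"
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# scentstress=0.1.0 config={cfg.digest()} seed={cfg.seed} stage={stage}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    log.info("wrote %s (%d rows)", path, len(df))


def _load_manifest(cfg: PipelineConfig) -> pd.DataFrame:
    mpath = Path(cfg.manifest)
    if not mpath.exists():
        raise PipelineError(f"manifest not found: {mpath}")
    manifest = pd.read_csv(mpath, comment="#")
    required = {"subject_id", "group", "batch", "trace_file", "cort_file", "epm_file"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise PipelineError(f"manifest {mpath} missing columns: {sorted(missing_cols)}")
    base = mpath.parent
    file_cols = [c for c in manifest.columns if c.endswith("_file")]
    for idx, row in manifest.iterrows():
        for col in file_cols:
            f = base / str(row[col])
            if not f.exists():
                raise PipelineError(
                    f"manifest {mpath} row {idx} (subject {row.subject_id}): missing file {f}"
                )
    return manifest


def run_pipeline(cfg: PipelineConfig, stages=ALL_STAGES) -> dict[str, pd.DataFrame]:
    """Run the requested stages in the fixed order; returns tables by name.

    Later stages consume earlier in-memory results (freezing drives
    phenotyping, the CORT correlations and the connectome screen), so
    prerequisite computations run even when only a later stage's tables are
    requested.
    """
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    manifest = _load_manifest(cfg)
    base = Path(cfg.manifest).parent
    tables: dict[str, pd.DataFrame] = {}
    log.info("pipeline start: %d subjects, stages=%s", len(manifest), ",".join(stages))

    # ---- behavior (always computed: downstream stages need freezing) ----
    rows, epm_rows = [], []
    for _, m in manifest.iterrows():
        trace = sio.read_trace(base / m.trace_file)
        speed = bhv.compute_speed(trace)
        mask, _bouts = bhv.detect_freezing(
            speed, trace.rate, cfg.freeze_threshold_cm_s, cfg.freeze_min_bout_s
        )
        s = bhv.summarize_exposure(trace, mask)
        row = {
            "subject_id": m.subject_id,
            "group": m.group,
            "freezing_s": s.freezing_s,
            "freezing_pct": s.freezing_pct,
            "mean_dist_pad_cm": s.mean_dist_pad_cm,
            "distance_traveled_cm": s.distance_traveled_cm,
            "max_speed_cm_s": s.max_speed_cm_s,
            "mean_speed_mobile_cm_s": s.mean_speed_mobile_cm_s,
        }
        row.update({f"freeze_min{i + 1}_s": v for i, v in enumerate(s.freezing_per_min)})
        row.update({f"zone{i + 1}_time_s": v for i, v in enumerate(s.zone_time_s)})
        row.update({f"zone{i + 1}_freeze_pct": v for i, v in enumerate(s.zone_freezing_pct)})
        rows.append(row)
        e = sio.read_epm(base / m.epm_file)
        epm_rows.append(
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "open_s": e.open_s,
                "closed_s": e.closed_s,
                "center_s": e.center_s,
                "epm_score": e.score,
            }
        )
    beh = pd.DataFrame(rows)
    epm = pd.DataFrame(epm_rows)
    if "behavior" in stages:
        _write_table(beh, out / "behavior_summary.csv", cfg, "behavior")
        _write_table(epm, out / "epm.csv", cfg, "behavior")
    tables["behavior"] = beh
    tables["epm"] = epm

    # ---- phenotyping on exposed animals' freezing ----
    exposed = beh[beh.group == "exposed"].reset_index(drop=True)
    assignment = assign_phenotype(exposed.freezing_pct.to_numpy(), cfg.phenotype_method)
    pheno = exposed[["subject_id", "freezing_pct"]].copy()
    pheno["phenotype"] = assignment.labels
    tables["phenotype"] = pheno
    if "phenotype" in stages:
        sel = fit_gmm_series(
            exposed.freezing_pct.to_numpy(),
            k_max=cfg.k_max,
            n_restarts=cfg.gmm_restarts,
            seed=cfg.seed,
        )
        gmm = pd.DataFrame(
            {
                "k": [f.k for f in sel.fits],
                "log_likelihood": [f.log_likelihood for f in sel.fits],
                "aic": [f.aic for f in sel.fits],
                "delta_aic": sel.delta_aic,
                "akaike_weight": sel.weights,
                "selected": [f.k == sel.selected_k for f in sel.fits],
                "weights": [";".join(f"{w:.4g}" for w in f.weights) for f in sel.fits],
                "means": [";".join(f"{m:.4g}" for m in f.means) for f in sel.fits],
                "sds": [";".join(f"{s:.4g}" for s in f.sds) for f in sel.fits],
            }
        )
        _write_table(pheno, out / "phenotypes.csv", cfg, "phenotype")
        _write_table(gmm, out / "gmm_selection.csv", cfg, "phenotype")
        tables["gmm_selection"] = gmm

    # ---- endocrine ----
    if "cort" in stages:
        profiles = {
            m.subject_id: sio.read_cort(base / m.cort_file) for _, m in manifest.iterrows()
        }
        cort_df = pd.DataFrame(
            {
                "subject_id": list(profiles),
                "cort_0": [p.conc_ng_ml[0] for p in profiles.values()],
                "cort_30": [p.conc_ng_ml[1] for p in profiles.values()],
                "cort_60": [p.conc_ng_ml[2] for p in profiles.values()],
                "cort_120": [p.conc_ng_ml[3] for p in profiles.values()],
                "total_response": [p.total_response for p in profiles.values()],
            }
        ).merge(manifest[["subject_id", "group"]], on="subject_id")
        freezing = dict(zip(exposed.subject_id, exposed.freezing_pct))
        epm_scores = dict(zip(epm.subject_id, epm.epm_score))
        exp_profiles = {s: p for s, p in profiles.items() if s in freezing}
        report = cort_behavior_correlations(exp_profiles, freezing, epm_scores)
        corr_df = pd.DataFrame(
            [
                {
                    "pair": "total_cort_vs_freezing",
                    "r": report.vs_freezing.statistic,
                    "p": report.vs_freezing.p,
                    "n": int(report.vs_freezing.df) + 2,
                },
                {
                    "pair": "total_cort_vs_epm",
                    "r": report.vs_epm.statistic,
                    "p": report.vs_epm.p,
                    "n": int(report.vs_epm.df) + 2,
                },
            ]
        )
        # group contrasts on the total response (low vs high / control)
        merged = cort_df.merge(pheno[["subject_id", "phenotype"]], on="subject_id", how="left")
        merged.loc[merged.group == "control", "phenotype"] = "control"
        contrasts = []
        for a, b in (("low", "high"), ("low", "control")):
            ta = merged.loc[merged.phenotype == a, "total_response"]
            tb = merged.loc[merged.phenotype == b, "total_response"]
            if len(ta) >= 2 and len(tb) >= 2:
                res = two_sample_t(ta, tb)
                contrasts.append({"contrast": f"{a}_vs_{b}", "t": res.statistic, "p": res.p})
        _write_table(cort_df, out / "cort.csv", cfg, "cort")
        _write_table(corr_df, out / "cort_correlations.csv", cfg, "cort")
        if contrasts:
            _write_table(pd.DataFrame(contrasts), out / "cort_contrasts.csv", cfg, "cort")
        tables["cort"] = cort_df
        tables["cort_correlations"] = corr_df

    # ---- connectome ----
    if "connectome" in stages:
        ppath = Path(cfg.parcellation)
        if not ppath.exists():
            raise PipelineError(f"parcellation not found: {ppath}")
        parcellation = pd.read_csv(ppath, comment="#")
        labels = list(parcellation["label"])
        z_by_subject: dict[str, np.ndarray] = {}
        excluded_rows = []
        for idx, m in manifest.iterrows():
            if "roi_file" not in manifest.columns or pd.isna(m.get("roi_file")):
                continue
            run = sio.read_roi_run(
                base / m.roi_file,
                base / m.motion_file,
                base / m.nuisance_file,
                subject_id=m.subject_id,
                tr=cfg.tr_s,
                batch_id=m.batch,
            )
            if list(run.region_labels) != labels:
                raise PipelineError(
                    f"manifest {cfg.manifest} row {idx} (subject {m.subject_id}): "
                    f"ROI columns do not match parcellation {ppath}"
                )
            clean = conn.preprocess_run(
                run,
                fd_threshold=cfg.fd_threshold_mm,
                drop_first=cfg.drop_first,
                max_removed_frac=cfg.max_removed_frac,
                band=cfg.band_hz,
                radius_mm=cfg.fd_radius_mm,
            )
            if clean.excluded:
                excluded_rows.append(
                    {"subject_id": m.subject_id, "reason": clean.exclusion_reason}
                )
                continue
            z_by_subject[m.subject_id] = conn.rsfc_matrix(clean).z
        log.info("connectome: %d usable runs, %d excluded", len(z_by_subject), len(excluded_rows))

        screen_ids = [s for s in exposed.subject_id if s in z_by_subject]
        zmats = [z_by_subject[s] for s in screen_ids]
        score = exposed.set_index("subject_id").loc[screen_ids, "freezing_pct"].to_numpy()
        edge_table = conn.edgewise_behavior_screen(zmats, score, alpha=cfg.screen_alpha)
        edge_table.insert(0, "label_i", [labels[i] for i in edge_table.region_i])
        edge_table.insert(1, "label_j", [labels[j] for j in edge_table.region_j])
        _write_table(edge_table, out / "edge_association.csv", cfg, "connectome")
        tables["edge_association"] = edge_table

        ph_map = dict(zip(pheno.subject_id, pheno.phenotype))
        lh_ids = [s for s in screen_ids if ph_map.get(s) in ("low", "high")]
        if len(lh_ids) >= 4:
            glabels = [ph_map[s] for s in lh_ids]
            gtable = conn.group_edge_difference(
                [z_by_subject[s] for s in lh_ids], glabels, alpha=cfg.group_alpha
            )
            gtable.insert(0, "label_i", [labels[i] for i in gtable.region_i])
            gtable.insert(1, "label_j", [labels[j] for j in gtable.region_j])
            _write_table(gtable, out / "group_difference.csv", cfg, "connectome")
            tables["group_difference"] = gtable

            # batch-adjusted contrast at the strongest group-difference edges
            batch_map = dict(zip(manifest.subject_id, manifest.batch))
            top = gtable.nsmallest(min(10, len(gtable)), "p")
            iu = top.region_i.to_numpy()
            ju = top.region_j.to_numpy()
            adj_rows = []
            zs = np.asarray([z_by_subject[s] for s in lh_ids])
            for label_i, label_j, i, j in zip(top.label_i, top.label_j, iu, ju):
                eff = conn.batch_adjusted_effect(
                    zs[:, i, j], glabels, [batch_map[s] for s in lh_ids]
                )
                adj_rows.append(
                    {
                        "label_i": label_i,
                        "label_j": label_j,
                        "estimate": eff.estimate,
                        "se": eff.se,
                        "p": eff.p,
                        "n_batches": eff.n_batches,
                        "model": eff.model,
                    }
                )
            _write_table(pd.DataFrame(adj_rows), out / "batch_adjusted.csv", cfg, "connectome")

        for seed_label in cfg.seed_regions:
            if seed_label not in labels:
                continue
            prof = conn.seed_profile(zmats, labels.index(seed_label), alpha=cfg.screen_alpha)
            prof.insert(0, "label", [labels[r] for r in prof.region])
            _write_table(prof, out / f"seed_profile_{seed_label}.csv", cfg, "connectome")

        if excluded_rows:
            _write_table(pd.DataFrame(excluded_rows), out / "excluded_runs.csv", cfg, "connectome")

    # run log
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_log.txt", "a") as fh:
        fh.write(
            f"scentstress=0.1.0 config={cfg.digest()} seed={cfg.seed} "
            f"stages={','.join(stages)} subjects={len(manifest)}\n"
        )
    return tables
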