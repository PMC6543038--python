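"""ROI-level resting-state functional connectivity and brain-behavior screens.

Consumes per-run T x R regionally-averaged BOLD matrices with motion and
nuisance regressors, applies the temporal preprocessing chain
(steady-state trim -> framewise-displacement scrubbing -> band-pass ->
nuisance regression), estimates per-subject Pearson/Fisher-z connectivity, and
runs the across-subject screens: edge-wise correlation with behavior,
high-vs-low group differences, batch-adjusted mixed-model contrasts, and
ROI-level seed profiles — all with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats as sps

from .stats import bh_fdr

FD_THRESHOLD_MM = 0.2
DROP_FIRST = 10
MAX_REMOVED_FRAC = 0.20
FD_RADIUS_MM = 5.0  # rat-brain rotation-to-translation conversion radius
BAND_HZ = (0.01, 0.1)
MIN_KEPT_VOLUMES = 30

__all__ = [
    "RoiRun",
    "ConnectivityMatrix",
    "compute_fd",
    "censor_volumes",
    "bandpass",
    "nuisance_regress",
    "preprocess_run",
    "rsfc_matrix",
    "edgewise_behavior_screen",
    "group_edge_difference",
    "batch_adjusted_effect",
    "seed_profile",
    "edge_index",
]


@dataclass(frozen=True)
class RoiRun:
    """One rsfMRI run: T x R BOLD matrix plus motion/nuisance regressors."""

    subject_id: str
    run_id: str
    tr: float  # s
    data: np.ndarray  # T x R
    motion: np.ndarray  # T x 6: tx, ty, tz (mm), rx, ry, rz (rad)
    nuisance: np.ndarray  # T x m (white-matter / ventricle signals)
    batch_id: str = "batch0"
    region_labels: tuple[str, ...] | None = None
    keep_mask: np.ndarray | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        motion = np.asarray(self.motion, dtype=float)
        nuis = np.asarray(self.nuisance, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "motion", motion)
        object.__setattr__(self, "nuisance", nuis)
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if data.ndim != 2:
            raise ValueError("data must be a T x R matrix")
        t = data.shape[0]
        if motion.shape != (t, 6):
            raise ValueError("motion must be T x 6")
        if nuis.ndim != 2 or nuis.shape[0] != t:
            raise ValueError("nuisance must be T x m")
        if self.region_labels is not None and len(self.region_labels) != data.shape[1]:
            raise ValueError("region label count must match data columns")


def compute_fd(motion, radius_mm: float = FD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement (mm): sum of absolute backward differences of the
    three translations plus ``radius_mm`` times the rotation differences.
    FD at the first volume is 0 by convention."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have 6 columns (3 translations, 3 rotations)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor_volumes(
    fd,
    fd_threshold: float = FD_THRESHOLD_MM,
    drop_first: int = DROP_FIRST,
    max_removed_frac: float = MAX_REMOVED_FRAC,
) -> tuple[np.ndarray, bool, float]:
    """Motion scrubbing bookkeeping on a per-run FD series.

    A volume is flagged iff its FD exceeds ``fd_threshold``; the removed set is
    the flagged volumes, their immediate temporal neighbors, and the first
    ``drop_first`` steady-state volumes. Returns ``(keep_mask, excluded,
    removed_frac)`` where ``removed_frac`` is the motion-removed fraction of
    the post-trim volumes and ``excluded`` marks runs losing more than
    ``max_removed_frac`` of them.
    """
    fd = np.asarray(fd, dtype=float).ravel()
    t = fd.size
    keep = np.ones(t, dtype=bool)
    keep[:drop_first] = False

    flagged = fd > fd_threshold
    removed = flagged.copy()
    removed[:-1] |= flagged[1:]
    removed[1:] |= flagged[:-1]
    keep &= ~removed

    n_post = max(t - drop_first, 1)
    removed_frac = float((removed & (np.arange(t) >= drop_first)).sum()) / n_post
    return keep, bool(removed_frac > max_removed_frac), removed_frac


def bandpass(data, tr: float, low: float = BAND_HZ[0], high: float = BAND_HZ[1]) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0 (order 3, forward-backward)."""
    data = np.asarray(data, dtype=float)
    nyq = 0.5 / tr
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq}) Hz")
    sos = signal.butter(3, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, data - data.mean(axis=0), axis=0)


def nuisance_regress(data, regressors) -> np.ndarray:
    """Per-region OLS residuals against the regressors (intercept added).

    Raises on rank-deficient designs, naming the offending columns.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    t, m = reg.shape
    if data.shape[0] != t:
        raise ValueError("data and regressors must share the time axis")
    if t <= m + 1:
        raise ValueError("need more time points than regressors")
    design = np.column_stack([np.ones(t), reg])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            j - 1
            for j in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient nuisance design; redundant columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def preprocess_run(
    run: RoiRun,
    fd_threshold: float = FD_THRESHOLD_MM,
    drop_first: int = DROP_FIRST,
    max_removed_frac: float = MAX_REMOVED_FRAC,
    band: tuple[float, float] = BAND_HZ,
    radius_mm: float = FD_RADIUS_MM,
) -> RoiRun:
    """Full temporal preprocessing of one run.

    Order: steady-state trim -> FD scrubbing -> linear interpolation across
    censored volumes -> zero-phase band-pass -> re-censoring -> regression of
    motion + nuisance signals (band-passed identically). Censored volumes are
    interpolated before filtering so gaps do not leak spectrally, then dropped
    again before regression and correlation. Returns a new ``RoiRun`` whose
    ``data`` holds the cleaned, censored series (kept volumes only) or an
    excluded run.
    """
    fd = compute_fd(run.motion, radius_mm=radius_mm)
    keep, excluded, frac = censor_volumes(fd, fd_threshold, drop_first, max_removed_frac)
    if excluded:
        return replace(
            run,
            keep_mask=keep,
            excluded=True,
            exclusion_reason=f"{frac:.1%} of volumes removed by motion scrubbing",
        )

    post = slice(drop_first, None)
    kept_post = keep[post]
    idx = np.arange(kept_post.size)

    def _interp(block: np.ndarray) -> np.ndarray:
        block = block[post].copy()
        if not kept_post.all():
            good = idx[kept_post]
            for col in range(block.shape[1]):
                block[~kept_post, col] = np.interp(idx[~kept_post], good, block[good, col])
        return block

    data = bandpass(_interp(run.data), run.tr, *band)[kept_post]
    reg = bandpass(_interp(np.column_stack([run.motion, run.nuisance])), run.tr, *band)[kept_post]
    # constant channels (e.g. motion-free phantoms) carry no nuisance signal
    reg = reg[:, reg.std(axis=0) > 1e-12]
    cleaned = nuisance_regress(data, reg) if reg.shape[1] else data - data.mean(axis=0)
    return replace(
        run,
        data=cleaned,
        motion=run.motion[keep],
        nuisance=run.nuisance[keep],
        keep_mask=keep,
        excluded=False,
    )


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric R x R Pearson and Fisher-z connectivity for one subject."""

    subject_id: str
    r: np.ndarray
    z: np.ndarray
    region_labels: tuple[str, ...] | None = None


def rsfc_matrix(run: RoiRun) -> ConnectivityMatrix:
    """Pearson correlation of regionally averaged BOLD over the kept volumes,
    with the Fisher-z (atanh) counterpart; r clipped to +/-(1 - 1e-12) first."""
    if run.excluded:
        raise ValueError(f"run {run.run_id} was excluded: {run.exclusion_reason}")
    data = run.data
    if data.shape[0] < MIN_KEPT_VOLUMES:
        raise ValueError(f"fewer than {MIN_KEPT_VOLUMES} kept volumes")
    sd = data.std(axis=0)
    flat = sd <= 1e-10 * np.maximum(np.abs(data.mean(axis=0)), 1.0)
    if np.any(flat):
        raise ValueError(f"zero-variance regions: {list(np.flatnonzero(flat))}")
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(run.subject_id, r=r, z=z, region_labels=run.region_labels)


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) edge indices; R regions yield R(R-1)/2 edges."""
    return np.triu_indices(n_regions, k=1)


def _stack_edges(z_matrices) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    zs = np.asarray([m.z if isinstance(m, ConnectivityMatrix) else m for m in z_matrices], dtype=float)
    if zs.ndim != 3 or zs.shape[1] != zs.shape[2]:
        raise ValueError("z_matrices must be n_subjects square matrices")
    iu, ju = edge_index(zs.shape[1])
    return zs[:, iu, ju], iu, ju


def _corr_p(t_stat: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * sps.t.sf(np.abs(t_stat), df)


def edgewise_behavior_screen(z_matrices, behavior, alpha: float = 0.05) -> pd.DataFrame:
    """Brain-wide edge-vs-behavior correlation screen.

    For each of the R(R-1)/2 edges, Pearson r between the subjects' Fisher-z
    connectivity and the behavior score, the two-sided p from the t-transform
    with n-2 df, and BH-FDR q across all edges. Returns a DataFrame with
    columns ``region_i, region_j, r, p, q, significant, sign`` sorted by edge
    index.
    """
    x, iu, ju = _stack_edges(z_matrices)
    y = np.asarray(behavior, dtype=float).ravel()
    n = x.shape[0]
    if y.size != n:
        raise ValueError("one behavior score per subject required")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(y) == 0:
        raise ValueError("behavior scores are constant")

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = _corr_p(t_stat, n - 2)
    rejected, q = bh_fdr(p, alpha=alpha)
    return pd.DataFrame(
        {
            "region_i": iu,
            "region_j": ju,
            "r": r,
            "p": p,
            "q": q,
            "significant": rejected,
            "sign": np.sign(r).astype(int),
        }
    )


def group_edge_difference(z_matrices, labels, alpha: float = 0.01) -> pd.DataFrame:
    """Per-edge two-sample (pooled) t of Fisher-z values between two groups,
    BH-FDR corrected across edges. ``labels`` must contain exactly two levels;
    the sign convention is first-level minus second-level (sorted order)."""
    x, iu, ju = _stack_edges(z_matrices)
    labels = np.asarray(labels)
    if labels.size != x.shape[0]:
        raise ValueError("one label per subject required")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a, b = x[labels == levels[0]], x[labels == levels[1]]
    na, nb = a.shape[0], b.shape[0]
    if min(na, nb) < 2:
        raise ValueError("need >= 2 subjects per group")
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    if np.any(sp2 == 0):
        bad = np.flatnonzero(sp2 == 0)
        raise ValueError(f"zero pooled variance at edges {list(bad[:5])}")
    t_stat = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = _corr_p(t_stat, na + nb - 2)
    rejected, q = bh_fdr(p, alpha=alpha)
    return pd.DataFrame(
        {
            "region_i": iu,
            "region_j": ju,
            "delta_z": diff,
            "t": t_stat,
            "p": p,
            "q": q,
            "significant": rejected,
            "sign": np.sign(diff).astype(int),
        }
    )


@dataclass(frozen=True)
class BatchAdjustedEffect:
    estimate: float  # group fixed effect on Fisher-z (first minus second level)
    se: float
    p: float
    n_batches: int
    model: str


def batch_adjusted_effect(z_values, group, batch) -> BatchAdjustedEffect:
    """Group effect on one edge's Fisher-z with a random intercept per batch.

    Fitted by REML with statsmodels' linear mixed model. With a single batch
    the random intercept is unidentifiable and the estimator reduces exactly
    to the OLS group-mean difference.
    """
    z = np.asarray(z_values, dtype=float).ravel()
    group = np.asarray(group)
    batch = np.asarray(batch)
    if not (z.size == group.size == batch.size):
        raise ValueError("z_values, group and batch must be aligned")
    levels = sorted(set(group.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g = (group == levels[0]).astype(float)  # effect = first minus second level

    n_batches = len(set(batch.tolist()))
    if n_batches == 1:
        from .stats import two_sample_t

        res = two_sample_t(z[g == 1], z[g == 0])
        est = float(z[g == 1].mean() - z[g == 0].mean())
        se = est / res.statistic if res.statistic != 0 else np.nan
        return BatchAdjustedEffect(est, float(abs(se)), res.p, 1, "ols")

    import statsmodels.api as sm

    exog = sm.add_constant(g)
    fit = sm.MixedLM(z, exog, groups=batch).fit(reml=True)
    return BatchAdjustedEffect(
        estimate=float(np.asarray(fit.params)[1]),
        se=float(np.asarray(fit.bse)[1]),
        p=float(np.asarray(fit.pvalues)[1]),
        n_batches=n_batches,
        model="mixedlm_reml",
    )


def seed_profile(z_matrices, seed_region: int, alpha: float = 0.05) -> pd.DataFrame:
    """ROI-level seed connectivity profile across subjects.

    For every non-seed region: mean Fisher-z with the seed, a one-sample t
    against 0, and BH-FDR across the R-1 regions.
    """
    zs = np.asarray([m.z if isinstance(m, ConnectivityMatrix) else m for m in z_matrices], dtype=float)
    n, r_regions = zs.shape[0], zs.shape[1]
    if not 0 <= seed_region < r_regions:
        raise ValueError("seed region outside the parcellation")
    rows = zs[:, seed_region, :]  # n x R, NaN at the seed itself
    others = np.delete(np.arange(r_regions), seed_region)
    vals = rows[:, others]
    mean_z = vals.mean(axis=0)
    t_stat, p = sps.ttest_1samp(vals, 0.0, axis=0)
    rejected, q = bh_fdr(p, alpha=alpha)
    return pd.DataFrame(
        {
            "region": others,
            "mean_z": mean_z,
            "t": t_stat,
            "p": p,
            "q": q,
            "significant": rejected,
        }
    )
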