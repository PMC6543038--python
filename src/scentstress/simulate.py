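"""Seeded synthetic-cohort generators with planted ground truth.

Every generator is a pure function of (config, seed): a fresh
``numpy.random.default_rng(seed)`` is created per call and no global state is
touched, so identical inputs give bit-identical outputs.

The tracking generator uses a two-state (mobile/freeze) semi-Markov bout
process whose freeze occupancy is phenotype specific, with an
Ornstein-Uhlenbeck position process whose attractor sits away from the scent
pad for exposed phenotypes. The BOLD generator uses a latent-factor
construction: a global factor sets the baseline pairwise correlation and one
extra factor per coupled edge sets that pair's target correlation
tanh(mu + beta * z_score + trait scatter) exactly, on top of slow drift,
high-frequency contamination, shared nuisance channels and spiking motion
traces so that filtering, regression and scrubbing are all consequential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import Arena, EPMResult, TrackingTrace
from .config import PHENOTYPES, SyntheticConfig
from .connectome import RoiRun
from .endocrine import CortProfile

ADAPTATION_S = 120.0
EXPOSURE_S = 600.0
EPM_SESSION_S = 300.0
FREEZE_BOUT_MIN_S = 2.5
FREEZE_BOUT_MEAN_S = 6.0
# central-difference speed trims ~1 frame off each bout edge at 10 Hz
BOUT_EDGE_LOSS_S = 0.2

__all__ = [
    "simulate_tracking",
    "simulate_cort",
    "simulate_epm",
    "simulate_roi_runs",
    "simulate_cohort",
    "make_parcellation",
    "Cohort",
]


def _check_phenotype(phenotype: str) -> None:
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")


def _bout_schedule(rng, total_s: float, freeze_frac: float) -> list[tuple[bool, float]]:
    """Alternating (is_freeze, duration_s) bouts filling ``total_s``.

    Gamma bout durations (shape 8) are drawn around phenotype-specific means,
    then both states' durations are rescaled so that the session's freezing
    occupancy — after the ~1-frame edge loss the central-difference speed
    introduces at each bout boundary — matches ``freeze_frac``.
    """
    freeze_frac = float(np.clip(freeze_frac, 0.02, 0.95))
    mu_f = FREEZE_BOUT_MEAN_S
    mu_m = max(0.3, (mu_f - BOUT_EDGE_LOSS_S) / freeze_frac - mu_f)
    bouts: list[tuple[bool, float]] = []
    t = 0.0
    freezing = False  # sessions start mobile
    while t < total_s:
        if freezing:
            dur = FREEZE_BOUT_MIN_S + rng.gamma(8.0, (mu_f - FREEZE_BOUT_MIN_S) / 8.0)
        else:
            dur = 0.3 + rng.gamma(8.0, max(mu_m - 0.3, 1e-6) / 8.0)
        bouts.append((freezing, dur))
        t += dur
        freezing = not freezing

    # rescale so detected freezing (freeze time minus edge loss) hits target
    f_tot = sum(d for fz, d in bouts if fz)
    m_tot = sum(d for fz, d in bouts if not fz)
    n_f = sum(1 for fz, _ in bouts if fz)
    if f_tot > 0 and m_tot > 0:
        c = float(np.clip((freeze_frac * t + BOUT_EDGE_LOSS_S * n_f) / f_tot, 0.85, 1.4))
        d = (t - c * f_tot) / m_tot
        if d > 0:
            bouts = [(fz, (c if fz else d) * dur) for fz, dur in bouts]

    out: list[tuple[bool, float]] = []
    t = 0.0
    for fz, dur in bouts:
        dur = min(dur, total_s - t)
        if dur <= 0:
            break
        out.append((fz, dur))
        t += dur
    return out


def simulate_tracking(
    config: SyntheticConfig,
    phenotype: str,
    seed: int,
    subject_id: str = "sim",
    target_freezing_pct: float | None = None,
) -> TrackingTrace:
    """One 12-min arena trace: 2 min adaptation then 10 min scent exposure.

    ``target_freezing_pct`` overrides the phenotype's mean exposure-phase
    freezing fraction (used by the cohort generator to plant per-subject
    scores). Exposed phenotypes drift away from the pad end of the 45 cm cage;
    controls wander around the midpoint.
    """
    _check_phenotype(phenotype)
    rng = np.random.default_rng(seed)
    rate = config.tracking_rate_hz
    dt = 1.0 / rate
    arena = Arena()

    if target_freezing_pct is None:
        target_freezing_pct = config.freezing_targets[phenotype].mean
    adapt_frac = config.freezing_targets["control"].mean / 100.0

    # positional attractors along the pad axis (pad at x = 45)
    mid = arena.length_cm / 2.0
    attractor = {"control": mid, "high": 14.0, "low": 8.0}[phenotype]

    segments = [
        ("adaptation", ADAPTATION_S, adapt_frac, mid),
        ("exposure", EXPOSURE_S, target_freezing_pct / 100.0, attractor),
    ]

    xs, ys, phases = [], [], []
    x, y = mid, arena.width_cm / 2.0
    k_rev, sigma_x, sigma_y = 0.5, 2.0, 1.2
    for phase, total_s, frac, mu_x in segments:
        n_frames = int(round(total_s * rate))
        frame_states = np.zeros(n_frames, dtype=bool)
        pos = 0
        for is_freeze, dur in _bout_schedule(rng, total_s, frac):
            nf = int(round(dur * rate))
            nf = min(nf, n_frames - pos)
            frame_states[pos : pos + nf] = is_freeze
            pos += nf
            if pos >= n_frames:
                break
        jitter = rng.normal(0.0, 0.01, size=(n_frames, 2))
        steps = rng.normal(0.0, 1.0, size=(n_frames, 2))
        for i in range(n_frames):
            if frame_states[i]:
                nx, ny = x + jitter[i, 0], y + jitter[i, 1]
            else:
                nx = x + k_rev * (mu_x - x) * dt + sigma_x * np.sqrt(dt) * steps[i, 0]
                ny = y + k_rev * (arena.width_cm / 2.0 - y) * dt + sigma_y * np.sqrt(dt) * steps[i, 1]
            x = float(np.clip(nx, 0.0, arena.length_cm))
            y = float(np.clip(ny, 0.0, arena.width_cm))
            xs.append(x)
            ys.append(y)
            phases.append(phase)

    return TrackingTrace(
        subject_id=subject_id,
        rate=rate,
        x=np.array(xs),
        y=np.array(ys),
        phase=np.array(phases, dtype=object),
        arena=arena,
    )


def simulate_cort(
    phenotype: str, config: SyntheticConfig, seed: int, subject_id: str = "sim"
) -> CortProfile:
    """Four-point CORT profile: configured phenotype means plus Gaussian noise,
    clipped at zero."""
    _check_phenotype(phenotype)
    if config.cort_noise_sd < 0:
        raise ValueError("negative noise sd")
    rng = np.random.default_rng(seed)
    means = np.asarray(config.cort_means[phenotype], dtype=float)
    conc = np.clip(means + rng.normal(0.0, config.cort_noise_sd, size=4), 0.0, None)
    return CortProfile(subject_id=subject_id, conc_ng_ml=tuple(conc))


def simulate_epm(
    phenotype: str, config: SyntheticConfig, seed: int, subject_id: str = "sim"
) -> EPMResult:
    """A 300 s elevated-plus-maze session with the configured open-arm score."""
    _check_phenotype(phenotype)
    rng = np.random.default_rng(seed)
    spec = config.epm_score[phenotype]
    score = float(np.clip(rng.normal(spec.mean, spec.sd), 0.01, 0.95))
    center = float(np.clip(rng.normal(config.epm_center_s.mean, config.epm_center_s.sd), 5.0, 90.0))
    open_s = score * (EPM_SESSION_S - center)
    return EPMResult(
        subject_id=subject_id,
        open_s=open_s,
        closed_s=EPM_SESSION_S - center - open_s,
        center_s=center,
    )


def _edge_loading(r_target: float) -> tuple[float, float]:
    """Loading magnitude and sign for a shared pair factor achieving pairwise
    correlation ``r_target`` between two unit-noise regions: loadings
    (b, s*b) give correlation s * b^2 / (1 + b^2)."""
    r = float(np.clip(r_target, -0.95, 0.95))
    b2 = abs(r) / (1.0 - abs(r))
    sign = 1.0 if r >= 0 else -1.0
    return float(np.sqrt(b2)), sign


def simulate_roi_runs(
    config: SyntheticConfig,
    behavior_scores,
    seed: int,
    subject_ids: list[str] | None = None,
    batches: list[str] | None = None,
) -> list[RoiRun]:
    """Per-subject T x R BOLD runs whose coupled-edge connectivity tracks the
    behavior score.

    At a coupled edge e the subject's target Pearson correlation is
    tanh(mu_e + beta_e * standardized score + trait scatter), clipped to
    +/-0.95; all other pairs share the configured baseline. Slow drift,
    high-frequency contamination, shared white-matter/ventricle channels and
    Poisson-placed motion spikes are superimposed so that every preprocessing
    step has work to do.
    """
    roi = config.roi
    scores = np.asarray(behavior_scores, dtype=float).ravel()
    n_sub = scores.size
    if subject_ids is None:
        subject_ids = [f"sub{i:03d}" for i in range(n_sub)]
    if len(subject_ids) != n_sub:
        raise ValueError("one behavior score per subject required")
    if batches is None:
        batches = [f"batch{i % config.n_batches}" for i in range(n_sub)]
    if len(batches) != n_sub:
        raise ValueError("one batch label per subject required")

    z_scores = (scores - scores.mean()) / scores.std() if scores.std() > 0 else np.zeros(n_sub)
    rng = np.random.default_rng(seed)
    t_len, n_reg = roi.n_volumes, roi.n_regions
    a2 = roi.baseline_r / (1.0 - roi.baseline_r)
    a = np.sqrt(a2)
    labels = tuple(make_parcellation(n_reg)["label"])
    times = np.arange(t_len) * roi.tr
    # coupled regions stay off the global baseline factor so their variance,
    # which tracks the behavior score through the pair loading, cannot leak a
    # score dependence into edges incident to them
    coupled_regions = np.zeros(n_reg, dtype=bool)
    for (i, j), _beta in roi.coupled_edges:
        coupled_regions[[i, j]] = True

    runs: list[RoiRun] = []
    for s in range(n_sub):
        data = rng.standard_normal((t_len, n_reg))
        data[:, ~coupled_regions] += a * rng.standard_normal(t_len)[:, None]
        for (i, j), beta in roi.coupled_edges:
            z_target = roi.edge_mu_z + beta * z_scores[s] + rng.normal(0.0, roi.edge_scatter_sd)
            b, sign = _edge_loading(np.tanh(z_target))
            f = rng.standard_normal(t_len)
            data[:, i] += b * f
            data[:, j] += sign * b * f

        # slow drift (<0.01 Hz) and high-frequency (>0.1 Hz) contamination
        f_lo = rng.uniform(0.002, 0.008, size=n_reg)
        f_hi = rng.uniform(0.2, 0.4, size=n_reg)
        ph = rng.uniform(0, 2 * np.pi, size=(2, n_reg))
        data += roi.drift_amp * np.sin(2 * np.pi * times[:, None] * f_lo + ph[0])
        data += roi.hf_amp * np.sin(2 * np.pi * times[:, None] * f_hi + ph[1])

        # shared nuisance channels (white matter / ventricles): smooth in-band
        kernel = np.exp(-0.5 * (np.arange(-15, 16) / 5.0) ** 2)
        kernel /= kernel.sum()
        nuisance = np.column_stack(
            [
                np.convolve(rng.standard_normal(t_len + 30), kernel, mode="valid")[:t_len]
                for _ in range(roi.n_nuisance)
            ]
        )
        nuisance /= nuisance.std(axis=0)
        loadings = rng.normal(roi.nuisance_amp, 0.1, size=(roi.n_nuisance, n_reg))
        data += nuisance @ loadings

        # motion: small jitter plus sparse one-volume translation spikes
        motion = np.cumsum(
            np.column_stack(
                [
                    rng.normal(0.0, roi.motion_jitter_mm, size=(t_len, 3)),
                    rng.normal(0.0, roi.rotation_jitter_rad, size=(t_len, 3)),
                ]
            ),
            axis=0,
        )
        spikes = np.flatnonzero(rng.random(t_len - 1) < roi.spike_rate) + 1
        amps = rng.uniform(*roi.spike_amp_mm, size=spikes.size) * rng.choice([-1.0, 1.0], spikes.size)
        motion[spikes, 0] += amps  # out-and-back: two FD exceedances per spike

        runs.append(
            RoiRun(
                subject_id=subject_ids[s],
                run_id=f"{subject_ids[s]}_run1",
                batch_id=batches[s],
                tr=roi.tr,
                data=data,
                motion=motion,
                nuisance=nuisance,
                region_labels=labels,
            )
        )
    return runs


_NAMED_REGIONS = [
    "ACC", "AON", "PBn", "BNST", "LS", "MS", "PL", "HT", "NAc", "ZI",
    "GP", "PVN", "AI", "AOB", "nLOT", "Amygdala", "CortAmygdala", "OB",
    "Postsubiculum", "AuditoryCtx", "VisualCtx", "VisceralCtx", "Pituitary",
    "Hippocampus",
]
_SYSTEMS = [
    "prefrontal", "olfactory", "brainstem", "extended amygdala", "septal",
    "septal", "prefrontal", "hypothalamic", "striatal", "subthalamic",
    "striatal", "hypothalamic", "insular", "olfactory", "olfactory",
    "amygdalar", "amygdalar", "olfactory", "hippocampal", "sensory",
    "sensory", "sensory", "endocrine", "hippocampal",
]


def make_parcellation(n_regions: int = 67) -> pd.DataFrame:
    """Region id / label / brain-system table for the synthetic parcellation."""
    labels, systems = [], []
    for i in range(n_regions):
        if i < len(_NAMED_REGIONS):
            labels.append(_NAMED_REGIONS[i])
            systems.append(_SYSTEMS[i])
        else:
            labels.append(f"region{i:02d}")
            systems.append(["cortical", "subcortical", "brainstem"][i % 3])
    return pd.DataFrame({"region_id": range(n_regions), "label": labels, "system": systems})


@dataclass
class Cohort:
    """A complete synthetic cohort with its planted ground truth."""

    config: SyntheticConfig
    subjects: pd.DataFrame  # subject_id, group, phenotype_true, batch, freezing_target_pct
    traces: dict[str, TrackingTrace] = field(default_factory=dict)
    cort: dict[str, CortProfile] = field(default_factory=dict)
    epm: dict[str, EPMResult] = field(default_factory=dict)
    runs: list[RoiRun] = field(default_factory=list)


def simulate_cohort(
    config: SyntheticConfig,
    seed: int | None = None,
    with_roi: bool = True,
) -> Cohort:
    """Generate the full cohort: traces, CORT, EPM and (optionally) BOLD runs.

    Exposed animals draw their phenotype (low with probability
    ``phenotype_mix``) and a per-subject freezing target from the phenotype's
    Normal spec; the same target couples the subject's BOLD edges.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(config.n_control + config.n_exposed):
        if i < config.n_control:
            group, ph = "control", "control"
        else:
            group = "exposed"
            ph = "low" if rng.random() < config.phenotype_mix else "high"
        spec = config.freezing_targets[ph]
        target = float(np.clip(rng.normal(spec.mean, spec.sd), 2.0, 95.0))
        rows.append(
            {
                "subject_id": f"sub{i:03d}",
                "group": group,
                "phenotype_true": ph,
                "batch": f"batch{i % config.n_batches}",
                "freezing_target_pct": target,
            }
        )
    subjects = pd.DataFrame(rows)

    cohort = Cohort(config=config, subjects=subjects)
    child = np.random.SeedSequence(seed).spawn(3 * len(subjects) + 1)
    for k, row in subjects.iterrows():
        sid, ph = row.subject_id, row.phenotype_true
        cohort.traces[sid] = simulate_tracking(
            config, ph, _small_seed(child[3 * k]), sid, target_freezing_pct=row.freezing_target_pct
        )
        cohort.cort[sid] = simulate_cort(ph, config, _small_seed(child[3 * k + 1]), sid)
        cohort.epm[sid] = simulate_epm(ph, config, _small_seed(child[3 * k + 2]), sid)

    if with_roi:
        cohort.runs = simulate_roi_runs(
            config,
            subjects["freezing_target_pct"].to_numpy(),
            _small_seed(child[-1]),
            subject_ids=list(subjects["subject_id"]),
            batches=list(subjects["batch"]),
        )
    return cohort


def _small_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, np.uint32)[0])
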