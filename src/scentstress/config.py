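"""Configuration objects for the synthetic cohort generator and the pipeline.

The synthetic defaults emulate the study conditions: a main cohort of 23
controls and 62 scent-exposed animals whose freezing times form a 50/50
bimodal mixture, flat control corticosterone versus a transient (high-freezer)
or prolonged (low-freezer) response, elevated-plus-maze scores lowest in
low-freezers, and 67-region / 2400-volume BOLD runs (TR = 1 s) in which 15
edges' connectivity is linearly coupled to each animal's freezing score.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

PHENOTYPES = ("control", "low", "high")

__all__ = ["PHENOTYPES", "NormalSpec", "RoiParams", "SyntheticConfig", "default_coupled_edges"]


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def default_coupled_edges(
    n_regions: int = 67,
    n_coupled: int = 15,
    slope: float = 0.085,
    n_positive: int = 6,
) -> tuple[tuple[tuple[int, int], float], ...]:
    """Disjoint region pairs carrying behavior-coupled connectivity.

    6 positively and 9 negatively coupled edges by default, mirroring the
    direction split of the freezing-associated circuits.
    """
    if 2 * n_coupled > n_regions:
        raise ValueError("not enough regions for disjoint coupled pairs")
    return tuple(
        ((2 * k, 2 * k + 1), slope if k < n_positive else -slope)
        for k in range(n_coupled)
    )


@dataclass(frozen=True)
class RoiParams:
    """Ground-truth parameters of the synthetic BOLD generator."""

    n_regions: int = 67
    n_volumes: int = 2400
    tr: float = 1.0  # s
    baseline_r: float = 0.10  # uncoupled-pair Pearson correlation
    coupled_edges: tuple[tuple[tuple[int, int], float], ...] = field(
        default_factory=default_coupled_edges
    )
    edge_mu_z: float = 0.25  # mean Fisher-z at coupled edges
    edge_scatter_sd: float = 0.12  # per-subject trait scatter around mu + beta*z
    spike_rate: float = 0.01  # motion spikes per volume
    spike_amp_mm: tuple[float, float] = (0.3, 0.5)
    motion_jitter_mm: float = 0.005
    rotation_jitter_rad: float = 0.0005
    drift_amp: float = 0.5  # slow (<0.01 Hz) sinusoidal drift amplitude
    hf_amp: float = 0.3  # high-frequency (>0.1 Hz) contamination amplitude
    nuisance_amp: float = 0.3  # mean loading of WM/ventricle channels
    n_nuisance: int = 2

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_volumes < 1:
            raise ValueError("need >= 2 regions and >= 1 volume")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not 0 <= self.baseline_r < 1:
            raise ValueError("baseline correlation must lie in [0, 1)")
        seen: set[int] = set()
        for (i, j), _slope in self.coupled_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions) or i == j:
                raise ValueError(f"coupled edge ({i}, {j}) invalid for {self.n_regions} regions")
            if i in seen or j in seen:
                raise ValueError("coupled edges must use disjoint region pairs")
            seen.update((i, j))


def _default_freezing() -> dict[str, NormalSpec]:
    return {
        "control": NormalSpec(15.0, 6.0),
        "low": NormalSpec(20.0, 10.0),
        "high": NormalSpec(60.0, 10.0),
    }


def _default_cort() -> dict[str, tuple[float, float, float, float]]:
    # ng/ml at 0/30/60/120 min; baselines are generator placeholders
    return {
        "control": (50.0, 50.0, 50.0, 50.0),
        "high": (50.0, 150.0, 60.0, 52.0),
        "low": (50.0, 150.0, 140.0, 65.0),
    }


def _default_epm() -> dict[str, NormalSpec]:
    return {
        "control": NormalSpec(0.35, 0.08),
        "low": NormalSpec(0.20, 0.08),
        "high": NormalSpec(0.35, 0.08),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the synthetic cohort; identical config + seed
    yields bit-identical outputs."""

    seed: int = 0
    n_control: int = 23
    n_exposed: int = 62
    phenotype_mix: float = 0.5  # proportion of low freezers among exposed
    freezing_targets: dict[str, NormalSpec] = field(default_factory=_default_freezing)
    cort_means: dict[str, tuple[float, float, float, float]] = field(default_factory=_default_cort)
    cort_noise_sd: float = 15.0
    epm_score: dict[str, NormalSpec] = field(default_factory=_default_epm)
    epm_center_s: NormalSpec = field(default_factory=lambda: NormalSpec(30.0, 8.0))
    roi: RoiParams = field(default_factory=RoiParams)
    n_batches: int = 3
    tracking_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_exposed < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0 <= self.phenotype_mix <= 1:
            raise ValueError("phenotype_mix must lie in [0, 1]")
        if self.cort_noise_sd < 0:
            raise ValueError("CORT noise sd must be non-negative")
        if self.tracking_rate_hz <= 0:
            raise ValueError("tracking rate must be positive")
        for ph in PHENOTYPES:
            if ph not in self.freezing_targets or ph not in self.cort_means or ph not in self.epm_score:
                raise ValueError(f"phenotype {ph!r} missing from configured targets")
            if len(self.cort_means[ph]) != 4:
                raise ValueError("CORT means need the four time points 0/30/60/120 min")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi"]["coupled_edges"] = [
            [int(i), int(j), float(s)] for (i, j), s in self.roi.coupled_edges
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key, factory in (("freezing_targets", NormalSpec), ("epm_score", NormalSpec)):
            if key in d:
                d[key] = {k: NormalSpec(**v) if isinstance(v, dict) else v for k, v in d[key].items()}
        if "cort_means" in d:
            d["cort_means"] = {k: tuple(v) for k, v in d["cort_means"].items()}
        if "epm_center_s" in d and isinstance(d["epm_center_s"], dict):
            d["epm_center_s"] = NormalSpec(**d["epm_center_s"])
        if "roi" in d and isinstance(d["roi"], dict):
            roi = dict(d["roi"])
            if "coupled_edges" in roi:
                roi["coupled_edges"] = tuple(
                    ((int(i), int(j)), float(s)) for i, j, s in roi["coupled_edges"]
                )
            if "spike_amp_mm" in roi:
                roi["spike_amp_mm"] = tuple(roi["spike_amp_mm"])
            d["roi"] = RoiParams(**roi)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Short stable hash of the full configuration, for provenance headers."""
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)
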