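"""Central numerical tolerances and small configuration helpers.

All geometric quantities are in millimetres unless stated otherwise;
angular tolerances are in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Tolerances:
    """Numerical tolerances shared by the geometry and detection stages.

    geometric : mm — support-plane side test, mirror symmetry checks.
    angular   : rad — plane-normal normalisation and parallelism tests.
    degenerate_area : mm^2 — faces below this area are rejected.
    on_surface : mm — a landmark must lie this close to its mesh.
    manual_snap : mm — manually placed points further than this from the
        surface are rejected instead of snapped.
    """

    geometric: float = 1e-6
    angular: float = 1e-9
    degenerate_area: float = 1e-12
    on_surface: float = 1e-3
    manual_snap: float = 1.0


TOL = Tolerances()


def _ensure_known_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class StatsOptions:
    alpha: float = 0.05
    n_pairwise: int = 6  # four orientation groups -> 6 pairs

    @property
    def bonferroni_threshold(self) -> float:
        # stored at full precision (0.05/6 = 0.008333...)
        return self.alpha / self.n_pairwise


@dataclass
class ReportOptions:
    side: str = "L"  # unilateral parameters reported from the left side
    decimals: int = 2


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    out_dir: str = "mandigrow_out"
    seed: int = 0
    n_subjects: int = 4
    n_timepoints: int = 12
    resolution: int = 40000
    noise_sd: float = 0.0
    overwrite: bool = False
    stats: StatsOptions = field(default_factory=StatsOptions)
    report: ReportOptions = field(default_factory=ReportOptions)
    rois: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        allowed = {
            "out_dir", "seed", "n_subjects", "n_timepoints", "resolution",
            "noise_sd", "overwrite", "stats", "report", "rois",
        }
        _ensure_known_keys(d, allowed, "pipeline config")
        if "stats" in d:
            s = d.pop("stats")
            _ensure_known_keys(s, {"alpha", "n_pairwise"}, "stats")
            d["stats"] = StatsOptions(**s)
        if "report" in d:
            r = d.pop("report")
            _ensure_known_keys(r, {"side", "decimals"}, "report")
            d["report"] = ReportOptions(**r)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data)}")
        return cls.from_dict(data)
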