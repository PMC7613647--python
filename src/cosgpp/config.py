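"""Site configuration: column mapping, thresholds and model overrides."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml

from .lru import LRUCapParams

_KNOWN_KEYS = {
    "column_map", "ustar_threshold", "soil_cos_flux", "lru_model",
    "lru_const", "cap_params", "pressure_kpa", "window_days",
    "spring_months", "summer_months",
}


@dataclass
class SiteConfig:
    """All site-level knobs of the pipeline, loadable from YAML.

    ``column_map`` maps canonical names to the user's CSV headers.  Physical
    overrides are range-checked on load; unknown keys are rejected so typos
    fail loudly rather than silently keeping a default.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    ustar_threshold: float = 0.3
    soil_cos_flux: float = -2.7
    lru_model: str = "cap"
    lru_const: float = 1.6
    cap_params: LRUCapParams = field(default_factory=LRUCapParams)
    pressure_kpa: float = 101.325
    window_days: int = 15
    spring_months: tuple[int, ...] = (3, 4, 5)
    summer_months: tuple[int, ...] = (6, 7, 8)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ustar_threshold <= 2.0:
            raise ValueError("ustar_threshold outside [0, 2] m s-1")
        if not -10.0 <= self.soil_cos_flux <= 5.0:
            raise ValueError("soil_cos_flux outside the sanity band [-10, 5]")
        if self.lru_model not in {"par", "cap", "const"}:
            raise ValueError(f"unknown lru_model {self.lru_model!r}")
        if not 50.0 <= self.pressure_kpa <= 110.0:
            raise ValueError("pressure_kpa outside [50, 110]")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")


def load_config(path) -> SiteConfig:
    """Read a YAML site configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cap_raw = raw.pop("cap_params", None)
    cfg = SiteConfig(**{k: tuple(v) if k.endswith("_months") else v
                        for k, v in raw.items()})
    if cap_raw:
        valid = {f.name for f in fields(LRUCapParams)}
        bad = set(cap_raw) - valid
        if bad:
            raise ValueError(f"unknown cap_params key(s): {sorted(bad)}")
        cfg = replace(cfg, cap_params=LRUCapParams(**cap_raw))
    return cfg
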