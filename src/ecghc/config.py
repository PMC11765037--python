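"""Run configuration, packaged defaults and the audit config file.

``RunConfig`` carries every analysis parameter with the study defaults
(D = 4, tau = 2, 512 ms beat windows, 75% correlation gate, 20 uV / 20 ms
RMS gate, 30 s occlusion and 15 s recovery windows, alpha = 0.05).  The
packaged YAML also exposes the Kors matrix and the synthetic-generator
calibration for audit; any override of a default is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["RunConfig", "default_config", "generator_defaults", "ConfigError"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


def default_config() -> dict:
    """The packaged default configuration as a plain dict."""
    text = resources.files("ecghc").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def generator_defaults() -> dict:
    """Calibrated synthetic-generator parameters from the packaged config."""
    return default_config()["generator"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters for one study run.

    Defaults reproduce the reference protocol; overriding any of them is
    logged at construction.
    """

    D: int = 4
    tau: int = 2
    window_ms: float = 512.0
    xcorr_threshold: float = 0.75
    rms_limit_uv: float = 20.0
    pre_q_ms: float = 20.0
    occlusion_window_s: float = 30.0
    recovery_window_s: float = 15.0
    line_freq: float = 60.0
    alpha: float = 0.05
    seed: int = 0
    tie_jitter: float = 0.0
    pooled_pdf_windows: bool = False  # average PDFs instead of quantifiers
    paired_tests: bool = False
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if self.D < 2 or self.tau < 1:
            raise ConfigError("require D >= 2 and tau >= 1")
        if not 0 < self.xcorr_threshold < 1:
            raise ConfigError("xcorr_threshold must lie in (0, 1)")
        if min(self.window_ms, self.pre_q_ms, self.occlusion_window_s,
               self.recovery_window_s, self.line_freq) <= 0:
            raise ConfigError("durations and frequencies must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.default is not dataclasses.MISSING and v != f.default:
                log.info("config override: %s = %r (default %r)", f.name, v, f.default)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d.get("analysis", d))

    @property
    def config_hash(self) -> str:
        """Hash of every analysis parameter (changes iff a parameter changes)."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
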