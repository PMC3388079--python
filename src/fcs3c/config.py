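"""Run configuration: a single structured YAML block with strict keys.

Unknown keys anywhere in the file are rejected, so typos fail loudly
instead of silently running with defaults. Every pipeline run writes its
fully resolved configuration beside its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]

STAGES = (
    "simulate_curve",
    "simulate_gel",
    "fit",
    "refit_3d",
    "calibrate",
    "predict_tau",
    "equilibrium",
    "detect_limit",
    "threec_quant",
)

_BLOCK_KEYS: dict[str, set[str]] = {
    "simulate_curve": {"n", "tau_d", "n2", "tau_d2", "sigma0", "lag_power", "grid"},
    "simulate_gel": {
        "true_ratio",
        "primer_efficiencies",
        "condition_scales",
        "noise_cv",
        "replicates",
        "masses",
    },
    "fit": {"model_id", "weighted", "fit_range", "fit_baseline", "structure_param"},
    "refit_3d": {"structure_param"},
    "calibrate": {"dye", "d", "tau_d"},
    "predict_tau": {
        "mass_kda",
        "omega_nm",
        "temperature",
        "viscosity",
        "partial_specific_volume",
        "hydration",
        "dna_rise",
        "dna_scaling_exponent",
        "component_tau_ds",
    },
    "equilibrium": {"c_total", "kd"},
    "detect_limit": {
        "c_total",
        "kd",
        "tau_d_monomer",
        "tau_d_dimer",
        "n_total",
        "kd_grid",
        "measured_tau_d",
        "measured_sd",
        "sigma_threshold",
    },
    "threec_quant": {
        "test_pair",
        "control_pair",
        "numerator_condition",
        "denominator_condition",
        "linearity_threshold",
    },
}

_TOP_KEYS = {"stages", "seed", "outdir", "verbose", "curve_file", "bands_file"} | set(
    _BLOCK_KEYS
)


@dataclass
class RunConfig:
    """Pipeline configuration; block dicts feed the matching stages."""

    stages: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str = "fcs3c_out"
    verbose: bool = False
    curve_file: str | None = None
    bands_file: str | None = None
    blocks: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(
                f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}"
            )
        for block, params in self.blocks.items():
            if block not in _BLOCK_KEYS:
                raise ConfigurationError(f"unknown config block {block!r}")
            bad = set(params) - _BLOCK_KEYS[block]
            if bad:
                raise ConfigurationError(
                    f"unknown key(s) {sorted(bad)} in block {block!r}; "
                    f"allowed: {sorted(_BLOCK_KEYS[block])}"
                )

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        bad = set(raw) - _TOP_KEYS
        if bad:
            raise ConfigurationError(
                f"unknown top-level config key(s): {sorted(bad)}"
            )
        blocks = {k: dict(v) for k, v in raw.items() if k in _BLOCK_KEYS}
        return cls(
            stages=list(raw.get("stages", [])),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "fcs3c_out")),
            verbose=bool(raw.get("verbose", False)),
            curve_file=raw.get("curve_file"),
            bands_file=raw.get("bands_file"),
            blocks=blocks,
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        blocks = d.pop("blocks")
        d.update(blocks)
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)
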