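"""Pipeline configuration: every numeric threshold in one place.

Defaults reproduce the stringent protocol; the relaxed variant raises only
the H3K27ac peak-sharing ceiling from 3 to 4 comparison cell types.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


@dataclass
class Config:
    # association thresholds
    gwas_p_threshold: float = 5e-8
    ebmd_imputed_p_threshold: float = 6.6e-9
    # LD expansion
    r2_threshold: float = 0.8
    proxy_search_window_bp: int = 500_000
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    # chromatin filtering
    strong_states: frozenset[int] = frozenset({1, 3, 8, 9})
    state_max_other: int = 3
    k27ac_max_other: int = 3  # relaxed protocol: 4
    state_label_window_bp: int = 200
    # gene prioritization
    expr_ratio_min: float = 5.0
    expr_focal_min_rpkm: float = 1.0
    excluded_genes: tuple[str, ...] = ()
    # TFBS prediction
    tf_min_rpkm: float = 0.8
    tfbs_window: int = 21
    tfbs_fold_min: float = 5.0
    partial_match_min_frac: float = 0.2
    conserved_prob_min: float = 0.85
    partly_conserved_prob_min: float = 0.5
    pwm_pseudocount: float = 0.01
    # imputed augmentation
    imputed_locus_buffer_bp: int = 500_000
    # cell-type panels
    focal_cell_type: str = "ostb"
    chromatin_comparison_cell_types: tuple[str, ...] = ()
    expression_comparison_cell_types: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gwas_p_threshold", "ebmd_imputed_p_threshold", "r2_threshold",
            "proxy_search_window_bp", "expr_ratio_min", "expr_focal_min_rpkm",
            "tf_min_rpkm", "tfbs_window", "tfbs_fold_min",
            "partial_match_min_frac", "conserved_prob_min",
            "partly_conserved_prob_min", "imputed_locus_buffer_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")
        if self.tfbs_window % 2 == 0:
            raise ValueError("tfbs_window must be odd")
        if not isinstance(self.strong_states, frozenset):
            object.__setattr__(self, "strong_states", frozenset(self.strong_states))

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)


def load_config(path) -> Config:
    """Read a TOML config file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "strong_states" in raw:
        raw["strong_states"] = frozenset(int(s) for s in raw["strong_states"])
    for key in ("chromatin_comparison_cell_types",
                "expression_comparison_cell_types", "excluded_genes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return Config(**raw)


def dump_config(config: Config, path) -> None:
    """Write a config as TOML (round-trips through load_config)."""
    lines = []
    for f in dataclasses.fields(Config):
        value = getattr(config, f.name)
        if isinstance(value, frozenset):
            value = sorted(value)
        if isinstance(value, tuple):
            value = list(value)
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, (int, float)):
            rendered = repr(value)
        elif isinstance(value, str):
            rendered = f'"{value}"'
        elif isinstance(value, list):
            rendered = "[" + ", ".join(
                f'"{v}"' if isinstance(v, str) else repr(v) for v in value
            ) + "]"
        else:  # pragma: no cover - no other field types exist
            raise TypeError(f"cannot render config field {f.name}")
        lines.append(f"{f.name} = {rendered}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
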