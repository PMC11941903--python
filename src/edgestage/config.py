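"""Pipeline configuration: a flat key/value mapping with file round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with defaults.

    ``pair_universe_mode`` is ``"ppi"`` (use the supplied edge list,
    intersected with filtered genes) or ``"deg_pairs"`` (all pairs among
    the intersection DEG list, capped at ``max_fallback_pairs`` in
    lexicographic order).  ``include_normal`` switches between 5-class
    (default) and 4-class classification.
    """

    fdr_alpha: float = 0.05
    min_abs_lfc: float = 1.0
    de_test: str = "rank_sum"
    max_zero_fraction: float = 0.5
    log_base_transform: str = "log2p1"  # the only supported convention
    top_k: int = 20
    folds: int = 10
    f1_average: str = "macro"
    max_per_type: int = 6
    max_total: int = 20
    forest_trees: int = 100
    forest_seed: int = 42
    pair_universe_mode: str = "ppi"
    max_fallback_pairs: int = 2000
    rfecv_step: float = 0.1
    include_normal: bool = True

    @property
    def forest_params(self) -> dict:
        return {"n_estimators": self.forest_trees, "random_state": self.forest_seed}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a flat key/value mapping")
        known = {f.name: f.type for f in fields(cls)}
        unknown = sorted(set(raw) - set(known))
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


__all__ = ["PipelineConfig"]
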