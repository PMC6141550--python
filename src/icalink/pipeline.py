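"""End-to-end pipeline: profiles → modes → engagement → association.

A :class:`PipelineConfig` fully determines a run; the run manifest written
alongside the outputs (config, package version, convergence flags) is
sufficient to reproduce every numeric artifact exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import blocks_from_family_ids, run_association
from .io import (
    read_personality_table,
    read_timeseries_dir,
    write_association,
    write_engagement,
    write_json,
    write_loadings,
)
from .modes import derive_temporal_modes, engagement_from_set
from .profiles import derive_profiles

__all__ = ["PipelineConfig", "run_pipeline", "gender_covariate"]


@dataclass
class PipelineConfig:
    """Serializable configuration of a full association run."""

    personality_path: str
    timeseries_dir: str
    output_dir: str
    ica_tol: float = 1e-6
    ica_max_iter: int = 1000
    ica_nonlinearity: str = "logcosh"
    ica_seed: int = 0
    n_perm: int = 10_000
    q: float = 0.05
    perm_seed: int = 0

    def __post_init__(self):
        if self.ica_tol <= 0 or self.ica_max_iter <= 0:
            raise ValueError("ICA tolerance and max_iter must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def gender_covariate(table) -> np.ndarray:
    """Encode gender as a 0/1 column (female = 1)."""
    g = table.frame["gender"].astype(str).str.lower()
    bad = sorted(set(g) - {"male", "female"})
    if bad:
        raise ValueError(f"unrecognized gender label(s): {bad}")
    return (g == "female").to_numpy(dtype=float)[:, None]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Stages: read inputs → derive personality profiles → derive temporal
    modes → compute engagement → family-aware permutation association.
    Any stage failure raises with the stage name; identical configs produce
    byte-identical numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        table = read_personality_table(config.personality_path)
        ts = read_timeseries_dir(config.timeseries_dir, table.subject_ids)

        stage = "personality_profiles"
        profiles, loadings = derive_profiles(
            table,
            nonlinearity=config.ica_nonlinearity,
            tol=config.ica_tol,
            max_iter=config.ica_max_iter,
            seed=config.ica_seed,
        )
        if not profiles.converged:
            warnings.warn("personality ICA did not converge", RuntimeWarning)

        stage = "temporal_modes"
        modes = derive_temporal_modes(
            ts,
            nonlinearity=config.ica_nonlinearity,
            tol=config.ica_tol,
            max_iter=config.ica_max_iter,
            seed=config.ica_seed,
        )
        if not modes.converged:
            warnings.warn("temporal ICA did not converge", RuntimeWarning)

        stage = "engagement"
        engagement = engagement_from_set(ts, modes)

        stage = "association"
        blocks = blocks_from_family_ids(table.frame["family_id"].tolist())
        result = run_association(
            engagement,
            loadings,
            gender_covariate(table),
            blocks,
            n_perm=config.n_perm,
            seed=config.perm_seed,
            q=config.q,
        )

        stage = "write_outputs"
        write_json(profiles, out / "profiles.json")
        write_loadings(loadings, out / "loadings.tsv")
        write_json(modes, out / "modes.json")
        write_engagement(engagement, out / "engagement.tsv")
        write_association(result, out / "association")
        manifest = {
            "config": config.to_dict(),
            "version": __version__,
            "n_subjects": table.n_subjects,
            "profiles_converged": bool(profiles.converged),
            "modes_converged": bool(modes.converged),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    return {
        "table": table,
        "profiles": profiles,
        "loadings": loadings,
        "modes": modes,
        "engagement": engagement,
        "association": result,
        "manifest": manifest,
    }
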