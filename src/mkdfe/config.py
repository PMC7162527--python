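"""Run configuration: YAML with defaults, seeds and a provenance manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS = {
    "families": ["GammaZero", "GammaExpo", "ScaledBeta"],
    "subset": "all",
    "projection_m": None,  # None -> maximize projected SNP count
    "bootstrap_B": 200,
    "n_starts": 10,
    "seed": 0,
    "include_positive_in_omega_na": False,
    "simulate": {
        "n_genes": 200,
        "target_N": 200,
        "p_pos": 0.02,
        "replicates": 1,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides."""
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, {k: v for k, v in overrides.items() if v is not None})
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def write_manifest(out_dir, cfg: dict, inputs: list, stages: dict) -> Path:
    """Provenance manifest: config hash, input digests, per-stage status."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "stages": stages,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
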