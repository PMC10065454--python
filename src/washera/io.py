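"""Reading and writing cluster tables and parameter configurations.

Cluster tables are plain CSV (header row, one cluster per row, '.'
decimal); parameter configurations are YAML with ``rates``, ``traits``
and ``scheme`` sections whose keys mirror the model field names.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .params import ClusterProfile, InputError, RateConfig, SelectionScheme, TraitParams, TraitSet

__all__ = [
    "CLUSTER_COLUMNS",
    "read_clusters",
    "write_clusters",
    "load_config",
    "dump_config",
]

CLUSTER_COLUMNS = [
    "cluster_id", "n_cbbps", "households", "flock_size",
    "ewes_per_household", "litter_size", "targeted_ewes",
]


def read_clusters(path: str | Path) -> list[ClusterProfile]:
    """Load cluster profiles from a CSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"cluster_id": str}, float_precision="round_trip")
    missing = set(CLUSTER_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"cluster file {path} lacks columns: {sorted(missing)}")
    if frame.empty:
        raise InputError(f"cluster file {path} contains no clusters")
    return [ClusterProfile(**row[CLUSTER_COLUMNS].to_dict()) for _, row in frame.iterrows()]


def write_clusters(clusters: list[ClusterProfile], path: str | Path) -> None:
    """Write cluster profiles in the same CSV dialect ``read_clusters`` reads."""
    frame = pd.DataFrame([c.model_dump() for c in clusters])[CLUSTER_COLUMNS]
    # shortest round-trippable float representation
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def load_config(path: str | Path) -> tuple[RateConfig, TraitSet, SelectionScheme]:
    """Load rates, traits and selection scheme from a YAML config.

    Absent sections or keys fall back to the package defaults, so a
    config needs to state only what it overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rates = RateConfig(**raw.get("rates", {}))
    traits_raw = dict(raw.get("traits", {}))
    updates: dict = {}
    for key in ("smw", "ls"):
        if key in traits_raw:
            base = getattr(TraitSet(), key)
            updates[key] = TraitParams(**{**base.model_dump(), **traits_raw.pop(key)})
    traits = TraitSet(**{**traits_raw, **updates})
    scheme = SelectionScheme(**raw.get("scheme", {}))
    return rates, traits, scheme


def dump_config(
    rates: RateConfig, traits: TraitSet, scheme: SelectionScheme, path: str | Path
) -> None:
    """Write a complete parameter configuration as YAML."""
    payload = {
        "rates": rates.model_dump(),
        "traits": traits.model_dump(),
        "scheme": scheme.model_dump(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
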