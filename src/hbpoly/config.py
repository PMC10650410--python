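"""Config-file (YAML/JSON) parsing for pools, constraints and schedules."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .monomers import GrowthConstraints, MonomerSpec
from .schedule import DryingSchedule, DryingStage

__all__ = [
    "load_config",
    "pool_from_config",
    "constraints_from_config",
    "schedule_from_config",
]


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def pool_from_config(data: dict) -> list[MonomerSpec]:
    return [
        MonomerSpec(
            name=m["name"],
            role=m["role"],
            template=m["template"],
            n_attachment_points=int(m["n_attachment_points"]),
            mass=float(m["mass"]),
        )
        for m in data["monomers"]
    ]


def constraints_from_config(data: dict) -> GrowthConstraints:
    return GrowthConstraints(
        total_monomers=int(data["total_monomers"]),
        quantity_per_monomer={k: int(v) for k, v in data["quantities"].items()},
        ramification_threshold=float(data.get("ramification_threshold", 0.5)),
        nonterminal_threshold=float(data.get("nonterminal_threshold", 0.5)),
        n_arms=int(data.get("n_arms", 3)),
        seed=int(data.get("seed", 0)),
    )


def schedule_from_config(data: dict) -> DryingSchedule:
    """Schedule from a config table with columns mirroring the protocol
    tables: stage name, solvent, shell (A), ensemble, duration (ns)."""
    stages = [
        DryingStage(
            stage_name=row["stage_name"],
            solvent=row["solvent"],
            shell_radius=(None if row.get("shell") in (None, "") else float(row["shell"])),
            ensemble=row["ensemble"],
            duration_ns=float(row["duration_ns"]),
        )
        for row in data["stages"]
    ]
    return DryingSchedule(stages=stages, provenance=data.get("provenance", "custom"))
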