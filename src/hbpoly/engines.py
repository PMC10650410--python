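"""Pluggable MD engine backends.

Force-field integration is delegated to an injected engine satisfying a
small contract: given a system, an ensemble label and a duration it returns
a trajectory of one or more frames with unchanged atom identity and count.
Two desk-scale engines are bundled so every pipeline stage can be exercised
without a force field:

* :class:`NullEngine` — returns the input coordinates for every frame;
* :class:`JitterEngine` — a seeded Gaussian random walk (default 0.05 A
  standard deviation per frame per coordinate).

An adapter for a real MD code can implement the same protocol.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .errors import EngineFailure
from .system import SimulationSystem

__all__ = ["EngineContract", "NullEngine", "JitterEngine", "get_engine"]


@runtime_checkable
class EngineContract(Protocol):
    """Capability descriptor + run handle for an MD backend."""

    ensembles: frozenset[str]

    def run(
        self,
        system: SimulationSystem,
        ensemble: str,
        duration_ns: float,
        seed: int = 0,
    ) -> list[np.ndarray]:
        """Return >= 1 coordinate frames of shape (n_atoms, 3)."""
        ...


def _n_frames(duration_ns: float, frames_per_ns: float) -> int:
    return max(1, int(round(duration_ns * frames_per_ns)))


class NullEngine:
    """Identity engine: every frame equals the input coordinates."""

    ensembles = frozenset({"NPT", "NVT"})

    def __init__(self, frames_per_ns: float = 1.0):
        self.frames_per_ns = frames_per_ns

    def run(self, system, ensemble, duration_ns, seed=0):
        if ensemble not in self.ensembles:
            raise EngineFailure(-1, f"unsupported ensemble {ensemble!r}")
        coords = system.coords()
        return [coords.copy() for _ in range(_n_frames(duration_ns, self.frames_per_ns))]


class JitterEngine:
    """Seeded Gaussian random-walk engine.

    Each successive frame adds independent N(0, sd^2) displacements to every
    coordinate, emulating thermal motion at desk scale; sd defaults to
    0.05 A per frame.
    """

    ensembles = frozenset({"NPT", "NVT"})

    def __init__(self, sd: float = 0.05, frames_per_ns: float = 1.0):
        self.sd = sd
        self.frames_per_ns = frames_per_ns

    def run(self, system, ensemble, duration_ns, seed=0):
        if ensemble not in self.ensembles:
            raise EngineFailure(-1, f"unsupported ensemble {ensemble!r}")
        rng = np.random.default_rng(seed)
        coords = system.coords().copy()
        frames = []
        for _ in range(_n_frames(duration_ns, self.frames_per_ns)):
            coords = coords + rng.normal(0.0, self.sd, size=coords.shape)
            frames.append(coords.copy())
        return frames


def get_engine(name: str, **kwargs) -> EngineContract:
    """Engine factory for the CLI: ``null`` or ``jitter``."""
    if name == "null":
        return NullEngine(**kwargs)
    if name == "jitter":
        return JitterEngine(**kwargs)
    raise ValueError(f"unknown engine {name!r} (expected 'null' or 'jitter')")
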