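"""Run manifests and report bundles.

Every CLI run emits a manifest (config digest, seeds, package version,
scenario, timestamp, accumulated warnings) so result files are traceable to
the exact inputs that produced them.  Deterministic sections of a bundle are
byte-identical across reruns; stochastic sections are identical given the
same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .config import config_digest

__all__ = ["RunManifest", "write_json"]


@dataclass
class RunManifest:
    config_sha256: str
    seed: int | None
    scenario: str
    version: str = __version__
    timestamp: str = ""
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    @classmethod
    def create(cls, cfg, seed, scenario, warnings=()) -> "RunManifest":
        return cls(
            config_sha256=config_digest(cfg),
            seed=seed,
            scenario=str(scenario),
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            warnings=list(warnings),
        )

    def register(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_json(obj, path, deterministic: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=deterministic, default=float)
        fh.write("\n")
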