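"""Reproducible run manifests.

Every CLI run records its configuration snapshot, master seed and derived
substream seeds, input-file digests, and the files it wrote — enough to
re-run any deterministic stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RunManifest", "substream_seeds", "sha256_file"]


def substream_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    """Derive one named, independent seed (< 2^31) per pipeline stage."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    master_seed: int
    substreams: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        self.finished = time.time()
        payload = {
            "command": self.command,
            "config": self.config,
            "master_seed": self.master_seed,
            "substreams": self.substreams,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "elapsed_s": round(self.finished - self.started, 3),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
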