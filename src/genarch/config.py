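"""Run configuration: one serialisable object describing an entire run.

Every CLI command resolves its options into a RunConfig, writes the
resolved config as JSON next to its outputs, and stamps every text
artefact with the config hash and seed so that outputs are traceable and
re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    window_size: int = 5000
    telomere_motif: str = "TTTAGGG"
    cag_motif: str = "CAG"
    kmer_sizes: tuple[int, ...] = (3, 4)
    fragment_length: int = 150
    mappability_fold: int = 10
    include_features: list[str] | None = None
    exclude_features: list[str] | None = None
    n_values: tuple[int, ...] = (5, 10, 15, 20)
    c_values: tuple[int, ...] = (50, 100, 200, 500)
    n_neighbours: int | None = None
    min_cluster_size: int | None = None
    min_dist: float = 0.1
    alpha: float = 1e-20
    seed: int = 42
    merge_factor: int | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        kwargs = {
            f.name: data[f.name] for f in dataclasses.fields(cls) if f.name in data
        }
        for name in ("kmer_sizes", "n_values", "c_values"):
            if isinstance(kwargs.get(name), list):
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def stamp(self) -> list[str]:
        """Header comment lines for output artefacts."""
        return [f"config_hash={self.hash}", f"seed={self.seed}"]
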