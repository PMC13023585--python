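"""Group-level container of connectivity matrices.

A :class:`GroupDataset` holds one :class:`~plvnet.connectivity.ConnectivityMatrix`
per subject x condition x time x band cell of a fully crossed within-subject
design, and is the input to the inference stages (NBS, strengths, statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .connectivity import ConnectivityMatrix

__all__ = ["GroupDataset"]

Key = tuple[int, str, str, str]  # (subject, condition, time, band)


@dataclass
class GroupDataset:
    subjects: list[int]
    conditions: list[str]
    times: list[str]
    bands: list[str]
    matrices: dict[Key, ConnectivityMatrix] = field(default_factory=dict)

    def put(
        self, subject: int, condition: str, time: str, band: str, cm: ConnectivityMatrix
    ) -> None:
        self.matrices[(subject, condition, time, band)] = cm

    def get(
        self, subject: int, condition: str, time: str, band: str
    ) -> ConnectivityMatrix:
        return self.matrices[(subject, condition, time, band)]

    def cell(self, condition: str, time: str, band: str) -> list[ConnectivityMatrix]:
        """All subjects' matrices for one condition x time x band cell, subject order."""
        return [self.get(s, condition, time, band) for s in self.subjects]

    @property
    def labels(self) -> list[str]:
        return next(iter(self.matrices.values())).labels

    def validate_complete(self) -> None:
        missing = [
            (s, c, t, b)
            for s in self.subjects
            for c in self.conditions
            for t in self.times
            for b in self.bands
            if (s, c, t, b) not in self.matrices
        ]
        if missing:
            raise ValueError(f"incomplete design; missing cells: {missing[:5]}...")

    # -- plain-text round trip -------------------------------------------------

    def write_dir(self, out_dir: str | Path) -> dict:
        """Write one CSV per matrix plus a manifest JSON; returns the manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for (s, c, t, b), cm in sorted(self.matrices.items()):
            name = f"sub-{s:03d}_{c}_{t}_{b}.csv"
            cm.to_csv(out_dir / name)
            entries.append(
                {"subject": s, "condition": c, "time": t, "band": b, "file": name}
            )
        manifest = {
            "subjects": self.subjects,
            "conditions": self.conditions,
            "times": self.times,
            "bands": self.bands,
            "matrices": entries,
        }
        (out_dir / "dataset.json").write_text(json.dumps(manifest, indent=1))
        return manifest

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> "GroupDataset":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "dataset.json").read_text())
        ds = cls(
            manifest["subjects"],
            manifest["conditions"],
            manifest["times"],
            manifest["bands"],
        )
        for e in manifest["matrices"]:
            cm = ConnectivityMatrix.from_csv(in_dir / e["file"])
            ds.put(e["subject"], e["condition"], e["time"], e["band"], cm)
        return ds
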