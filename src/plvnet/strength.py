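"""Within/between resting-state-network connection strengths.

Regions are grouped into five canonical resting-state networks -- SMN
(sensorimotor), DAN (dorsal attention), SN (salience), CEN (central
executive/control) and DMN (default mode).  Strengths are plain means of PLV
over the relevant region pairs: the total average excludes self-connections,
a within-network strength averages pairs inside one network, and a
between-network strength averages pairs straddling two networks.  The total
average is exactly the pair-count-weighted mean of the 5 within and 10
between strengths.  Min-max normalization rescales a collection of strength
values to [0, 1] while preserving order.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .dataset import GroupDataset

__all__ = [
    "CANONICAL_NETWORKS",
    "NetworkPartition",
    "default_partition_path",
    "total_average_plv",
    "within_strength",
    "between_strength",
    "minmax_normalize",
    "strength_table",
]

CANONICAL_NETWORKS = ("SMN", "DAN", "SN", "CEN", "DMN")


class PartitionError(ValueError):
    pass


@dataclass
class NetworkPartition:
    """Mapping from region label to one of the five canonical networks."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        networks = set(self.mapping.values())
        unknown = networks - set(CANONICAL_NETWORKS)
        if unknown:
            raise PartitionError(f"unknown network labels: {sorted(unknown)}")
        for net in networks:
            if sum(1 for v in self.mapping.values() if v == net) < 2:
                raise PartitionError(f"network {net!r} has fewer than 2 regions")

    @property
    def networks(self) -> list[str]:
        present = set(self.mapping.values())
        return [n for n in CANONICAL_NETWORKS if n in present]

    @property
    def regions(self) -> list[str]:
        return list(self.mapping)

    def members(self, net: str) -> list[str]:
        if net not in self.networks:
            raise PartitionError(f"unknown network {net!r}")
        return [r for r, n in self.mapping.items() if n == net]

    def network_pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.networks, 2))

    def indices(self, labels: list[str], net: str) -> np.ndarray:
        members = set(self.members(net))
        return np.array([k for k, lab in enumerate(labels) if lab in members])

    def validate_against_labels(self, labels: list[str]) -> None:
        missing = [lab for lab in labels if lab not in self.mapping]
        if missing:
            raise PartitionError(f"regions not in partition: {missing[:5]}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkPartition":
        """Read a two-column TSV (region_label, network_label), with header optional.

        Errors name the offending line number.
        """
        mapping: dict[str, str] = {}
        lines = Path(path).read_text().splitlines()
        for lineno, line in enumerate(lines, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PartitionError(f"{path}:{lineno}: expected 2 tab-separated columns")
            region, net = parts[0].strip(), parts[1].strip()
            if lineno == 1 and net not in CANONICAL_NETWORKS:
                continue  # header row
            if region in mapping:
                raise PartitionError(f"{path}:{lineno}: duplicate region {region!r}")
            if net not in CANONICAL_NETWORKS:
                raise PartitionError(
                    f"{path}:{lineno}: unknown network {net!r} "
                    f"(expected one of {CANONICAL_NETWORKS})"
                )
            mapping[region] = net
        if not mapping:
            raise PartitionError(f"{path}: no regions parsed")
        return cls(mapping)


def default_partition_path() -> Path:
    """Path of the 78-region partition file shipped with the package.

    The shipped file is a synthetic stand-in with realistic per-network
    region counts; deriving the true membership from the public
    Schaefer 100-parcel / Yeo 7-network lookup is left to the user.
    """
    return Path(resources.files("plvnet.data") / "partition_78.tsv")


def load_default_partition() -> NetworkPartition:
    return NetworkPartition.from_tsv(default_partition_path())


def total_average_plv(W: ConnectivityMatrix) -> float:
    """Mean PLV over all region pairs, excluding self-connections."""
    if W.n_regions < 2:
        raise ValueError("need at least 2 regions")
    return float(W.upper_triangle().mean())


def within_strength(W: ConnectivityMatrix, p: NetworkPartition, net: str) -> float:
    """Mean PLV over unordered region pairs with both regions in ``net``."""
    idx = p.indices(W.labels, net)
    if idx.size < 2:
        raise PartitionError(f"network {net!r} has fewer than 2 regions in this matrix")
    sub = W.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def between_strength(
    W: ConnectivityMatrix, p: NetworkPartition, net_a: str, net_b: str
) -> float:
    """Mean PLV over region pairs with one region in each network; symmetric."""
    if net_a == net_b:
        raise PartitionError("between-strength requires two distinct networks")
    ia = p.indices(W.labels, net_a)
    ib = p.indices(W.labels, net_b)
    if ia.size == 0 or ib.size == 0:
        raise PartitionError("empty network in this matrix")
    return float(W.values[np.ix_(ia, ib)].mean())


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); order-preserving map onto [0, 1]."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError(f"min-max normalization degenerate: all values equal {lo}")
    return (values - lo) / (hi - lo)


def strength_table(
    dataset: GroupDataset,
    partition: NetworkPartition,
    normalize: bool = True,
) -> pd.DataFrame:
    """Long-format table of total/within/between strengths for a group dataset.

    Columns: subject, condition, time, band, measure, value, value_norm.
    ``measure`` is ``total``, ``within:NET`` or ``between:NETA-NETB``.  When
    ``normalize`` is set, min-max normalization is applied per (band,
    measure) across all subject x condition x time values, so the four
    compared conditions share one scale.
    """
    partition.validate_against_labels(dataset.labels)
    rows = []
    for (s, c, t, b), cm in sorted(dataset.matrices.items()):
        rows.append((s, c, t, b, "total", total_average_plv(cm)))
        for net in partition.networks:
            rows.append((s, c, t, b, f"within:{net}", within_strength(cm, partition, net)))
        for na, nb in partition.network_pairs():
            rows.append(
                (s, c, t, b, f"between:{na}-{nb}", between_strength(cm, partition, na, nb))
            )
    df = pd.DataFrame(
        rows, columns=["subject", "condition", "time", "band", "measure", "value"]
    )
    if normalize:
        df["value_norm"] = df.groupby(["band", "measure"])["value"].transform(
            lambda v: minmax_normalize(v.to_numpy())
        )
    return df
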