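"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("FH", "SFH")


@dataclass
class CountMatrix:
    """Raw integer counts, features x samples, with per-sample group labels.

    Parameters
    ----------
    counts
        DataFrame with feature ids as the index and sample ids as columns.
        Values must be non-negative integers.
    groups
        Mapping/Series sample id -> group label ("FH" or "SFH").
    feature_kind
        "miRNA" or "gene"; informational, used to label network nodes.
    """

    counts: pd.DataFrame
    groups: pd.Series
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(self.groups)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(feature_ids)], self.groups, self.feature_kind
        )


@dataclass
class NormalizedMatrix:
    """Counts-per-million matrix sharing axes with its source CountMatrix."""

    cpm: pd.DataFrame
    groups: pd.Series
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(self.groups)
        self.groups = self.groups.loc[self.cpm.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.cpm.index)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.cpm.columns if self.groups[s] == group]


@dataclass
class CorrelationEdge:
    """A signed co-expression edge in one group's network.

    node_a < node_b lexicographically; edge_class is one of
    "miRNA-gene", "miRNA-miRNA", "gene-gene".
    """

    node_a: str
    node_b: str
    r: float
    group: str
    edge_class: str
    pcit_significant: bool = True
    p_value: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.node_a > self.node_b:
            self.node_a, self.node_b = self.node_b, self.node_a
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of bounds: {self.r}")
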