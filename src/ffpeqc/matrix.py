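"""Expression-matrix container with group and replicate-pairing metadata.

The matrix holds normalized gene signals (genes x samples) on either the
linear or the log2 scale, together with a mapping of each sample to an
experimental group (e.g. ``FF`` / ``FFPE``) and to a replicate index within
that group.  Paired designs — the typical FF/FFPE study where each case
contributes one fresh-frozen and one fixed specimen — are expressed through
equal replicate indices across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

Scale = str  # "linear" | "log2"

_VALID_SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples signal table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    scale
        ``"linear"`` (signals > 0) or ``"log2"``.
    groups
        Mapping ``sample_id -> group label``; every sample must appear.
    pairing
        Mapping ``sample_id -> replicate index`` (1-based) within its group.
        Defaults to enumeration order within each group.
    """

    values: pd.DataFrame
    scale: Scale = "log2"
    groups: dict[str, str] = field(default_factory=dict)
    pairing: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise InvalidInputError(f"scale must be one of {_VALID_SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate sample ids: {dups[:5]}")
        if not self.groups:
            # single implicit group
            self.groups = {s: "all" for s in self.values.columns}
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise InvalidInputError(f"samples missing from group mapping: {missing}")
        if not self.pairing:
            counters: dict[str, int] = {}
            for s in self.values.columns:
                g = self.groups[s]
                counters[g] = counters.get(g, 0) + 1
                self.pairing[s] = counters[g]
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            raise InvalidInputError("linear-scale values must be strictly positive")

    # -- basic accessors ---------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids of one group, ordered by replicate index."""
        members = [s for s in self.values.columns if self.groups[s] == group]
        if not members:
            raise InvalidInputError(f"group {group!r} not present")
        return sorted(members, key=lambda s: (self.pairing[s], s))

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    # -- scale conversion --------------------------------------------------

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(
            values=np.exp2(self.values),
            scale="linear",
            groups=dict(self.groups),
            pairing=dict(self.pairing),
        )

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(
            values=np.log2(self.values),
            scale="log2",
            groups=dict(self.groups),
            pairing=dict(self.pairing),
        )

    # -- group slices ------------------------------------------------------

    def group_slice(self, group: str) -> pd.DataFrame:
        """Linear-scale values of one group, columns ordered by replicate index."""
        return self.to_linear().values[self.samples_in_group(group)]

    def group_slice_log2(self, group: str) -> pd.DataFrame:
        return self.to_log2().values[self.samples_in_group(group)]
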