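"""Expression matrix container and plain-text I/O.

The matrix tracks its scale (``linear`` intensities vs ``log2`` units) and
whether between-sample normalization has been applied, so downstream steps
can refuse to run out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

VALID_FLAGS = frozenset({"P", "M", "A"})
SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with detection flags and design.

    Parameters
    ----------
    values
        DataFrame of intensities, probes as index, samples as columns.
    groups
        Mapping sample id -> group label for every sample.
    flags
        Optional DataFrame of per-cell detection flags in {P, M, A},
        same shape/labels as ``values``.
    scale
        ``"linear"`` (raw intensities) or ``"log2"``.
    normalized
        Whether between-sample normalization has been applied. A matrix
        constructed directly on the log2 scale is assumed normalized.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    flags: pd.DataFrame | None = None
    scale: str = SCALE_LINEAR
    normalized: bool | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_LINEAR, SCALE_LOG2):
            raise ScaleError(f"unknown scale marker {self.scale!r}")
        if self.normalized is None:
            self.normalized = self.scale == SCALE_LOG2
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(
                "duplicate probe identifiers are not supported "
                f"(one probe per gene is assumed): {list(dups)[:5]}"
            )
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("flags matrix shape differs from values")
            bad = set(pd.unique(self.flags.values.ravel())) - VALID_FLAGS
            if bad:
                raise ValueError(f"invalid detection flags: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def with_values(self, values: pd.DataFrame, **changes) -> "ExpressionMatrix":
        """Copy of self with new values (and optional marker changes)."""
        flags = changes.pop("flags", self.flags)
        if flags is not None and not flags.index.equals(values.index):
            flags = flags.loc[values.index]
        return replace(self, values=values, flags=flags, **changes)


def read_expression(
    values_path, design_path, flags_path=None, scale: str = SCALE_LINEAR
) -> ExpressionMatrix:
    """Load an expression matrix from TSV files written by :func:`write_expression`."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    groups = design.iloc[:, 0].astype(str).to_dict()
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
        flags.index = flags.index.astype(str)
    return ExpressionMatrix(values=values, groups=groups, flags=flags, scale=scale)


def write_expression(m: ExpressionMatrix, values_path, design_path, flags_path=None) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="probe", float_format="%.10g")
    design = pd.DataFrame({"group": [m.groups[s] for s in m.sample_ids]}, index=m.sample_ids)
    design.to_csv(design_path, sep="\t", index_label="sample")
    if flags_path is not None and m.flags is not None:
        m.flags.to_csv(flags_path, sep="\t", index_label="probe")
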