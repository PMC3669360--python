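"""Probe-by-sample expression matrix with sample-design metadata.

The :class:`ExpressionMatrix` is the substrate of every pipeline stage: a
probes x samples table of (log2-scale) intensities plus a design table
mapping each sample column to a condition label and replicate index.

File formats
------------
* matrix TSV — first column ``probe_id``, header row of sample ids;
* design TSV — columns ``sample_id``, ``condition``, ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Expression intensities with sample design metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes (index) by samples (columns) real intensities.
    design : pandas.DataFrame
        Indexed by sample id, with ``condition`` (str) and ``replicate``
        (int) columns covering every sample column of ``values``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise ValueError(f"design table lacks required column {col!r}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite intensities")

    # ------------------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in design order, deduplicated."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(str(self.design.loc[s, "condition"]), None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [
            s
            for s in self.sample_ids
            if str(self.design.loc[s, "condition"]) == condition
        ]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same design, new value table (labels must be preserved)."""
        return ExpressionMatrix(values=values, design=self.design)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[:, list(samples)],
            design=self.design.loc[list(samples)],
        )

    def subset_probes(self, probes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(probes)], design=self.design
        )

    # ------------------------------------------------------------------
    @classmethod
    def read_tsv(cls, matrix_path: str | Path, design_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(
            matrix_path, sep="\t", index_col=0, float_precision="round_trip"
        )
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        design = read_design_tsv(design_path)
        return cls(values=values, design=design)

    def write_tsv(self, matrix_path: str | Path, design_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "probe_id"
        # %.17g makes the decimal text round-trip IEEE doubles exactly
        out.to_csv(matrix_path, sep="\t", float_format="%.17g")
        if design_path is not None:
            write_design_tsv(self.design, design_path)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    design = design.set_index("sample_id")
    return design


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
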