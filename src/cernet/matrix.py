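"""Expression-matrix container with paired tumor/normal sample metadata.

The matrix holds log2 intensities, features in rows, samples in columns.
Sample metadata assigns each sample a condition (``tumor`` or ``normal``)
and a pair id; a pair id must map to exactly one tumor and one normal
sample whenever a paired analysis is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "normal")


class MatrixError(ValueError):
    """Raised for structurally invalid expression matrices or metadata."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = feature ids, columns = sample
        ids.  No missing values are allowed.
    meta
        DataFrame indexed by sample id with columns ``condition`` and
        ``pair_id``.  Every matrix column must have a metadata row.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise MatrixError("expression matrix must have >=1 feature and >=1 sample")
        if v.index.duplicated().any():
            raise MatrixError("duplicate feature ids")
        if v.columns.duplicated().any():
            raise MatrixError("duplicate sample ids")
        if v.isna().to_numpy().any():
            raise MatrixError("missing values in expression matrix")
        missing = set(v.columns) - set(self.meta.index)
        if missing:
            raise MatrixError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise MatrixError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_samples(self, condition: str) -> list[str]:
        """Sample ids of one condition, in matrix column order."""
        if condition not in CONDITIONS:
            raise MatrixError(f"unknown condition {condition!r}")
        keep = self.meta.loc[self.meta["condition"] == condition].index
        return [s for s in self.values.columns if s in set(keep)]

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.condition_samples(condition)]

    def pairs(self) -> list[tuple[str, str, str]]:
        """(pair_id, tumor_sample, normal_sample) triples, sorted by pair id.

        Raises if any pair id does not map to exactly one tumor and one
        normal sample among the matrix columns.
        """
        meta = self.meta.loc[self.sample_ids]
        out = []
        for pid, grp in sorted(meta.groupby("pair_id")):
            tum = list(grp.index[grp["condition"] == "tumor"])
            nor = list(grp.index[grp["condition"] == "normal"])
            if len(tum) != 1 or len(nor) != 1:
                raise MatrixError(
                    f"pair {pid!r} has {len(tum)} tumor / {len(nor)} normal samples; "
                    "paired analysis needs exactly one of each"
                )
            out.append((str(pid), tum[0], nor[0]))
        return out

    def paired_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(tumor, normal) value arrays with aligned pair columns."""
        triples = self.pairs()
        pids = [p for p, _, _ in triples]
        tum = self.values[[t for _, t, _ in triples]].to_numpy(float)
        nor = self.values[[n for _, _, n in triples]].to_numpy(float)
        return tum, nor, pids

    # ------------------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"pair_id": str})
        meta.index = meta.index.astype(str)
        return cls(values=values, meta=meta)
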