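"""Expression-matrix container shared by every pipeline stage.

An :class:`ExpressionMatrix` holds a gene x sample table of microarray-style
intensities together with the two pieces of metadata the pipeline needs:
the class of every gene (miRNA / lncRNA / mRNA) and the group of every
sample (control / induced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_CLASSES = ("miRNA", "lncRNA", "mRNA")
GROUPS = ("control", "induced")


@dataclass
class ExpressionMatrix:
    """Gene x sample intensities with gene-class and group labels.

    Parameters
    ----------
    values
        DataFrame of nonnegative intensities, genes as rows, samples as
        columns.  After :func:`cncnet.diffexpr.log2_normalize` the values
        are on the log2 scale and ``is_log2`` is set.
    gene_class
        Series mapping gene id -> one of ``miRNA``, ``lncRNA``, ``mRNA``.
    groups
        Series mapping sample id -> ``control`` or ``induced``.
    """

    values: pd.DataFrame
    gene_class: pd.Series
    groups: pd.Series
    is_log2: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_class = self.gene_class.reindex(self.values.index)
        self.groups = self.groups.reindex(self.values.columns)
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.is_log2 and (self.values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be nonnegative")
        if self.gene_class.isna().any():
            missing = self.gene_class.index[self.gene_class.isna()][0]
            raise ValueError(f"gene without class label: {missing!r}")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene class(es): {sorted(bad)}")
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise ValueError(f"sample without group label: {missing!r}")
        badg = set(self.groups.unique()) - set(GROUPS)
        if badg:
            raise ValueError(f"unknown group label(s): {sorted(badg)}")
        counts = self.groups.value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < 2:
                raise ValueError(
                    f"group {g!r} has {counts.get(g, 0)} samples; "
                    "need at least 2 per group for a t-test"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def genes_of_class(self, gene_class: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == gene_class])

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        vals = self.values
        if genes is not None:
            vals = vals.loc[list(genes)]
        if samples is not None:
            vals = vals[list(samples)]
        return ExpressionMatrix(
            vals.copy(), self.gene_class.copy(), self.groups.copy(),
            is_log2=self.is_log2, meta=dict(self.meta),
        )

    def group_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (control, induced) value arrays, genes x replicates."""
        ctrl = self.values[self.samples_in("control")].to_numpy(float)
        ind = self.values[self.samples_in("induced")].to_numpy(float)
        return ctrl, ind
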