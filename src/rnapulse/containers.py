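"""Tabular containers shared across quantification, simulation and fitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import TimeGrid

__all__ = ["TimeCourseExpression"]


@dataclass
class TimeCourseExpression:
    """Genes x time matrices of pre-mRNA (P), total (T) and labeled (TL)
    signal, plus the time grid, unit and normalization tags.

    P is measured by the intronic signal of the total libraries, T by
    their exonic signal, and TL by the exonic signal of the labeled
    libraries.  All three frames share the gene index and have one column
    per sampling time (column labels are the times in minutes).
    """

    P: pd.DataFrame
    T: pd.DataFrame
    TL: pd.DataFrame
    grid: TimeGrid
    unit: str = "counts"
    normalization: str = "none"
    #: per-gene warnings/flags, e.g. genes without introns
    gene_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.grid.n
        for name in ("P", "T", "TL"):
            df = getattr(self, name)
            if df.shape[1] != n:
                raise ValueError(
                    f"{name} has {df.shape[1]} columns but grid has {n} time points"
                )
        if not (self.P.index.equals(self.T.index) and self.T.index.equals(self.TL.index)):
            raise ValueError("P, T and TL must share the same gene index")

    @property
    def genes(self) -> list[str]:
        return list(self.P.index)

    @property
    def n_genes(self) -> int:
        return len(self.P.index)

    def gene_arrays(self, gene: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The (P, T, TL) series of one gene as float arrays."""
        return (
            self.P.loc[gene].to_numpy(dtype=float),
            self.T.loc[gene].to_numpy(dtype=float),
            self.TL.loc[gene].to_numpy(dtype=float),
        )

    def subset(self, genes) -> "TimeCourseExpression":
        genes = list(genes)
        return TimeCourseExpression(
            P=self.P.loc[genes].copy(),
            T=self.T.loc[genes].copy(),
            TL=self.TL.loc[genes].copy(),
            grid=self.grid,
            unit=self.unit,
            normalization=self.normalization,
            gene_flags={g: f for g, f in self.gene_flags.items() if g in set(genes)},
        )
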