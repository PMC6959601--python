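"""Co-binding structure of transcription factors at classified loci.

Association between factors is the phi coefficient (Pearson correlation of 0/1
membership vectors); combination counts follow UpSet's distinct mode, where
each locus contributes to exactly one combination -- its exact membership
pattern over the chosen factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, overlap_membership

__all__ = [
    "BindingMatrix",
    "CLASS_LABELS",
    "build_binding_matrix",
    "combination_counts_by_class",
    "phi_correlation",
    "select_cofactors",
]

CLASS_LABELS = ("DE_promoter", "enhancer", "super_enhancer", "other")
META_COLS = ("locus_id", "chrom", "start", "end", "class")


@dataclass
class BindingMatrix:
    """Loci x factors boolean membership with a genomic class label per locus."""

    table: pd.DataFrame = field(repr=False)
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.factors:
            self.factors = tuple(
                c for c in self.table.columns if c not in META_COLS
            )
        if len(self.factors) < 1:
            raise ValueError("binding matrix needs at least one factor")
        unknown = set(self.table["class"]) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        for f in self.factors:
            vals = set(self.table[f].unique())
            if not vals <= {0, 1, True, False}:
                raise ValueError(f"factor column {f!r} must be 0/1")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def membership(self) -> np.ndarray:
        return self.table[list(self.factors)].to_numpy(dtype=bool)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingMatrix":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_binding_matrix(
    loci: PeakSet,
    factor_tracks: dict[str, PeakSet],
    class_tracks: dict[str, PeakSet] | None = None,
) -> BindingMatrix:
    """Cross loci against factor cistromes (>=1 bp overlap) and class tracks.

    Class assignment uses the priority DE_promoter > super_enhancer > enhancer
    > other, with class track keys matching those labels.
    """
    factors = list(factor_tracks)
    member = overlap_membership(loci, [factor_tracks[f] for f in factors])
    if class_tracks:
        class_order = [c for c in ("DE_promoter", "super_enhancer", "enhancer") if c in class_tracks]
        class_member = overlap_membership(loci, [class_tracks[c] for c in class_order])
    rows = []
    for i, iv in enumerate(loci):
        cls = "other"
        if class_tracks:
            for j, c in enumerate(class_order):
                if class_member[i, j]:
                    cls = c
                    break
        row = {
            "locus_id": iv.name if iv.name != "." else f"locus_{i}",
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "class": cls,
        }
        row.update({f: int(member[i, j]) for j, f in enumerate(factors)})
        rows.append(row)
    return BindingMatrix(pd.DataFrame(rows), tuple(factors))


def phi_correlation(matrix: BindingMatrix) -> pd.DataFrame:
    """Factor x factor phi coefficients; constant columns give NaN entries."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 loci to correlate")
    x = matrix.membership().astype(float)
    n = x.shape[0]
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / n
    sd = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = cov / np.outer(sd, sd)
    phi[:, sd == 0] = np.nan
    phi[sd == 0, :] = np.nan
    return pd.DataFrame(phi, index=matrix.factors, columns=matrix.factors)


def select_cofactors(
    matrix: BindingMatrix,
    target: str,
    min_phi: float = 0.2,
    top_k: int | None = None,
) -> list[str]:
    """Factors whose phi with ``target`` is >= min_phi, strongest first.

    Ties break alphabetically; factors with undefined phi (constant columns)
    are excluded with a warning; the target never selects itself.
    """
    if target not in matrix.factors:
        raise ValueError(f"unknown target factor {target!r}")
    phi = phi_correlation(matrix)[target].drop(labels=[target])
    undefined = phi.index[phi.isna()]
    if len(undefined):
        warnings.warn(
            f"phi undefined (constant membership) for {list(undefined)}; excluded",
            stacklevel=2,
        )
        phi = phi.dropna()
    selected = phi[phi >= min_phi]
    ordered = sorted(selected.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [name for name, _ in ordered]
    return names[:top_k] if top_k is not None else names


def combination_counts_by_class(
    matrix: BindingMatrix, cls: str, factors: Sequence[str] | None = None
) -> list[tuple[tuple[str, ...], int]]:
    """Exact-pattern combination counts for loci of one class (UpSet distinct mode).

    Each locus contributes to exactly one combination: the tuple of factors
    binding it, ordered as in ``factors``. Ranked by count descending, ties by
    the member-name tuple ascending; counts sum to the class size.
    """
    factors = list(factors) if factors is not None else list(matrix.factors)
    unknown = set(factors) - set(matrix.factors)
    if unknown:
        raise ValueError(f"unknown factors {sorted(unknown)}")
    sub = matrix.table.loc[matrix.table["class"] == cls, factors]
    if sub.empty:
        raise ValueError(f"no loci of class {cls!r}")
    tally: dict[tuple[str, ...], int] = {}
    for row in sub.itertuples(index=False):
        combo = tuple(f for f, present in zip(factors, row) if present)
        tally[combo] = tally.get(combo, 0) + 1
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
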