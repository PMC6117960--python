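"""The differential-methylation measure: offset fold-change and M-score.

For region j in comparison i the fold-change is

    f_ij = (I_case,ij + beta*L) / (I_control,ij + beta*L)

where I are regional methylation intensities in bases, L is the short
read length (default 36) and beta (default 10) an offset multiplier.
The additive offset beta*L suppresses the effect of weak methylation
signals in the denominator: for weakly covered regions f shrinks toward
1, while for strongly covered regions f approaches the raw intensity
ratio.  The signed score M = log2(f) makes hyper- and hypomethylation
symmetric around 0 (positive M = hypermethylated in case).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import IntensityMatrix, aggregate_groups


@dataclass(frozen=True)
class FoldChangeParams:
    """Offset fold-change parameters: read length L and offset multiplier beta.

    The product beta*L enters as a single additive offset in bases
    (default 10 * 36 = 360).
    """

    L: int = 36
    beta: float = 10.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def offset(self) -> float:
        return self.beta * self.L


def fold_change(i_case, i_control, params: FoldChangeParams = FoldChangeParams()):
    """Offset fold-change (I_case + beta*L) / (I_control + beta*L).

    Accepts scalars or arrays.  With a zero offset both intensities must
    not be zero (the ratio is undefined).
    """
    i_case = np.asarray(i_case, dtype=float)
    i_control = np.asarray(i_control, dtype=float)
    if (i_case < 0).any() or (i_control < 0).any():
        raise ValueError("intensities must be nonnegative")
    offset = params.offset
    if offset == 0 and ((i_case == 0) & (i_control == 0)).any():
        raise ValueError("fold-change undefined: both intensities 0 with zero offset")
    out = (i_case + offset) / (i_control + offset)
    return float(out) if out.ndim == 0 else out


def m_score(f):
    """Signed differential-methylation score M = log2(f).

    Positive M means hypermethylated in the case group.
    """
    f = np.asarray(f, dtype=float)
    if (f <= 0).any():
        raise ValueError("fold-change must be positive")
    out = np.log2(f)
    return float(out) if out.ndim == 0 else out


def score_regions(matrix: IntensityMatrix,
                  params: FoldChangeParams = FoldChangeParams()) -> pd.DataFrame:
    """Per-region fold-change and M-score for one case-vs-control comparison.

    Group intensities are replicate means.  Scores for different region
    roles (promoters, CpG islands, CpG sites, units) are kept in one
    table but must never be pooled into one null — downstream inference
    stratifies by role.
    """
    agg = aggregate_groups(matrix)
    f = fold_change(agg["I_case"].to_numpy(), agg["I_control"].to_numpy(), params)
    table = pd.DataFrame(
        {
            "region_id": agg["region_id"],
            "role": [r.role for r in matrix.regions],
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
            "I_case": agg["I_case"],
            "I_control": agg["I_control"],
            "f": f,
            "M": m_score(f),
        }
    )
    return table
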