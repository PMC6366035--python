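"""Ranking miRNAs by their impact on global transcriptome change.

Each miRNA is first considered alone: a single-predictor model
``fc ~ dk_i * (c'_.i * miRNA_i) + b0`` is fitted by least squares and the
Spearman correlation between its predictions and the observed fold
changes becomes the miRNA's score.  Because the slope is re-estimated,
the correlation is non-negative for any informative column even when the
full-model dk_i is negative.  miRNAs are ranked by descending score.

Cumulative-inclusion curves then re-fit the model on the first n miRNAs
in rank order (forward: best first; reverse: worst first), re-estimating
the dk subvector and b0 at every n.  On data where a small set of miRNAs
carries the signal the forward curve plateaus once the active set is
included, while the reverse curve climbs only near the end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidArgumentError
from .expression import FoldChangeVector
from .interaction import WeightedTargetMatrix
from .model import MiRNAPerturbationModel, build_design, spearman


@dataclass
class MiRNARanking:
    """Per-miRNA single-predictor scores, ordered by descending score."""

    table: pd.DataFrame  # columns: rank, mirna_id, rho_single, dk_single

    @property
    def ordered_ids(self) -> list[str]:
        return list(self.table["mirna_id"])

    def top(self, n: int) -> list[str]:
        return self.ordered_ids[:n]


@dataclass
class CumulativeCurve:
    """Model correlation as miRNAs are added one at a time."""

    order: str  # "forward" or "reverse"
    n_included: np.ndarray
    rho_at_n: np.ndarray

    def plateau_n(self, tolerance: float = 0.01) -> int:
        """Smallest n whose correlation is within ``tolerance`` of the maximum."""
        target = np.nanmax(self.rho_at_n) - tolerance
        return int(self.n_included[np.nonzero(self.rho_at_n >= target)[0][0]])


def _as_fc(fc_observed) -> np.ndarray:
    if isinstance(fc_observed, FoldChangeVector):
        return fc_observed.fc
    return np.asarray(fc_observed, dtype=float)


def rank_single_mirnas(
    C_prime: WeightedTargetMatrix, mirna_expr, fc_observed
) -> MiRNARanking:
    """Score and rank every miRNA as a lone predictor of the fold changes.

    Degenerate (all-zero) target columns get a NaN score and are ranked
    last; ties in score break by lexicographic miRNA id.
    """
    design = build_design(C_prime, mirna_expr)
    fc = _as_fc(fc_observed)
    est = MiRNAPerturbationModel()
    records = []
    for i, mirna_id in enumerate(design.mirna_ids):
        column = design.A[:, [i]]
        if np.all(column == column[0]):
            records.append((mirna_id, float("nan"), float("nan")))
            continue
        est.fit(column, fc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearman(est.fitted_values_, fc)
        records.append((mirna_id, rho, float(est.coef_[0])))
    table = pd.DataFrame(records, columns=["mirna_id", "rho_single", "dk_single"])
    table = table.sort_values(
        ["rho_single", "mirna_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return MiRNARanking(table)


CURVE_ORDERS = ("forward", "reverse")


def cumulative_curve(
    C_prime: WeightedTargetMatrix,
    mirna_expr,
    fc_observed,
    ranking: MiRNARanking,
    order: str = "forward",
) -> CumulativeCurve:
    """Correlation of the model restricted to the first n ranked miRNAs.

    For every n the dk subvector and b0 are re-estimated on the included
    columns, so the final point of both orders equals the full-model
    training correlation.
    """
    if order not in CURVE_ORDERS:
        raise InvalidArgumentError(f"order must be one of {CURVE_ORDERS}")
    design = build_design(C_prime, mirna_expr)
    if set(ranking.ordered_ids) != set(design.mirna_ids):
        raise DataError("ranking does not cover the miRNAs of C'")
    fc = _as_fc(fc_observed)
    ordered = ranking.ordered_ids if order == "forward" else ranking.ordered_ids[::-1]
    col_of = {m: i for i, m in enumerate(design.mirna_ids)}
    est = MiRNAPerturbationModel()
    n_mi = len(ordered)
    rho = np.empty(n_mi)
    cols: list[int] = []
    for n, mirna_id in enumerate(ordered, start=1):
        cols.append(col_of[mirna_id])
        est.fit(design.A[:, cols], fc)
        rho[n - 1] = est.rho_train_
    return CumulativeCurve(order, np.arange(1, n_mi + 1), rho)
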