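"""Structural features of miRNAs and fit-quality analysis of mRNAs.

miRNA features (length, GC content of the mature sequence / seed /
precursor, hairpin geometry from dot-bracket structures, number of
targeted transcripts, abundance) are compared between groups — by the
sign of the fitted perturbation coefficient, or top-ranked vs the rest —
with Mann–Whitney U tests.  mRNAs are classified by how well the model
predicts them (|observed − predicted| against a cut-off, 0.5 log2 units
by convention) and their annotations (3'-UTR length, AU-rich-element
counts, promoter-element counts, turnover times) compared between
good- and poor-fit groups with two-sample t-tests, optionally sweeping
the cut-off on a grid.

Dot-bracket conventions used here (declared stand-ins, configurable by
reading the code rather than the field's one true definition, which does
not exist): the hairpin length is the span from the first to the last
paired base on the 5' arm inclusive; complementary fragments are maximal
stacks of nested base pairs; unpaired fragments are maximal runs of
unpaired positions within the mature-miRNA span of the precursor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DataError,
    InvalidArgumentError,
    SequenceParseError,
    ShapeError,
)
from .expression import FoldChangeVector
from .interaction import DEFAULT_SEED_SPAN, WeightedTargetMatrix, _as_dna
from .model import FittedModel

FEATURE_COLUMNS = [
    "mature_length",
    "gc_mature",
    "gc_seed",
    "premirna_length",
    "gc_premirna",
    "hairpin_length",
    "n_gc_pairs",
    "n_unpaired_fragments",
    "mean_complementary_fragment_length",
    "n_targeted_transcripts",
    "expression",
]


def parse_dot_bracket(structure: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), 0-based, i < j, from a dot-bracket string."""
    if set(structure) - set("().-"):
        raise SequenceParseError(
            f"invalid characters in dot-bracket string: "
            f"{sorted(set(structure) - set('().-'))}"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise SequenceParseError("unbalanced dot-bracket: unmatched ')'")
            pairs.append((stack.pop(), i))
    if stack:
        raise SequenceParseError("unbalanced dot-bracket: unmatched '('")
    return sorted(pairs)


def _gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def _stem_lengths(pairs: list[tuple[int, int]]) -> list[int]:
    """Lengths of maximal stacks of nested base pairs (helical stems)."""
    pair_set = set(pairs)
    lengths = []
    for i, j in pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # interior of a stem
        length = 1
        while (i + length, j - length) in pair_set:
            length += 1
        lengths.append(length)
    return lengths


def _unpaired_runs(structure: str, span: tuple[int, int]) -> int:
    """Number of maximal runs of unpaired positions within [lo, hi)."""
    lo, hi = span
    runs = 0
    in_run = False
    for ch in structure[lo:hi]:
        if ch in ".-":
            if not in_run:
                runs += 1
            in_run = True
        else:
            in_run = False
    return runs


def compute_mirna_features(
    mature_seqs: dict[str, str],
    premirna_seqs: dict[str, str] | None = None,
    structures: dict[str, str] | None = None,
    targets: WeightedTargetMatrix | None = None,
    expr=None,
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
) -> pd.DataFrame:
    """Per-miRNA structural feature table.

    Sequence features come from the mature sequences; precursor features
    need ``premirna_seqs`` and Vienna-style ``structures`` (NaN where
    absent); ``targets`` supplies the number of targeted transcripts
    (weighted count > 0) and ``expr`` the log2 abundance.
    """
    premirna_seqs = premirna_seqs or {}
    structures = structures or {}
    lo, hi = seed_span
    rows = {}
    for mirna_id, mature_raw in mature_seqs.items():
        mature = _as_dna(mature_raw, f"mature sequence of {mirna_id}")
        if not (1 <= lo <= hi <= len(mature)):
            raise InvalidArgumentError(
                f"seed span {seed_span} outside mature miRNA {mirna_id}"
            )
        row = dict.fromkeys(FEATURE_COLUMNS, float("nan"))
        row["mature_length"] = len(mature)
        row["gc_mature"] = _gc_percent(mature)
        row["gc_seed"] = _gc_percent(mature[lo - 1 : hi])
        if mirna_id in premirna_seqs:
            pre = _as_dna(premirna_seqs[mirna_id], f"precursor of {mirna_id}")
            row["premirna_length"] = len(pre)
            row["gc_premirna"] = _gc_percent(pre)
            if mirna_id in structures:
                structure = structures[mirna_id]
                if len(structure) != len(pre):
                    raise DataError(
                        f"structure length {len(structure)} != precursor length "
                        f"{len(pre)} for {mirna_id}"
                    )
                pairs = parse_dot_bracket(structure)
                opening = [i for i, j in pairs]
                row["hairpin_length"] = (
                    max(opening) - min(opening) + 1 if opening else 0
                )
                row["n_gc_pairs"] = sum(
                    1 for i, j in pairs if {pre[i], pre[j]} == {"G", "C"}
                )
                stems = _stem_lengths(pairs)
                row["mean_complementary_fragment_length"] = (
                    float(np.mean(stems)) if stems else 0.0
                )
                start = pre.find(mature)
                if start < 0:
                    warnings.warn(
                        f"mature {mirna_id} not found in its precursor; "
                        "counting unpaired runs over the whole structure",
                        stacklevel=2,
                    )
                    mature_span = (0, len(pre))
                else:
                    mature_span = (start, start + len(mature))
                row["n_unpaired_fragments"] = _unpaired_runs(structure, mature_span)
        if targets is not None and mirna_id in targets.mirna_ids:
            col = targets.mirna_ids.index(mirna_id)
            row["n_targeted_transcripts"] = int(np.sum(targets.values[:, col] > 0))
        if expr is not None:
            try:
                row["expression"] = float(expr[mirna_id])
            except (KeyError, IndexError):
                pass
        rows[mirna_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")[FEATURE_COLUMNS]


def split_by_dk_sign(model: FittedModel) -> tuple[list[str], list[str], list[str]]:
    """Partition miRNA ids by the sign of their fitted dk.

    Returns (positive, negative, zero) id lists; positive dk means
    weakened repression after treatment.
    """
    dk = np.asarray(model.dk)
    ids = np.asarray(model.mirna_ids)
    return (
        list(ids[dk > 0]),
        list(ids[dk < 0]),
        list(ids[dk == 0]),
    )


@dataclass
class GroupComparison:
    """One feature compared between two groups."""

    feature: str
    test: str
    group_a_mean: float
    group_b_mean: float
    statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int


TESTS = ("mann_whitney_u", "two_sample_t")


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact null enumeration when both groups have at most 8 tie-free
    observations, otherwise the normal approximation with tie correction.
    """
    tie_free = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    features: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    test: str = "mann_whitney_u",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare every feature column between two groups of rows.

    Returns one record per feature with group means, the two-sided
    p-value and a significance flag at ``alpha``.  Features with fewer
    than two finite values in either group are skipped with a warning.
    """
    if test not in TESTS:
        raise InvalidArgumentError(f"test must be one of {TESTS}")
    if not group_a or not group_b:
        raise InvalidArgumentError("both groups must be non-empty")
    records = []
    for feature in features.columns:
        a = features.loc[features.index.intersection(group_a), feature].dropna().to_numpy(dtype=float)
        b = features.loc[features.index.intersection(group_b), feature].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            warnings.warn(f"skipping {feature}: fewer than 2 values per group", stacklevel=2)
            continue
        if test == "mann_whitney_u":
            statistic, p_value = _mann_whitney(a, b)
        else:
            res = stats.ttest_ind(a, b)
            statistic, p_value = float(res.statistic), float(res.pvalue)
        if np.isnan(p_value):
            warnings.warn(f"{feature}: degenerate comparison, p undefined", stacklevel=2)
            continue
        records.append(
            GroupComparison(
                feature=feature,
                test=test,
                group_a_mean=float(a.mean()),
                group_b_mean=float(b.mean()),
                statistic=statistic,
                p_value=p_value,
                significant=bool(p_value < alpha),
                n_a=int(a.size),
                n_b=int(b.size),
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class FitClassification:
    """mRNAs split by prediction accuracy at an absolute-error cut-off."""

    cutoff: float
    good_ids: list[str]
    poor_ids: list[str]
    abs_error: pd.Series


def _aligned_fc(fc_observed, fc_predicted) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(fc_observed, FoldChangeVector):
        ids = list(fc_observed.transcript_ids)
        obs = fc_observed.fc
    else:
        obs = np.asarray(fc_observed, dtype=float)
        ids = [str(i) for i in range(obs.size)]
    pred = fc_predicted.fc if isinstance(fc_predicted, FoldChangeVector) else np.asarray(fc_predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ShapeError(f"observed {obs.shape} and predicted {pred.shape} differ")
    return obs, pred, ids


def classify_mrna_fit(fc_observed, fc_predicted, cutoff: float = 0.5) -> FitClassification:
    """Split transcripts into good fit (|error| <= cutoff) and poor fit.

    The boundary case |error| == cutoff counts as good.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    obs, pred, ids = _aligned_fc(fc_observed, fc_predicted)
    abs_error = pd.Series(np.abs(obs - pred), index=ids)
    good = abs_error.index[abs_error <= cutoff]
    poor = abs_error.index[abs_error > cutoff]
    return FitClassification(float(cutoff), list(good), list(poor), abs_error)


def sweep_fit_cutoff(
    fc_observed,
    fc_predicted,
    annotations: pd.DataFrame,
    cutoffs,
    test: str = "two_sample_t",
    alpha: float = 0.05,
) -> dict[float, pd.DataFrame]:
    """Good/poor-fit comparisons of mRNA annotations over a cut-off grid.

    ``annotations`` is a numeric per-mRNA table (3'-UTR length, motif
    counts, turnover time, ...) indexed by transcript id.  Returns
    {cutoff: comparison table}.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(c <= 0 for c in cutoffs):
        raise InvalidArgumentError("all cutoffs must be positive")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise InvalidArgumentError("cutoff grid must be strictly increasing")
    out: dict[float, pd.DataFrame] = {}
    for cutoff in cutoffs:
        cls = classify_mrna_fit(fc_observed, fc_predicted, cutoff)
        out[cutoff] = compare_groups(annotations, cls.good_ids, cls.poor_ids, test, alpha)
    return out
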