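"""Weighted miRNA-target interaction matrices.

A transcript j is linked to a miRNA i through the number of predicted
binding sites in its 3'-UTR.  Predictions from several algorithms are
combined into a single weighted count

    c'_ji = sum_k  w_k * c^k_ji

where ``c^k_ji`` is the site count reported by algorithm k and ``w_k`` its
weight.  The default weights reflect how many prediction features each
algorithm considers (text scan, binding energy, conservation, RNA folding):
miRanda 0.3, TargetScan 0.3, RNAhybrid 0.3, NucleoSeq 0.1.

The module also provides the in-repo text-scan stage (seed-complement
counting in UTRs), AU-rich-element scanning, and randomized control
matrices used to validate fitted models against chance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DataError,
    InvalidArgumentError,
    SequenceParseError,
)

#: Default per-algorithm weights, proportional to the number of prediction
#: features each algorithm uses.
DEFAULT_WEIGHTS: dict[str, float] = {
    "miranda": 0.3,
    "targetscan": 0.3,
    "rnahybrid": 0.3,
    "nucleoseq": 0.1,
}

#: Default seed span on the mature miRNA: positions 2-8, 1-based inclusive
#: (the conventional 7-mer seed from the 5' end).
DEFAULT_SEED_SPAN: tuple[int, int] = (2, 8)

#: AU-rich element consensus; W is the IUPAC code for A or T.
ARE_CONSENSUS = "TTATTTAWW"

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_NT = re.compile(r"^[ACGTU]*$")

COUNT_TABLE_COLUMNS = ("mirna_id", "transcript_id", "algorithm", "count")


def _as_dna(sequence: str, what: str = "sequence") -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T, validating it."""
    seq = sequence.upper().replace("U", "T")
    if not _VALID_NT.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise SequenceParseError(f"invalid characters {bad} in {what}")
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement on the DNA alphabet (U treated as T)."""
    return _as_dna(sequence)[::-1].translate(_DNA_COMPLEMENT)


@dataclass
class WeightedTargetMatrix:
    """Dense transcripts x miRNAs matrix of weighted binding-site counts.

    Attributes
    ----------
    values : ndarray of shape (n_transcripts, n_mirnas)
        Non-negative weighted counts ``c'_ji``.
    transcript_ids, mirna_ids : list of str
        Row and column identifiers, unique, in matrix order.
    weights : dict
        The per-algorithm weights used to build the matrix (provenance).
    """

    values: np.ndarray
    transcript_ids: list[str]
    mirna_ids: list[str]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.transcript_ids = list(self.transcript_ids)
        self.mirna_ids = list(self.mirna_ids)
        if self.values.ndim != 2:
            raise DataError("matrix must be 2-dimensional")
        if self.values.shape != (len(self.transcript_ids), len(self.mirna_ids)):
            raise DataError("identifier lists do not match matrix dimensions")
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise DataError("duplicate transcript ids")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise DataError("duplicate miRNA ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=self.mirna_ids
        )


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format site-count table and return it.

    Expected columns: mirna_id, transcript_id, algorithm, count.  Counts must
    be non-negative integers and (mirna, transcript, algorithm) unique.
    """
    missing = set(COUNT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"count table lacks columns {sorted(missing)}")
    counts = table["count"].to_numpy()
    if len(counts) and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
        raise DataError("counts must be non-negative integers")
    key = ["mirna_id", "transcript_id", "algorithm"]
    if table.duplicated(subset=key).any():
        dup = table[table.duplicated(subset=key)].iloc[0]
        raise DataError(
            "duplicate record for "
            f"({dup['mirna_id']}, {dup['transcript_id']}, {dup['algorithm']})"
        )
    return table


def scan_seed_matches(
    utr_sequence: str,
    mature_mirna: str,
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
) -> int:
    """Count seed-complement sites of a miRNA in a 3'-UTR.

    The seed is the subsequence of the mature miRNA at ``seed_span``
    (1-based, inclusive, from the 5' end).  A site is an occurrence of the
    reverse complement of the seed (DNA alphabet) in the UTR; occurrences
    are counted non-overlapping, scanning left to right, because physically
    overlapping sites cannot be bound simultaneously.

    Returns the site count (0 for an empty UTR).
    """
    utr = _as_dna(utr_sequence, "UTR sequence")
    mature = _as_dna(mature_mirna, "mature miRNA")
    lo, hi = seed_span
    if not (1 <= lo <= hi <= len(mature)):
        raise InvalidArgumentError(
            f"seed span {seed_span} outside mature miRNA of length {len(mature)}"
        )
    site = reverse_complement(mature[lo - 1 : hi])
    if not utr:
        return 0
    # str.count is exactly the greedy non-overlapping left-to-right count
    return utr.count(site)


def count_are_motifs(utr_sequence: str) -> int:
    """Count AU-rich-element motifs matching the TTATTTAWW consensus.

    W is A or T.  Because the consensus is degenerate, occurrences are
    allowed to overlap (lookahead matching).
    """
    utr = _as_dna(utr_sequence, "UTR sequence")
    return len(re.findall(r"(?=TTATTTA[AT][AT])", utr))


def build_weighted_matrix(
    tables: pd.DataFrame | list[pd.DataFrame],
    weights: dict[str, float] | None = None,
    transcript_ids: list[str] | None = None,
    mirna_ids: list[str] | None = None,
) -> WeightedTargetMatrix:
    """Combine per-algorithm count tables into the weighted matrix C'.

    Parameters
    ----------
    tables : DataFrame or list of DataFrame
        Long-format records (mirna_id, transcript_id, algorithm, count).
        Absent (transcript, miRNA, algorithm) records count as 0.
    weights : dict, optional
        Algorithm name -> non-negative weight; defaults to
        :data:`DEFAULT_WEIGHTS`.  Every algorithm appearing in the tables
        must have a weight.
    transcript_ids, mirna_ids : list, optional
        Row/column ordering.  Defaults to sorted identifiers found in the
        tables.
    """
    if weights is None:
        weights = dict(DEFAULT_WEIGHTS)
    if not weights or any(w < 0 for w in weights.values()):
        raise ConfigurationError("weights must be non-negative")
    if not any(w > 0 for w in weights.values()):
        raise ConfigurationError("at least one weight must be positive")

    if isinstance(tables, list):
        table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=list(COUNT_TABLE_COLUMNS))
        )
    else:
        table = tables
    table = validate_count_table(table)

    unknown = set(table["algorithm"].unique()) - set(weights)
    if unknown:
        raise ConfigurationError(f"no weight configured for algorithms {sorted(unknown)}")

    if transcript_ids is None:
        transcript_ids = sorted(table["transcript_id"].unique())
    if mirna_ids is None:
        mirna_ids = sorted(table["mirna_id"].unique())

    row_index = {t: j for j, t in enumerate(transcript_ids)}
    col_index = {m: i for i, m in enumerate(mirna_ids)}
    values = np.zeros((len(transcript_ids), len(mirna_ids)))
    known = table[
        table["transcript_id"].isin(row_index) & table["mirna_id"].isin(col_index)
    ]
    if len(known):
        rows = known["transcript_id"].map(row_index).to_numpy()
        cols = known["mirna_id"].map(col_index).to_numpy()
        w = known["algorithm"].map(weights).to_numpy(dtype=float)
        np.add.at(values, (rows, cols), w * known["count"].to_numpy(dtype=float))
    return WeightedTargetMatrix(values, transcript_ids, mirna_ids, dict(weights))


def scan_utr_counts(
    utr_records: dict[str, str],
    mature_records: dict[str, str],
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
    algorithm: str = "nucleoseq",
) -> pd.DataFrame:
    """Text-scan every (UTR, miRNA) pair into a long-format count table.

    This is the in-repo stage standing alongside the external prediction
    algorithms: a pure seed-complement substring scan.
    """
    records = []
    for mirna_id, mature in mature_records.items():
        for transcript_id, utr in utr_records.items():
            n = scan_seed_matches(utr, mature, seed_span)
            records.append((mirna_id, transcript_id, algorithm, n))
    return pd.DataFrame(records, columns=list(COUNT_TABLE_COLUMNS))


RANDOMIZATION_SCHEMES = ("uniform", "permute", "permute_after_fit")


def randomize_matrix(
    C_prime: WeightedTargetMatrix,
    scheme: str,
    seed: int | np.random.Generator | None = None,
) -> WeightedTargetMatrix:
    """Produce a randomized control matrix for model validation.

    Schemes
    -------
    ``uniform``
        Same shape, entries i.i.d. Uniform[0, 1]; conserves nothing but
        the dimensions.
    ``permute`` / ``permute_after_fit``
        Global shuffle of all entries of C'; the multiset of entries is
        conserved while row and column structure is destroyed.  The two
        permutation schemes differ only in how the result is used
        downstream (fit-and-predict vs predict-only).
    """
    if scheme not in RANDOMIZATION_SCHEMES:
        raise InvalidArgumentError(
            f"unknown scheme {scheme!r}; expected one of {RANDOMIZATION_SCHEMES}"
        )
    rng = np.random.default_rng(seed)
    if scheme == "uniform":
        values = rng.uniform(0.0, 1.0, size=C_prime.shape)
    else:
        values = rng.permutation(C_prime.values.ravel()).reshape(C_prime.shape)
    return WeightedTargetMatrix(
        values, C_prime.transcript_ids, C_prime.mirna_ids, dict(C_prime.weights)
    )
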