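"""Synthetic datasets with the statistical structure the model assumes.

The generators emulate the inputs of the perturbation pipeline so every
downstream stage is testable without microarray downloads:

* sparse non-negative integer binding-site count tables (four algorithm
  layers sharing one active-pair support),
* log2-scale miRNA abundances above a noise floor,
* mRNA fold changes produced by the linear model
  ``fc = C' diag(miRNA) dk + b0 + eps`` with a small planted set of active
  miRNAs,
* UTR sequences with exactly planted seed-complement sites (fixtures for
  the text scanner), and
* two-component Gaussian-mixture expression vectors (fixtures for the
  noise filter).

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, ShapeError
from .interaction import (
    COUNT_TABLE_COLUMNS,
    DEFAULT_SEED_SPAN,
    WeightedTargetMatrix,
    build_weighted_matrix,
    reverse_complement,
    scan_seed_matches,
)

ALGORITHMS = ("miranda", "targetscan", "rnahybrid", "nucleoseq")


@dataclass
class SyntheticDataset:
    """A generated study: counts, abundances, truth, and observed fold changes."""

    target_counts: pd.DataFrame
    C_prime: WeightedTargetMatrix
    mirna_expr: np.ndarray
    true_dk: np.ndarray
    true_b0: float
    noise_sd: float
    fc_observed: np.ndarray
    active_set: list[str]
    seed: int
    transcript_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)

    @property
    def fc_noiseless(self) -> np.ndarray:
        """Model prediction from the true parameters, without noise."""
        A = self.C_prime.values * self.mirna_expr
        return A @ self.true_dk + self.true_b0


def generate_target_counts(
    n_mrna: int,
    n_mirna: int,
    sparsity: float = 0.05,
    count_mean: float = 1.5,
    seed: int | None = None,
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> pd.DataFrame:
    """Generate per-algorithm binding-site count tables.

    Pairs (transcript, miRNA) are active with probability ``sparsity``; the
    active support is shared by all algorithm layers (prediction algorithms
    largely agree on which pairs interact and differ in site counts).  At an
    active pair each algorithm reports ``1 + Poisson(count_mean - 1)`` sites
    so the mean active count is ``count_mean`` and the nonzero fraction per
    layer equals ``sparsity``.  ``count_mean = 0`` degenerates to the empty
    table.

    Returns a long-format table (mirna_id, transcript_id, algorithm, count)
    containing only the nonzero records.
    """
    if n_mrna < 1 or n_mirna < 1:
        raise InvalidArgumentError("n_mrna and n_mirna must be positive")
    if not (0 < sparsity <= 1):
        raise InvalidArgumentError("sparsity must lie in (0, 1]")
    if count_mean < 0:
        raise InvalidArgumentError("count_mean must be non-negative")
    rng = np.random.default_rng(seed)

    transcript_ids = [f"tx{j:05d}" for j in range(n_mrna)]
    mirna_ids = [f"mir{i:04d}" for i in range(n_mirna)]
    records: list[tuple[str, str, str, int]] = []
    if count_mean > 0:
        active = rng.random((n_mrna, n_mirna)) < sparsity
        rows, cols = np.nonzero(active)
        for algorithm in algorithms:
            counts = 1 + rng.poisson(max(count_mean - 1.0, 0.0), size=rows.size)
            for r, c, n in zip(rows, cols, counts):
                records.append((mirna_ids[c], transcript_ids[r], algorithm, int(n)))
    table = pd.DataFrame(records, columns=list(COUNT_TABLE_COLUMNS))
    table.attrs["transcript_ids"] = transcript_ids
    table.attrs["mirna_ids"] = mirna_ids
    return table


def generate_fold_changes(
    C_prime: WeightedTargetMatrix | np.ndarray,
    mirna_expr: np.ndarray,
    true_dk: np.ndarray,
    true_b0: float,
    noise_sd: float,
    seed: int | None = None,
) -> np.ndarray:
    """Generate observed fold changes from the linear perturbation model.

    ``fc = C' diag(mirna_expr) dk + b0 + eps`` with ``eps ~ N(0, noise_sd^2)``
    i.i.d. per transcript.  With ``noise_sd = 0`` the output equals the
    deterministic model prediction.
    """
    values = C_prime.values if isinstance(C_prime, WeightedTargetMatrix) else np.asarray(C_prime)
    mirna_expr = np.asarray(mirna_expr, dtype=float)
    true_dk = np.asarray(true_dk, dtype=float)
    if values.ndim != 2 or values.shape[1] != mirna_expr.shape[0] or mirna_expr.shape != true_dk.shape:
        raise ShapeError(
            f"non-conformable shapes: C'{values.shape}, miRNA{mirna_expr.shape}, dk{true_dk.shape}"
        )
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    fc = (values * mirna_expr) @ true_dk + true_b0
    if noise_sd > 0:
        fc = fc + rng.normal(0.0, noise_sd, size=fc.shape)
    return fc


def generate_mixture_expression(
    n_features: int,
    weights: tuple[float, float],
    means: tuple[float, float],
    sds: tuple[float, float],
    seed: int | None = None,
) -> np.ndarray:
    """Draw log2 expression levels from a two-component Gaussian mixture.

    Emulates the bimodal signal/noise structure of microarray expression
    summaries on which the noise filter operates.
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("mixture weights must sum to 1")
    if np.any(sds <= 0):
        raise InvalidArgumentError("mixture SDs must be positive")
    rng = np.random.default_rng(seed)
    component = rng.random(n_features) >= weights[0]
    values = rng.normal(means[component.astype(int)], sds[component.astype(int)])
    return values


def generate_planted_sequences(
    n_utr: int,
    utr_len: int,
    mirna_seqs: dict[str, str],
    insert_counts: np.ndarray | pd.DataFrame,
    seed: int | None = None,
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
    max_redraws: int = 200,
) -> dict[str, str]:
    """Build UTR sequences containing exactly the requested seed sites.

    Each UTR hosts ``insert_counts[u, m]`` copies of the seed-complement
    site of miRNA ``m`` at non-overlapping random positions; the remaining
    background is uniform over {A,C,G,T} and is re-drawn whenever a spurious
    match changes any scan count, so the scanner's output table equals
    ``insert_counts`` exactly.

    Returns ``{utr_id: sequence}``; UTR ids are ``utr0000``, ``utr0001``...
    and miRNA columns follow the order of ``mirna_seqs``.
    """
    if isinstance(insert_counts, pd.DataFrame):
        insert_counts = insert_counts.to_numpy()
    insert_counts = np.asarray(insert_counts, dtype=int)
    mirna_ids = list(mirna_seqs)
    if insert_counts.shape != (n_utr, len(mirna_ids)):
        raise ShapeError(
            f"insert_counts shape {insert_counts.shape} != ({n_utr}, {len(mirna_ids)})"
        )
    if np.any(insert_counts < 0):
        raise InvalidArgumentError("insert counts must be non-negative")
    lo, hi = seed_span
    sites = {
        mid: reverse_complement(seq.upper().replace("U", "T")[lo - 1 : hi])
        for mid, seq in mirna_seqs.items()
    }
    rng = np.random.default_rng(seed)

    utrs: dict[str, str] = {}
    for u in range(n_utr):
        wanted = insert_counts[u]
        motifs: list[str] = []
        for m, mid in enumerate(mirna_ids):
            motifs.extend([sites[mid]] * wanted[m])
        total_len = sum(len(s) for s in motifs)
        if total_len > utr_len:
            raise InvalidArgumentError(
                f"UTR {u}: {total_len} nt of sites exceed UTR length {utr_len}"
            )
        for attempt in range(max_redraws):
            order = rng.permutation(len(motifs))
            slack = utr_len - total_len
            # stars-and-bars placement: uniform offsets into the slack
            offsets = np.sort(rng.integers(0, slack + 1, size=len(motifs)))
            seq = np.array(list("ACGT"))[rng.integers(0, 4, size=utr_len)]
            pos = 0
            consumed = 0
            for rank, k in enumerate(order):
                start = offsets[rank] + consumed
                motif = motifs[k]
                seq[start : start + len(motif)] = list(motif)
                consumed += len(motif)
            candidate = "".join(seq)
            ok = all(
                scan_seed_matches(candidate, mirna_seqs[mid], seed_span) == wanted[m]
                for m, mid in enumerate(mirna_ids)
            )
            if ok:
                utrs[f"utr{u:04d}"] = candidate
                break
        else:
            raise InvalidArgumentError(
                f"UTR {u}: could not avoid spurious seed matches after "
                f"{max_redraws} redraws"
            )
    return utrs


def noise_sd_for_r_squared(signal: np.ndarray, r_squared: float) -> float:
    """Noise SD giving the requested fraction of explained variance.

    For additive independent noise, R^2 = var(signal) / (var(signal) +
    noise_sd^2); solving gives ``noise_sd = sd(signal) * sqrt((1-R^2)/R^2)``.
    """
    if not (0 < r_squared <= 1):
        raise InvalidArgumentError("r_squared must lie in (0, 1]")
    return float(np.std(signal) * np.sqrt((1.0 - r_squared) / r_squared))


def make_dataset(
    n_mrna: int = 3000,
    n_mirna: int = 150,
    n_active: int = 30,
    sparsity: float = 0.05,
    count_mean: float = 1.5,
    dk_scale: float = 0.01,
    noise_sd: float | None = None,
    r_squared: float = 0.35,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete synthetic study for parameter-recovery work.

    Defaults emulate the study conditions the pipeline targets: a few
    thousand transcripts, order-a-hundred miRNAs of which ~30 are truly
    active, per-miRNA perturbation coefficients of magnitude ~1e-2, miRNA
    abundances Uniform(2, 12) on the log2 scale, and additive Gaussian
    fold-change noise.  If ``noise_sd`` is None it is set so the model
    explains a fraction ``r_squared`` of the fold-change variance.
    """
    if n_active > n_mirna:
        raise InvalidArgumentError("n_active cannot exceed n_mirna")
    rng = np.random.default_rng(seed)
    # distinct child seeds (kept below 2**31) for each generator stage
    sub = rng.integers(0, 2**31 - 1, size=4)

    table = generate_target_counts(n_mrna, n_mirna, sparsity, count_mean, int(sub[0]))
    transcript_ids = table.attrs["transcript_ids"]
    mirna_ids = table.attrs["mirna_ids"]
    C_prime = build_weighted_matrix(
        table, transcript_ids=transcript_ids, mirna_ids=mirna_ids
    )

    mirna_expr = rng.uniform(2.0, 12.0, size=n_mirna)
    active_idx = rng.choice(n_mirna, size=n_active, replace=False)
    true_dk = np.zeros(n_mirna)
    true_dk[active_idx] = rng.normal(0.0, dk_scale, size=n_active)
    true_b0 = float(rng.uniform(-0.3, 0.3))

    signal = (C_prime.values * mirna_expr) @ true_dk
    if noise_sd is None:
        noise_sd = noise_sd_for_r_squared(signal, r_squared)
    fc = generate_fold_changes(
        C_prime, mirna_expr, true_dk, true_b0, noise_sd, int(sub[1])
    )
    return SyntheticDataset(
        target_counts=table,
        C_prime=C_prime,
        mirna_expr=mirna_expr,
        true_dk=true_dk,
        true_b0=true_b0,
        noise_sd=float(noise_sd),
        fc_observed=fc,
        active_set=sorted(mirna_ids[i] for i in active_idx),
        seed=int(seed),
        transcript_ids=transcript_ids,
        mirna_ids=mirna_ids,
    )
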