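"""Permutation null for pair scores via shuffling of the DNA target sites.

The observed Zpx of a focal column pair is compared against the distribution
of Zpx values obtained after randomly shuffling the DNA target sequences and
rescoring the whole alignment.  Three shuffling schemes are provided:

``assignment``
    permutes whole 22-nt site rows across members, breaking the
    protein-site pairing while preserving every site sequence and every
    nucleotide column's composition (the default: both marginals intact);
``within_site``
    permutes the nucleotides inside each member's own site;
``within_column``
    permutes each nucleotide column independently across members.

Randomness is counter-based: shuffle ``k`` of a run seeded with ``s`` uses
``numpy.random.default_rng([s, k])``, so results do not depend on evaluation
order or parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import ColumnLabel, ConcatenatedAlignment
from .covariation import (
    apc,
    encode,
    joint_counts,
    mi_from_joint,
    mi_matrix,
    one_hot,
    zpx_scores,
)
from .errors import PdcovarError

SCHEMES = ("assignment", "within_site", "within_column")


@dataclass
class NullDistribution:
    """Shuffle-derived Zpx sample for one focal pair."""

    focal_pair: tuple[str, str]
    scheme: str
    n_shuffles: int
    seed: int
    scores: np.ndarray
    observed: float

    def quantiles(self, q=(0.025, 0.5, 0.975)) -> dict[float, float]:
        return {float(x): float(np.quantile(self.scores, x)) for x in q}


def _scheme_indexer(scheme: str, rng: np.random.Generator, n: int, m: int):
    """Index arrays that reorder an (n, m, ...) nucleotide block."""
    if scheme == "assignment":
        return rng.permutation(n), slice(None)
    if scheme == "within_site":
        cols = np.array([rng.permutation(m) for _ in range(n)])
        return np.arange(n)[:, None], cols
    if scheme == "within_column":
        rows = np.column_stack([rng.permutation(n) for _ in range(m)])
        return rows, np.arange(m)[None, :]
    raise ValueError(f"unknown shuffle scheme {scheme!r}; choose from {SCHEMES}")


def shuffle_sites(
    aln: ConcatenatedAlignment,
    scheme: str = "assignment",
    rng: np.random.Generator | None = None,
) -> ConcatenatedAlignment:
    """Return a copy of the alignment with shuffled DNA, protein untouched."""
    if rng is None:
        rng = np.random.default_rng()
    n_idx = aln.nucleotide_column_indices
    if n_idx.size == 0:
        raise PdcovarError("alignment has no nucleotide block")
    rows, cols = _scheme_indexer(scheme, rng, aln.n_members, n_idx.size)
    matrix = aln.matrix.copy()
    block = matrix[:, n_idx]
    matrix[:, n_idx] = block[rows, cols]
    return ConcatenatedAlignment(
        member_ids=list(aln.member_ids), columns=list(aln.columns), matrix=matrix
    )


def _zpx_square(M: np.ndarray) -> np.ndarray:
    """Square matrix of Zpx values from a square MI matrix."""
    A = apc(M)
    m = M.shape[0]
    iu = np.triu_indices(m, k=1)
    mi_v, apc_v = M[iu], A[iu]
    ok = np.isfinite(mi_v)
    z_v = zpx_scores((mi_v - apc_v)[ok])
    Z = np.full((m, m), np.nan)
    Z[iu[0][ok], iu[1][ok]] = z_v
    Z[iu[1][ok], iu[0][ok]] = z_v
    return Z


def null_distribution(
    aln: ConcatenatedAlignment,
    focal_pair: tuple[ColumnLabel | str, ColumnLabel | str],
    n_shuffles: int = 10_000,
    scheme: str = "assignment",
    seed: int = 0,
) -> NullDistribution:
    """Zpx null for ``focal_pair`` from repeated DNA shuffling and rescoring.

    Each shuffle triggers a full rescoring (MI -> APC -> MIp -> Zpx); only
    the MI entries a scheme can change are recomputed (protein-protein MI is
    invariant under all schemes, DNA-DNA MI under ``assignment``), which is
    an exact optimization, not an approximation.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown shuffle scheme {scheme!r}; choose from {SCHEMES}")
    fi = aln.column_index(focal_pair[0])
    fj = aln.column_index(focal_pair[1])

    M0, _ = mi_matrix(aln)
    Z0 = _zpx_square(M0)
    observed = float(Z0[fi, fj])
    if not np.isfinite(observed):
        raise KeyError(f"focal pair {focal_pair!r} is not scoreable")

    p_idx = aln.protein_column_indices
    n_idx = aln.nucleotide_column_indices
    if n_idx.size == 0:
        raise PdcovarError("alignment has no nucleotide block")
    oh = one_hot(encode(aln))
    # protein columns only use codes 0..19, nucleotide columns 20..23;
    # trimming the one-hot slabs shrinks every joint table accordingly
    ohP = oh[:, p_idx, :20]
    ohD0 = oh[:, n_idx, 20:24]
    cross_ix = np.ix_(p_idx, n_idx)
    cross_ix_t = np.ix_(n_idx, p_idx)
    dna_ix = np.ix_(n_idx, n_idx)

    scores = np.empty(n_shuffles, dtype=np.float64)
    M = M0.copy()
    for k in range(n_shuffles):
        rng = np.random.default_rng([seed, k])
        rows, cols = _scheme_indexer(scheme, rng, aln.n_members, n_idx.size)
        ohD = ohD0[rows, cols]
        cross = mi_from_joint(joint_counts(ohP, ohD))
        M[cross_ix] = cross
        M[cross_ix_t] = cross.T
        if scheme != "assignment":
            dd = mi_from_joint(joint_counts(ohD, ohD))
            np.fill_diagonal(dd, np.nan)
            M[dna_ix] = dd
        Z = _zpx_square(M)
        scores[k] = Z[fi, fj]

    return NullDistribution(
        focal_pair=(str(aln.columns[fi]), str(aln.columns[fj])),
        scheme=scheme,
        n_shuffles=n_shuffles,
        seed=seed,
        scores=scores,
        observed=observed,
    )


def empirical_p(null: NullDistribution) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (n + 1)."""
    if null.n_shuffles < 1:
        raise PdcovarError("empirical p undefined for an empty null")
    exceed = int(np.sum(null.scores >= null.observed))
    return (1 + exceed) / (null.n_shuffles + 1)
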