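"""Pairwise covariation statistics over a concatenated protein-DNA alignment.

For every pair of alignment columns (protein-protein, protein-DNA and
DNA-DNA alike) the mutual information

    MI(i, j) = sum_{x,y} p(x, y) log2 [ p(x, y) / (p(x) p(y)) ]

is computed in bits from raw symbol frequencies over the members that are
non-gap in both columns (pairwise-complete; gaps are never a 21st symbol and
no pseudocounts or sequence weights are applied).  Shared phylogenetic and
entropic signal is removed with the average-product correction

    APC(i, j) = mean_MI(i) * mean_MI(j) / mean_MI,      MIp = MI - APC,

where mean_MI(i) is the mean MI of column i against all other scoreable
columns and mean_MI the grand mean over all scoreable pairs.  MIp values are
Z-standardized over the full pair pool to give the Zpx score used for
ranking candidate coevolving pairs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignments import (
    GAP,
    NUCLEOTIDE,
    PROTEIN,
    ColumnLabel,
    ConcatenatedAlignment,
)
from .errors import (
    DegenerateAlignmentError,
    InsufficientDataError,
    StandardizationError,
)

# Unified symbol coding: amino acids 0..19, nucleotides 20..23, gap/unknown 24.
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = {aa: i for i, aa in enumerate(_AA_ORDER)}
_NT_CODE = {"A": 20, "C": 21, "G": 22, "T": 23}
N_CODES = 24  # valid codes; code 24 (gap/X) is dropped from the one-hot
_INVALID = 24

AA_AA = "AA_AA"
AA_DNA = "AA_DNA"
DNA_DNA = "DNA_DNA"


def pair_class(kind_i: str, kind_j: str) -> str:
    n_dna = (kind_i == NUCLEOTIDE) + (kind_j == NUCLEOTIDE)
    return (AA_AA, AA_DNA, DNA_DNA)[n_dna]


# ---------------------------------------------------------------------------
# encoding

def encode(aln: ConcatenatedAlignment) -> np.ndarray:
    """Integer-code an alignment column-kind-aware; gaps/X become code 24."""
    codes = np.full(aln.matrix.shape, _INVALID, dtype=np.int8)
    for j, col in enumerate(aln.columns):
        table = _AA_CODE if col.kind == PROTEIN else _NT_CODE
        for r in range(aln.n_members):
            codes[r, j] = table.get(aln.matrix[r, j], _INVALID)
    return codes


def one_hot(codes: np.ndarray) -> np.ndarray:
    """(n, m, 24) indicator array; gapped cells are all-zero rows.

    Because gap cells contribute nothing, the tensor contraction of two
    one-hot slabs yields joint counts over pairwise-complete members only.
    """
    n, m = codes.shape
    oh = np.zeros((n, m, N_CODES), dtype=np.float64)
    valid = codes < N_CODES
    rr, cc = np.nonzero(valid)
    oh[rr, cc, codes[rr, cc]] = 1.0
    return oh


def mi_from_joint(counts: np.ndarray) -> np.ndarray:
    """MI in bits from joint count tables of shape (..., A, B).

    Entries with fewer than two complete observations are NaN.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=(-2, -1))
    row = counts.sum(axis=-1)
    col = counts.sum(axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = (
            np.log2(counts)
            + np.log2(n)[..., None, None]
            - np.log2(row)[..., :, None]
            - np.log2(col)[..., None, :]
        )
        terms = np.where(counts > 0, counts * log_term, 0.0)
        mi = terms.sum(axis=(-2, -1)) / n
    mi = np.where(n >= 2, np.maximum(mi, 0.0), np.nan)
    return mi


def joint_counts(oh_a: np.ndarray, oh_b: np.ndarray) -> np.ndarray:
    """Joint count tables between two one-hot blocks.

    ``oh_a``: (n, ma, A); ``oh_b``: (n, mb, B) -> counts (ma, mb, A, B).
    """
    c = np.tensordot(oh_a, oh_b, axes=([0], [0]))  # (ma, A, mb, B)
    return c.transpose(0, 2, 1, 3)


def mi_matrix(
    aln: ConcatenatedAlignment, chunk: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Full symmetric MI matrix (bits) and pairwise-complete counts.

    Diagonal and pairs with <2 complete members are NaN; n_eff is the number
    of members non-gap in both columns.
    """
    codes = encode(aln)
    oh = one_hot(codes)
    m = aln.n_columns
    M = np.empty((m, m), dtype=np.float64)
    N = np.empty((m, m), dtype=np.float64)
    for i0 in range(0, m, chunk):
        i1 = min(i0 + chunk, m)
        C = joint_counts(oh[:, i0:i1], oh)
        M[i0:i1] = mi_from_joint(C)
        N[i0:i1] = C.sum(axis=(-2, -1))
    np.fill_diagonal(M, np.nan)
    # enforce exact symmetry (summation order differs between (i,j) and (j,i))
    iu = np.triu_indices(m, k=1)
    M[iu[1], iu[0]] = M[iu]
    N[iu[1], iu[0]] = N[iu]
    return M, N


# ---------------------------------------------------------------------------
# elementary statistics (reference, per-column API)

def _symbols(column: Iterable[str]) -> np.ndarray:
    if isinstance(column, str):
        column = list(column)
    return np.asarray(list(column), dtype="<U1")


def column_entropy(column: Iterable[str]) -> float:
    """Shannon entropy of a column in bits over non-gap symbols."""
    sym = _symbols(column)
    sym = sym[(sym != GAP) & (sym != "X")]
    if sym.size < 2:
        raise InsufficientDataError("need at least 2 non-gap symbols")
    _, counts = np.unique(sym, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(col_i: Iterable[str], col_j: Iterable[str]) -> float:
    """MI in bits between two columns over pairwise-complete members."""
    a, b = _symbols(col_i), _symbols(col_j)
    if a.size != b.size:
        raise ValueError("columns must have equal length")
    ok = (a != GAP) & (a != "X") & (b != GAP) & (b != "X")
    if ok.sum() < 2:
        raise InsufficientDataError("need at least 2 pairwise-complete members")
    a, b = a[ok], b[ok]
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    counts = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    return float(mi_from_joint(counts))


# ---------------------------------------------------------------------------
# APC / MIp / Zpx

def apc(mi: np.ndarray) -> np.ndarray:
    """Average-product correction per pair from a square MI matrix.

    ``mi`` is symmetric with NaN on the diagonal (and on unscoreable pairs).
    APC(i,j) = mean_MI(i) * mean_MI(j) / mean_MI; NaN wherever MI is NaN.
    """
    M = np.asarray(mi, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("mi must be a square matrix")
    iu = np.triu_indices(M.shape[0], k=1)
    vals = M[iu]
    scoreable = np.isfinite(vals)
    if scoreable.sum() < 2:
        raise DegenerateAlignmentError(
            "APC needs at least two scoreable pairs to define column means"
        )
    overall = float(vals[scoreable].mean())
    if overall == 0.0:
        raise DegenerateAlignmentError("overall mean MI is zero")
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(M, axis=1)
    out = np.outer(col_means, col_means) / overall
    out[~np.isfinite(M)] = np.nan
    return out


def zpx_scores(mip: np.ndarray) -> np.ndarray:
    """Global Z-standardization of a MIp vector (sample sd, ddof=1)."""
    mip = np.asarray(mip, dtype=np.float64)
    mu = mip.mean()
    sd = mip.std(ddof=1) if mip.size > 1 else 0.0
    if not np.isfinite(sd) or sd == 0.0:
        raise StandardizationError("MIp scores have zero spread")
    return (mip - mu) / sd


def score_pairs(aln: ConcatenatedAlignment) -> pd.DataFrame:
    """Score all column pairs of an alignment.

    Returns a DataFrame with one row per unordered scoreable pair
    (columns ``pos_i, pos_j, pair_class, n_eff, mi, apc, mip, zpx``),
    ordered by column position with i < j.
    """
    if aln.n_members < 2:
        raise InsufficientDataError("need at least 2 members")
    M, N = mi_matrix(aln)
    A = apc(M)
    iu = np.triu_indices(aln.n_columns, k=1)
    mi_v, apc_v, n_v = M[iu], A[iu], N[iu]
    ok = np.isfinite(mi_v)
    ii, jj = iu[0][ok], iu[1][ok]
    mi_v, apc_v, n_v = mi_v[ok], apc_v[ok], n_v[ok]
    mip_v = mi_v - apc_v
    zpx_v = zpx_scores(mip_v)
    labels = aln.columns
    return pd.DataFrame(
        {
            "pos_i": [str(labels[i]) for i in ii],
            "pos_j": [str(labels[j]) for j in jj],
            "pair_class": [
                pair_class(labels[i].kind, labels[j].kind) for i, j in zip(ii, jj)
            ],
            "n_eff": n_v.astype(int),
            "mi": mi_v,
            "apc": apc_v,
            "mip": mip_v,
            "zpx": zpx_v,
        }
    )


def top_pairs(
    table: pd.DataFrame, k: int, class_filter: str | None = None
) -> pd.DataFrame:
    """Top-k pairs by Zpx (ties: MI descending, then label order)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if table.empty and class_filter is None:
        raise ValueError("pair table is empty")
    t = table
    if class_filter is not None:
        t = t[t["pair_class"] == class_filter]
    t = t.sort_values(
        by=["zpx", "mi", "pos_i", "pos_j"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return t.head(k).reset_index(drop=True)
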