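"""Depletion-rate estimation and substrate-preference summaries.

Sequencing counts are compositional: only relative abundances are
informative.  Each sample (enzyme, replicate, timepoint) is therefore
transformed with a centered log-ratio,

    clr_s = log2(c_s + q) - mean_s' log2(c_s' + q),

with pseudocount q (default 0.5).  Because an exponentially depleted
substrate obeys  A_s(t) = A_s(0) * 2^(k_s t),  its CLR value is linear in
time with slope  k_s - mean(k),  so an ordinary least-squares fit of CLR
against minutes, pooling replicates into one regression per substrate,
yields the relative depletion rate k_rel (log2 units per minute; more
negative = faster cleaved) along with the regression's residual standard
error ("standard error of the estimate", sigma) and the slope's own SE.

Enzymes are compared substrate-by-substrate with an axis-aligned ellipse
test (semi-axes n_sd * sigma per enzyme, centered on the identity line), and
preference is summarized as a per-position nucleotide weight matrix over a
chosen substrate subset (logo-ready).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, NormalizationError, TransformError

NUCLEOTIDES = "ACGT"


# ---------------------------------------------------------------------------
# CLR

def clr_transform(
    counts,
    pseudocount: float = 0.5,
    n_mc: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Centered log-ratio (base 2) of one sample's count vector.

    With ``n_mc > 0`` the point estimate is replaced by the mean CLR over
    ``n_mc`` Dirichlet(counts + pseudocount) Monte-Carlo instances of the
    underlying composition (seeded via ``rng``); the default is the single
    deterministic transform.
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise TransformError("counts must be non-negative")
    if c.max(initial=0.0) + pseudocount <= 0:
        raise TransformError("all-zero sample cannot be CLR-transformed without a pseudocount")
    if n_mc > 0:
        if rng is None:
            rng = np.random.default_rng()
        draws = rng.dirichlet(c + pseudocount, size=n_mc)
        logs = np.log2(draws)
        return (logs - logs.mean(axis=1, keepdims=True)).mean(axis=0)
    logs = np.log2(c + pseudocount)
    return logs - logs.mean()


def clr_table(count_table: pd.DataFrame, pseudocount: float = 0.5, **kwargs) -> pd.DataFrame:
    """CLR-transform every sample (column) of a count table."""
    out = {
        col: clr_transform(count_table[col].to_numpy(), pseudocount, **kwargs)
        for col in count_table.columns
    }
    return pd.DataFrame(out, index=count_table.index)


# ---------------------------------------------------------------------------
# rate fitting

def _ols(Y: np.ndarray, t: np.ndarray):
    """Vectorized per-row OLS of Y (rows) against t; returns fit summaries."""
    n = t.size
    tc = t - t.mean()
    sxx = float((tc**2).sum())
    slope = Y @ tc / sxx
    intercept = Y.mean(axis=1) - slope * t.mean()
    resid = Y - (intercept[:, None] + slope[:, None] * t[None, :])
    rss = (resid**2).sum(axis=1)
    dof = n - 2
    sigma = np.sqrt(rss / dof) if dof > 0 else np.zeros_like(rss)
    se_slope = sigma / np.sqrt(sxx)
    return slope, intercept, sigma, se_slope


def depletion_rates(
    clr: pd.DataFrame, times: Sequence[float], enzyme: str | None = None
) -> pd.DataFrame:
    """Per-substrate depletion rate k_rel from CLR values over time.

    ``clr`` is substrates x samples; ``times`` gives each sample's timepoint
    in minutes (replicates appear as repeated timepoints and are pooled into
    a single fit).  Returns a DataFrame indexed by substrate with columns
    ``k_rel`` (slope), ``se_slope``, ``sigma`` (residual standard error of
    the regression), ``intercept`` and ``n_points``.
    """
    t = np.asarray(list(times), dtype=np.float64)
    if t.size != clr.shape[1]:
        raise ValueError("times must match the number of samples")
    if np.unique(t).size < 2:
        raise FitError("need at least 2 distinct timepoints")
    slope, intercept, sigma, se_slope = _ols(clr.to_numpy(dtype=np.float64), t)
    out = pd.DataFrame(
        {
            "k_rel": slope,
            "se_slope": se_slope,
            "sigma": sigma,
            "intercept": intercept,
            "n_points": t.size,
        },
        index=clr.index,
    )
    if enzyme is not None:
        out.attrs["enzyme"] = enzyme
    return out


def sample_times(columns) -> np.ndarray:
    """Timepoints from sample keys of the form (enzyme, replicate, time_min)."""
    return np.asarray([float(c[-1]) for c in columns])


def rates_from_counts(
    count_table: pd.DataFrame, pseudocount: float = 0.5
) -> dict[str, pd.DataFrame]:
    """CLR + pooled OLS per enzyme from a (enzyme, replicate, time) count table."""
    clr = clr_table(count_table, pseudocount)
    enzymes = sorted({c[0] for c in count_table.columns}, key=str)
    out = {}
    for enz in enzymes:
        cols = [c for c in count_table.columns if c[0] == enz]
        out[enz] = depletion_rates(clr[cols], sample_times(cols), enzyme=enz)
    return out


# ---------------------------------------------------------------------------
# enzyme comparison and preference

def differential_substrates(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
    n_sd: float = 2.0,
    sd_col: str = "sigma",
) -> pd.DataFrame:
    """Substrates whose (k_A, k_B) point falls outside the identity ellipse.

    For each substrate an axis-aligned ellipse with semi-axes
    ``n_sd * sd_col`` per enzyme is centered on the identity-matched mean
    ((k_A + k_B)/2 on both axes); points outside it are flagged, with side
    ``"A"`` when enzyme A depletes the substrate faster (more negative k)
    and ``"B"`` otherwise.  The flagging rule is recorded in ``attrs``.
    """
    if set(rates_a.index) != set(rates_b.index):
        raise ValueError("rate tables cover different substrate sets")
    b = rates_b.loc[rates_a.index]
    ka = rates_a["k_rel"].to_numpy(dtype=np.float64)
    kb = b["k_rel"].to_numpy(dtype=np.float64)
    sa = n_sd * rates_a[sd_col].to_numpy(dtype=np.float64)
    sb = n_sd * b[sd_col].to_numpy(dtype=np.float64)
    d = ka - kb  # (k - center) = +/- d/2 on the two axes
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(sa > 0, (d / (2 * sa)) ** 2, np.where(d == 0, 0.0, np.inf))
        tb = np.where(sb > 0, (d / (2 * sb)) ** 2, np.where(d == 0, 0.0, np.inf))
    outside = (ta + tb) > 1.0
    flagged = pd.DataFrame(
        {
            "k_a": ka[outside],
            "k_b": kb[outside],
            "delta": d[outside],
            "side": np.where(d[outside] < 0, "A", "B"),
        },
        index=rates_a.index[outside],
    )
    flagged.attrs["rule"] = f"axis-aligned ellipse, semi-axes {n_sd} * {sd_col}"
    return flagged


def preference_summary(
    substrates: Sequence[str], positions: Sequence[str] = ("+2", "+3", "+4", "+5")
) -> pd.DataFrame:
    """Per-position nucleotide frequency matrix over a substrate subset.

    Rows are labeled positions, columns A/C/G/T; each row sums to 1.
    """
    substrates = list(substrates)
    if not substrates:
        raise ValueError("substrate subset is empty")
    k = len(positions)
    if any(len(s) != k for s in substrates):
        raise ValueError(f"substrates must have length {k}")
    mat = np.zeros((k, 4))
    idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    for s in substrates:
        for p, base in enumerate(s.upper()):
            mat[p, idx[base]] += 1
    mat /= len(substrates)
    return pd.DataFrame(mat, index=list(positions), columns=list(NUCLEOTIDES))


def barcode_relative_cleavage(
    timecourses: pd.DataFrame | Mapping[str, tuple[Sequence[float], Sequence[float]]],
    reference: str,
) -> pd.Series:
    """Relative cleavage rates from barcode-assay timecourses.

    ``timecourses`` is long-form (columns ``substrate, time_min,
    cleaved_fraction``) or a mapping substrate -> (times, fractions).  Each
    substrate's cleaved fraction is fit by OLS against time; slopes are
    divided by the reference substrate's slope, which therefore maps to 1.0.
    """
    if isinstance(timecourses, pd.DataFrame):
        grouped = {
            str(s): (g["time_min"].to_numpy(), g["cleaved_fraction"].to_numpy())
            for s, g in timecourses.groupby("substrate")
        }
    else:
        grouped = {str(s): (np.asarray(t), np.asarray(f)) for s, (t, f) in timecourses.items()}
    if reference not in grouped:
        raise KeyError(f"reference substrate {reference!r} missing from timecourses")
    slopes = {}
    for sub, (t, f) in grouped.items():
        t = np.asarray(t, dtype=np.float64)
        f = np.asarray(f, dtype=np.float64)
        if np.unique(t).size < 2:
            raise FitError(f"substrate {sub!r}: need at least 2 distinct timepoints")
        slope, *_ = _ols(f[None, :], t)
        slopes[sub] = float(slope[0])
    ref = slopes[reference]
    if ref == 0.0:
        raise NormalizationError("reference substrate has zero cleavage slope")
    rel = pd.Series({s: v / ref for s, v in slopes.items()}, name="relative_rate")
    rel.index.name = "substrate"
    return rel
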