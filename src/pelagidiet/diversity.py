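"""Prey richness, Shannon-Wiener diversity, Whittaker beta-diversity and
sample-size-based rarefaction/extrapolation.

Richness and diversity are computed on prey counts (microscope source) or
presence/absence incidence (metabarcoding source).  Beta-diversity follows
Whittaker's presence/absence formulation

    beta_w = (a + b + c) / ((2a + b + c) / 2) - 1

with ``a`` the shared taxa and ``b``, ``c`` the taxa exclusive to either
diet; 0 means identical prey lists, 1 disjoint ones.

Rarefaction uses the analytic hypergeometric expectation of richness for
sub-samples and the Chao lower-bound estimate of undetected richness for
extrapolation, with bootstrap confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "BetaDiversityResult",
    "RarefactionCurve",
    "richness",
    "shannon",
    "beta_whittaker",
    "rarefy_extrapolate",
]


@dataclass(frozen=True)
class BetaDiversityResult:
    """Components and value of Whittaker's pairwise beta-diversity."""

    a: int  # taxa shared by both diets
    b: int  # taxa only in diet 1
    c: int  # taxa only in diet 2
    beta_w: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("beta-diversity components must be non-negative")


@dataclass
class RarefactionCurve:
    """Expected richness over sub- and super-sample sizes with 95% CI."""

    n: int
    sizes: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    s_obs: int
    f1: int
    f2: int
    mode: str = "abundance"
    segment: np.ndarray = field(default=None)  # "interp" / "extrap" per size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "segment": self.segment,
            }
        )


def richness(counts) -> int:
    """Number of taxa with at least one occurrence.

    Accepts a vector or a matrix (rows pooled), counts or presence/absence.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim > 1:
        arr = arr.sum(axis=0)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def shannon(counts) -> float:
    """Shannon-Wiener H' = -sum p_i ln p_i over non-zero proportions."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def beta_whittaker(taxa1, taxa2) -> BetaDiversityResult:
    """Whittaker beta-diversity between two presence sets.

    Parameters are iterables of taxon labels (or boolean/count vectors with a
    shared ordering, in which case positive entries denote presence).
    """
    s1, s2 = _as_set(taxa1), _as_set(taxa2)
    if not s1 and not s2:
        raise ValueError("both presence sets are empty")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    beta = (a + b + c) / ((2 * a + b + c) / 2) - 1.0
    return BetaDiversityResult(a=a, b=b, c=c, beta_w=float(beta))


def _as_set(taxa) -> set:
    arr = np.asarray(taxa)
    if arr.dtype.kind in "bifu":  # vector of counts/presence over indices
        return {i for i, v in enumerate(arr) if v > 0}
    return set(arr.tolist())


# ---------------------------------------------------------------------------
# rarefaction / extrapolation


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _interp_abundance(x: np.ndarray, n: int, m: int) -> float:
    # E[S(m)] = sum over detected taxa of 1 - C(n - x_i, m) / C(n, m)
    x = x[x > 0]
    keep = (n - x) >= m
    if not keep.any():
        return float(len(x))
    xa = x[keep]
    term = np.exp(_log_comb(n - xa, m) - _log_comb(n, m))
    return float(len(x) - term.sum())


def _chao_f0(f1: int, f2: int, n: int) -> float:
    # Chao1-type lower bound on undetected richness; bias-corrected when f2=0
    if f1 == 0:
        return 0.0
    k = (n - 1) / n
    if f2 > 0:
        return k * f1 * f1 / (2 * f2)
    return k * f1 * (f1 - 1) / 2.0


def _extrap_abundance(s_obs: int, f1: int, f2: int, n: int, m_star: int) -> float:
    f0 = _chao_f0(f1, f2, n)
    if f0 == 0.0 or f1 == 0:
        return float(s_obs)
    return s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star)


def _curve_abundance(x: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    n = int(x.sum())
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    out = np.empty(len(sizes))
    for i, m in enumerate(sizes):
        m = int(m)
        if m <= n:
            out[i] = _interp_abundance(x, n, m)
        else:
            out[i] = _extrap_abundance(s_obs, f1, f2, n, m - n)
    return out


def _curve_incidence(inc: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    # inc: units x taxa boolean/0-1 matrix; incidence frequencies Y_i out of T
    T = inc.shape[0]
    y = inc.sum(axis=0)
    s_obs = int((y > 0).sum())
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    out = np.empty(len(sizes))
    for i, t in enumerate(sizes):
        t = int(t)
        if t <= T:
            ya = y[y > 0]
            keep = (T - ya) >= t
            term = (np.exp(_log_comb(T - ya[keep], t) - _log_comb(T, t))
                    if keep.any() else np.array([]))
            out[i] = s_obs - term.sum()
        else:
            q0 = _chao_f0(q1, q2, T)
            if q0 == 0.0 or q1 == 0:
                out[i] = s_obs
            else:
                out[i] = s_obs + q0 * (1.0 - (1.0 - q1 / (T * q0 + q1)) ** (t - T))
    return out


def rarefy_extrapolate(
    data,
    mode: str = "abundance",
    grid=None,
    extrap_factor: float = 2.0,
    n_boot: int = 200,
    seed: int | None = None,
) -> RarefactionCurve:
    """Sample-size-based rarefaction and extrapolation of species richness.

    Parameters
    ----------
    data
        Abundance mode: a vector of per-taxon counts.  Incidence mode: a
        sampling-unit x taxon matrix whose positive entries denote detection.
    mode
        ``"abundance"`` (individual-based) or ``"incidence"`` (unit-based).
    grid
        Sample sizes at which to evaluate the curve; defaults to ~40 sizes
        from 1 to ``extrap_factor * n`` (extrapolation capped at 2n by
        default).
    n_boot, seed
        Bootstrap replicates for the 95% confidence band.

    Interpolation is the exact hypergeometric expectation of richness in a
    random sub-sample; extrapolation adds the Chao lower-bound estimate of
    undetected richness, approached geometrically.
    """
    rng = np.random.default_rng(seed)
    if mode == "abundance":
        x = np.asarray(data, dtype=int).ravel()
        if (x < 0).any():
            raise ValueError("negative counts")
        n = int(x.sum())
        if n < 1:
            raise ValueError("total count must be >= 1")
        s_obs = int((x > 0).sum())
        f1, f2 = int((x == 1).sum()), int((x == 2).sum())
        curve_fn = _curve_abundance
    elif mode == "incidence":
        inc = (np.asarray(data) > 0).astype(int)
        if inc.ndim != 2:
            raise ValueError("incidence mode expects a units x taxa matrix")
        n = inc.shape[0]
        if n < 1:
            raise ValueError("at least one sampling unit required")
        y = inc.sum(axis=0)
        s_obs = int((y > 0).sum())
        f1, f2 = int((y == 1).sum()), int((y == 2).sum())
        curve_fn = _curve_incidence
        x = inc
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cap = max(int(np.ceil(extrap_factor * n)), n)
    if grid is None:
        sizes = np.unique(np.concatenate([
            np.linspace(1, n, 20).astype(int),
            np.linspace(n, cap, 20).astype(int),
        ]))
    else:
        sizes = np.unique(np.asarray(grid, dtype=int))
        if sizes.min() < 1:
            raise ValueError("grid sizes must be >= 1")

    est = curve_fn(x, sizes)

    # bootstrap band: resample the reference sample, recompute the curve
    boot = np.empty((n_boot, len(sizes)))
    if mode == "abundance":
        p = x / n
        for b in range(n_boot):
            xb = rng.multinomial(n, p)
            boot[b] = _curve_abundance(xb, sizes)
    else:
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot[b] = _curve_incidence(x[idx], sizes)
    sd = boot.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(len(sizes))
    lower, upper = est - 1.96 * sd, est + 1.96 * sd

    return RarefactionCurve(
        n=n,
        sizes=sizes,
        estimate=est,
        lower=lower,
        upper=upper,
        s_obs=s_obs,
        f1=f1,
        f2=f2,
        mode=mode,
        segment=np.where(sizes <= n, "interp", "extrap"),
    )


def chao_asymptote(curve: RarefactionCurve) -> float:
    """Asymptotic richness S_obs + Chao-estimated undetected richness."""
    return curve.s_obs + _chao_f0(curve.f1, curve.f2, curve.n)
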