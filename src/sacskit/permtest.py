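"""Permutation significance tests for ΔFR and Δ√|PPC|, and Grubbs outlier
pruning of per-group effect sizes.

Both tests build an exchangeable null by pooling the pre-stimulus and
stimulation observations (100-ms rate bins, or spike phases), permuting the
pool without replacement, and resplitting into surrogate groups of the
original sizes.  Two-sided significance uses the absolute observed difference
against the null distribution of absolute surrogate differences, with the
add-one correction ``p = (1 + #{|Δ*| ≥ |Δ|}) / (1 + iters)`` so a finite
permutation count never reports p = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpikeTrain
from .spikemetrics import PhaseSet, sqrt_abs_ppc

__all__ = ["RateResult", "EntrainmentResult", "perm_test_fr", "perm_test_ppc", "grubbs"]

_CHUNK = 1000  # permutations per vectorized block (bounds peak memory)


@dataclass(frozen=True)
class RateResult:
    fr_pre: float
    fr_stim: float
    delta_fr: float
    p_value: float
    significant: bool
    direction: str  # {"increase", "decrease", "none"}


@dataclass(frozen=True)
class EntrainmentResult:
    sqrtabsppc_pre: float
    sqrtabsppc_stim: float
    delta: float
    p_value: float
    significant: bool
    direction: str
    testable: bool = True


def _direction(delta: float, significant: bool) -> str:
    if not significant or delta == 0:
        return "none"
    return "increase" if delta > 0 else "decrease"


def _perm_p(observed: float, null_abs: np.ndarray, iters: int) -> float:
    return float((1 + np.sum(null_abs >= abs(observed))) / (1 + iters))


def _permuted_group_means(
    pool: np.ndarray, n1: int, iters: int, rng: np.random.Generator,
    replace: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Means of surrogate group 1 (size n1) and group 2 for each permutation."""
    n = pool.size
    total = pool.sum()
    m1 = np.empty(iters)
    m2 = np.empty(iters)
    for lo in range(0, iters, _CHUNK):
        hi = min(lo + _CHUNK, iters)
        block = hi - lo
        if replace:
            draws1 = pool[rng.integers(0, n, size=(block, n1))]
            draws2 = pool[rng.integers(0, n, size=(block, n - n1))]
            m1[lo:hi] = draws1.mean(axis=1)
            m2[lo:hi] = draws2.mean(axis=1)
        else:
            perms = rng.permuted(np.broadcast_to(pool, (block, n)).copy(), axis=1)
            s1 = perms[:, :n1].sum(axis=1)
            m1[lo:hi] = s1 / n1
            m2[lo:hi] = (total - s1) / (n - n1)
    return m1, m2


def perm_test_fr(
    train: SpikeTrain,
    pre_interval: tuple[float, float],
    stim_interval: tuple[float, float],
    bin: float = 0.1,
    iters: int = 10000,
    alpha: float = 0.05,
    seed=None,
    replace: bool = False,
) -> RateResult:
    """Permutation test for a firing-rate change between two intervals.

    Rates are computed over ``bin``-second bins (default 100 ms) in each
    interval; the bins are pooled, shuffled, and resplit into surrogate
    groups of the original sizes to form the null ΔFR distribution
    (``iters`` times).  ``replace=True`` switches the resampling to a
    bootstrap with replacement.
    """
    rng = np.random.default_rng(seed)
    counts = []
    for (start, stop) in (pre_interval, stim_interval):
        if stop <= start or (stop - start) < bin:
            raise ValueError("interval must contain at least one whole bin")
        n_bins = int(np.floor((stop - start) / bin + 1e-9))
        edges = start + bin * np.arange(n_bins + 1)
        c, _ = np.histogram(train.times, bins=edges)
        counts.append(c / bin)  # Hz per bin
    pre_rates, stim_rates = counts
    fr_pre = float(pre_rates.mean())
    fr_stim = float(stim_rates.mean())
    delta = fr_stim - fr_pre

    pool = np.concatenate([pre_rates, stim_rates])
    m_pre, m_stim = _permuted_group_means(pool, pre_rates.size, iters, rng, replace)
    null_abs = np.abs(m_stim - m_pre)
    p = _perm_p(delta, null_abs, iters)
    sig = p <= alpha
    return RateResult(fr_pre, fr_stim, delta, p, sig, _direction(delta, sig))


def _ppc_from_resultant(resultant: np.ndarray, n: int) -> np.ndarray:
    return (np.abs(resultant) ** 2 - n) / (n * (n - 1))


def perm_test_ppc(
    phases_pre: PhaseSet,
    phases_stim: PhaseSet,
    iters: int = 10000,
    alpha: float = 0.05,
    seed=None,
) -> EntrainmentResult:
    """Permutation test for a change in √|PPC| between two phase sets.

    Pools and shuffles the spike phases of the two periods, resplits into
    surrogate groups of the original sizes, and compares the observed
    Δ√|PPC| against the null distribution of absolute surrogate differences.
    Either set having fewer than two phases marks the result untestable.
    """
    n1, n2 = phases_pre.n, phases_stim.n
    if n1 < 2 or n2 < 2:
        return EntrainmentResult(
            np.nan, np.nan, np.nan, np.nan, False, "none", testable=False
        )
    rng = np.random.default_rng(seed)
    s_pre = sqrt_abs_ppc(phases_pre)
    s_stim = sqrt_abs_ppc(phases_stim)
    delta = s_stim - s_pre

    pool = np.exp(1j * np.concatenate([phases_pre.phases, phases_stim.phases]))
    n = pool.size
    null_abs = np.empty(iters)
    for lo in range(0, iters, _CHUNK):
        hi = min(lo + _CHUNK, iters)
        block = hi - lo
        perms = rng.permuted(np.broadcast_to(pool, (block, n)).copy(), axis=1)
        r1 = perms[:, :n1].sum(axis=1)
        r2 = perms.sum(axis=1) - r1
        sp1 = np.sqrt(np.abs(_ppc_from_resultant(r1, n1)))
        sp2 = np.sqrt(np.abs(_ppc_from_resultant(r2, n2)))
        null_abs[lo:hi] = np.abs(sp2 - sp1)
    p = _perm_p(delta, null_abs, iters)
    sig = p <= alpha
    return EntrainmentResult(s_pre, s_stim, delta, p, sig, _direction(delta, sig))


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit at significance ``alpha``."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs(
    values: np.ndarray, alpha: float = 0.05, iterative: bool = True
) -> tuple[np.ndarray, list[int]]:
    """Grubbs outlier removal on a univariate sample.

    Repeatedly tests the most extreme deviation ``G = max|x − mean| / sd``
    against the two-sided t-based critical value at ``alpha``, removing the
    offending point until no rejection (``iterative=False`` stops after one
    pass).  Samples of fewer than three points pass through with a warning;
    a zero-variance sample is treated as outlier-free.

    Returns (retained values, indices removed — positions in the input).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("Grubbs test requires n >= 3; sample passed through")
        return x.copy(), []
    idx = np.arange(x.size)
    removed: list[int] = []
    while idx.size >= 3:
        sub = x[idx]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g > grubbs_critical(idx.size, alpha):
            removed.append(int(idx[j]))
            idx = np.delete(idx, j)
            if not iterative:
                break
        else:
            break
    return x[idx], removed
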