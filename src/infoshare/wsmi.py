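"""Ordinal-pattern symbolization and (weighted) Symbolic Mutual Information.

The connectivity measure implemented here summarizes how much information two
EEG channels share, after reducing each signal to a stream of ordinal
patterns ("symbols").  A symbol at time *t* is the permutation that sorts the
``k`` samples ``x[t], x[t+tau], ..., x[t+(k-1)tau]``; with the default
``k = 3`` there are ``3! = 6`` possible symbols.  The spacing ``tau`` sets
the frequency band the measure is sensitive to — at 256 Hz the default of
16 ms (4 samples) targets roughly the alpha/beta range (8–20 Hz).

Symbolic mutual information (SMI) is the mutual information of the joint
symbol distribution of a channel pair, in bits, normalized by ``log2(k!)`` so
that it lies in [0, 1].  The *weighted* variant (wSMI) zeroes the
contribution of identical and sign-mirrored symbol pairs, which are the
patterns a single common source seen through volume conduction would
produce; wSMI can therefore be slightly negative and is always <= SMI.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymbolParams",
    "JointSymbolDistribution",
    "symbolize",
    "permutation_of_code",
    "code_of_permutation",
    "mirror_symbol",
    "mirror_table",
    "joint_symbol_counts",
    "smi",
    "wsmi",
    "connectivity_matrix",
]


@dataclass(frozen=True)
class SymbolParams:
    """Parameters of the ordinal-pattern transform.

    Parameters
    ----------
    k
        Samples per symbol (pattern order); ``k!`` distinct symbols.
    tau_ms
        Spacing between the samples of one pattern, in milliseconds.
    fs
        Sampling rate in Hz, used to convert ``tau_ms`` to samples.
    """

    k: int = 3
    tau_ms: float = 16.0
    fs: float = 256.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.tau_samples < 1:
            raise ValueError("tau must round to at least one sample")

    @property
    def tau_samples(self) -> int:
        return int(round(self.tau_ms * self.fs / 1000.0))

    @property
    def n_symbols(self) -> int:
        return math.factorial(self.k)

    def n_patterns(self, n_samples: int) -> int:
        return n_samples - (self.k - 1) * self.tau_samples


@dataclass(frozen=True)
class JointSymbolDistribution:
    """Joint symbol counts of one channel pair, pooled over epochs."""

    counts: np.ndarray  # (k!, k!) nonnegative ints
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "n_total", int(c.sum()))

    def transpose(self) -> "JointSymbolDistribution":
        return JointSymbolDistribution(self.counts.T)


def _lehmer_rank(perm: np.ndarray) -> np.ndarray:
    """Lexicographic rank of permutations along the last axis."""
    k = perm.shape[-1]
    rank = np.zeros(perm.shape[:-1], dtype=np.int64)
    for i in range(k - 1):
        smaller_later = np.zeros(perm.shape[:-1], dtype=np.int64)
        for j in range(i + 1, k):
            smaller_later += perm[..., j] < perm[..., i]
        rank += smaller_later * math.factorial(k - 1 - i)
    return rank


def permutation_of_code(code: int, k: int) -> tuple[int, ...]:
    """Inverse of the lexicographic ranking (small ``k`` only)."""
    if not 0 <= code < math.factorial(k):
        raise ValueError(f"code {code} out of range for k={k}")
    items = list(range(k))
    perm = []
    for i in range(k, 0, -1):
        f = math.factorial(i - 1)
        idx, code = divmod(code, f)
        perm.append(items.pop(idx))
    return tuple(perm)


def code_of_permutation(perm: tuple[int, ...]) -> int:
    return int(_lehmer_rank(np.asarray(perm)))


def mirror_symbol(code: int, k: int) -> int:
    """Symbol of the negated sample tuple: the reversed permutation.

    An involution: ``mirror(mirror(s)) == s``.
    """
    perm = permutation_of_code(code, k)
    return code_of_permutation(perm[::-1])


def mirror_table(k: int) -> np.ndarray:
    """``mirror_table(k)[s] == mirror_symbol(s, k)`` for all symbols."""
    return np.array([mirror_symbol(s, k) for s in range(math.factorial(k))])


def symbolize(signal: np.ndarray, params: SymbolParams) -> np.ndarray:
    """Ordinal-pattern codes of a signal.

    ``signal`` may be a single trace ``(n_samples,)`` or any stack of traces
    ``(..., n_samples)``; codes are returned with the trailing axis shortened
    to ``n_samples - (k-1)*tau_samples``.  Ties rank the earlier sample lower
    (stable argsort), so a constant signal maps to the identity pattern.
    """
    x = np.asarray(signal, dtype=float)
    k, tau = params.k, params.tau_samples
    n = x.shape[-1]
    n_pat = params.n_patterns(n)
    if n_pat < 1:
        raise ValueError(
            f"signal of {n} samples too short for k={k}, tau={tau} samples"
        )
    windows = np.stack(
        [x[..., i * tau: i * tau + n_pat] for i in range(k)], axis=-1
    )
    perm = np.argsort(windows, axis=-1, kind="stable")
    return _lehmer_rank(perm)


def joint_symbol_counts(
    sa: np.ndarray, sb: np.ndarray, k: int = 3
) -> JointSymbolDistribution:
    """Tally joint symbol occurrences over all time points and epochs."""
    sa = np.asarray(sa)
    sb = np.asarray(sb)
    if sa.shape != sb.shape:
        raise ValueError(f"symbol shapes differ: {sa.shape} vs {sb.shape}")
    m = math.factorial(k)
    if sa.size and (sa.max() >= m or sb.max() >= m or sa.min() < 0 or sb.min() < 0):
        raise ValueError(f"symbol codes out of range for k={k}")
    combined = sa.ravel() * m + sb.ravel()
    counts = np.bincount(combined, minlength=m * m).reshape(m, m)
    return JointSymbolDistribution(counts)


def _mi_terms(counts: np.ndarray) -> np.ndarray:
    """Per-cell mutual-information terms in bits (0 for empty cells)."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.where(p > 0, terms, 0.0)


def smi(j: JointSymbolDistribution, k: int = 3) -> float:
    """Normalized symbolic mutual information, in [0, 1]."""
    if j.n_total == 0:
        raise ValueError("empty joint distribution")
    return float(_mi_terms(j.counts).sum() / np.log2(math.factorial(k)))


def _wsmi_weights(k: int) -> np.ndarray:
    """0/1 weight matrix: zero on identical and mirrored symbol pairs."""
    m = math.factorial(k)
    w = np.ones((m, m))
    w[np.arange(m), np.arange(m)] = 0.0
    w[np.arange(m), mirror_table(k)] = 0.0
    return w


def wsmi(j: JointSymbolDistribution, k: int = 3) -> float:
    """Weighted SMI: identical and mirrored symbol pairs contribute zero."""
    if j.n_total == 0:
        raise ValueError("empty joint distribution")
    terms = _mi_terms(j.counts) * _wsmi_weights(k)
    return float(terms.sum() / np.log2(math.factorial(k)))


def _batch_wsmi(counts: np.ndarray, k: int) -> np.ndarray:
    """wSMI for a stack of joint count matrices ``(..., k!, k!)``."""
    terms = _mi_terms(counts.astype(float)) * _wsmi_weights(k)
    return terms.sum(axis=(-2, -1)) / np.log2(math.factorial(k))


def connectivity_matrix(
    data: np.ndarray, params: SymbolParams | None = None
) -> np.ndarray:
    """Per-subject wSMI connectivity over all channel pairs.

    Parameters
    ----------
    data
        ``(n_channels, n_epochs, n_samples)`` (or ``(n_channels, n_samples)``
        for a single epoch) array of one subject's EEG.
    params
        Symbolization parameters; defaults to ``SymbolParams()``.

    Returns
    -------
    ``(n_channels, n_channels)`` symmetric matrix with zero diagonal.  Joint
    symbol counts are pooled across epochs before normalization.
    """
    params = params or SymbolParams()
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3:
        raise ValueError("data must be (channels, epochs, samples)")
    n_ch = x.shape[0]
    k = params.k
    m = params.n_symbols
    codes = symbolize(x, params).reshape(n_ch, -1)
    out = np.zeros((n_ch, n_ch))
    pairs = list(itertools.combinations(range(n_ch), 2))
    joint = np.empty((len(pairs), m, m), dtype=np.int64)
    for idx, (i, jx) in enumerate(pairs):
        combined = codes[i] * m + codes[jx]
        joint[idx] = np.bincount(combined, minlength=m * m).reshape(m, m)
    values = _batch_wsmi(joint, k)
    for idx, (i, jx) in enumerate(pairs):
        out[i, jx] = out[jx, i] = values[idx]
    return out
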