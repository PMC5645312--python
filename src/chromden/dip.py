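"""Hartigan's dip test of unimodality.

The dip statistic is the sup-norm distance from the empirical CDF to the
closest unimodal CDF.  P-values are calibrated by Monte Carlo against the
uniform null (the least favourable unimodal distribution), with a fixed
internal seed so that p-values are reproducible across runs.
"""

from __future__ import annotations

import numpy as np

from ._dipcore import dip_sorted_unique
from .exceptions import InsufficientDataError

#: replicates used for the Monte Carlo null table of each sample size
DEFAULT_NULL_REPLICATES = 10_000

#: fixed seed stem for null tables -- independent of user pipeline seeds
_NULL_TABLE_SEED = 177_013

_null_tables: dict[tuple[int, int], np.ndarray] = {}


def dip_statistic(sample) -> float:
    """Dip statistic of a 1-d sample.

    Parameters
    ----------
    sample : array-like
        Observations; at least 2 values.

    Returns
    -------
    float
        The dip, in [0, 0.25].
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError(f"dip statistic needs >= 2 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    v, counts = np.unique(x, return_counts=True)
    return float(dip_sorted_unique(v, counts.astype(float), float(x.size)))


def null_dip_table(n: int, n_replicates: int = DEFAULT_NULL_REPLICATES) -> np.ndarray:
    """Sorted dip statistics of `n_replicates` uniform samples of size `n`.

    Tables are memoised per (n, n_replicates) and generated from a fixed
    seed, so the calibration is deterministic.
    """
    key = (int(n), int(n_replicates))
    if key not in _null_tables:
        rng = np.random.default_rng(np.random.SeedSequence((_NULL_TABLE_SEED, n)))
        dips = np.empty(n_replicates)
        for i in range(n_replicates):
            u = rng.random(n)
            v, counts = np.unique(u, return_counts=True)
            dips[i] = dip_sorted_unique(v, counts.astype(float), float(n))
        dips.sort()
        _null_tables[key] = dips
    return _null_tables[key]


def dip_test(sample, n_replicates: int = DEFAULT_NULL_REPLICATES) -> tuple[float, float]:
    """Dip statistic and Monte Carlo p-value against the uniform null.

    The p-value is (1 + #{null dip >= observed}) / (n_replicates + 1).
    Samples of fewer than 4 observations are rejected: the dip of any
    3-point sample carries no modality information.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise InsufficientDataError(f"dip test needs >= 4 observations, got {x.size}")
    stat = dip_statistic(x)
    table = null_dip_table(x.size, n_replicates)
    n_ge = table.size - np.searchsorted(table, stat - 1e-12, side="left")
    p = (1.0 + n_ge) / (table.size + 1.0)
    return stat, float(p)
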