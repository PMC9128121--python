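"""Posterior sample containers and basic convergence diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PosteriorSamples:
    """Named arrays of MCMC draws with per-draw dataset provenance.

    Each value in ``params`` has shape (n_draws, ...); ``dataset_index``
    records which imputed dataset each draw came from (1-based).
    """

    params: dict[str, np.ndarray]
    dataset_index: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dataset_index = np.asarray(self.dataset_index, dtype=int)
        n = self.n_draws
        for name, a in self.params.items():
            if a.shape[0] != n:
                raise ValueError(f"parameter {name!r} has inconsistent draw count")

    @property
    def n_draws(self) -> int:
        return int(self.dataset_index.size)

    @staticmethod
    def concat(samples: list["PosteriorSamples"]) -> "PosteriorSamples":
        keys = samples[0].params.keys()
        params = {k: np.concatenate([s.params[k] for s in samples]) for k in keys}
        didx = np.concatenate([s.dataset_index for s in samples])
        meta = {"pooled_from": [s.meta for s in samples]}
        return PosteriorSamples(params=params, dataset_index=didx, meta=meta)


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a single chain: compare its two halves.

    Values near 1 indicate the two halves explore the same distribution.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], [*x[n : 2 * n]]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return np.nan
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(x: np.ndarray, max_lag: int | None = None) -> float:
    """Initial-positive-sequence estimate of the effective sample size."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        return float(n)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return float(n)
    max_lag = max_lag or min(n - 2, 1000)
    s = 1.0
    for lag in range(1, max_lag):
        rho = float(xc[:-lag] @ xc[lag:]) / denom
        if rho <= 0.0:
            break
        s += 2.0 * rho
    return float(n / s)
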