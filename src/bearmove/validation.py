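"""Case-control cross-validation of the fitted step-selection model.

Per imputed dataset, 20% of clusters are withheld; the model is refit on the
remaining 80%; each held-out cluster's 26 rows are ranked by their predicted
choice probability and the rank of the used row recorded.  Well-fitting
models place used rows in high bins, so the Spearman rank correlation of the
bin counts against bin index (1..26) is near 1; a model with no information
gives a flat histogram and a correlation near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .movement import MCMCConfig
from .samples import PosteriorSamples
from .ssf import (
    Cluster,
    SSFPriors,
    apply_scaling,
    run_ssf_mcmc_single,
    scale_design,
)


@dataclass
class CVResult:
    dataset_index: int
    bin_counts: np.ndarray  # (n_rows,) non-negative integers
    rho: float
    n_test_clusters: int


@dataclass(frozen=True)
class CVConfig:
    test_frac: float = 0.2
    mcmc: MCMCConfig = MCMCConfig.desk_movement()
    priors: SSFPriors = SSFPriors()
    use_individual: bool = False  # score with alpha_i when available
    n_rows: int = 26


def split_clusters(
    clusters: list[Cluster], test_frac: float = 0.2, rng: np.random.Generator | None = None
) -> tuple[list[Cluster], list[Cluster]]:
    """Random split at cluster granularity; test size rounds half away from zero."""
    rng = np.random.default_rng() if rng is None else rng
    n = len(clusters)
    n_test = int(np.floor(n * test_frac + 0.5))
    n_test = min(max(n_test, 0), n)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [c for i, c in enumerate(clusters) if i not in test_idx]
    test = [c for i, c in enumerate(clusters) if i in test_idx]
    return train, test


def cv_bin_counts(
    test_clusters: list[Cluster],
    coefs: dict[str, np.ndarray] | np.ndarray,
    rng: np.random.Generator | None = None,
    n_rows: int = 26,
) -> np.ndarray:
    """Histogram of used-row ranks (1..n_rows) over the held-out clusters.

    ``coefs`` is either a single coefficient vector or a mapping from
    animal_id to one.  Within each cluster, rows are ranked by linear
    predictor ascending (a strictly monotone transform of the choice
    probability, so the ranks coincide); ties are broken by a seeded random
    permutation.
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = np.zeros(n_rows, dtype=int)
    for c in test_clusters:
        if c.n_rows != n_rows:
            raise ValueError(
                f"cluster for {c.animal_id} has {c.n_rows} rows, expected {n_rows}"
            )
        a = coefs[c.animal_id] if isinstance(coefs, dict) else coefs
        lp = c.design() @ np.asarray(a, float)
        tiebreak = rng.permutation(n_rows)
        order = np.lexsort((tiebreak, lp))  # ascending lp, random ties
        rank_of_used = int(np.where(order == 0)[0][0]) + 1
        counts[rank_of_used - 1] += 1
    return counts


def spearman_bin_correlation(bin_counts: np.ndarray) -> float:
    """Spearman correlation between bin index (1..n) and bin counts.

    Uses average ranks for ties.  Raises ``ValueError`` when the counts have
    zero variance (the correlation is undefined, not zero).
    """
    counts = np.asarray(bin_counts, dtype=float)
    if np.all(counts == counts[0]):
        raise ValueError("bin counts are constant; Spearman correlation is undefined")
    res = spearmanr(np.arange(1, counts.size + 1), counts)
    return float(res.statistic)


def run_cv(
    cluster_datasets: list[list[Cluster]],
    config: CVConfig,
    rng: np.random.Generator,
    posteriors: PosteriorSamples | None = None,
    class_names=None,
) -> dict:
    """Cross-validate each imputed dataset and pool the correlations.

    By default the model is refit on each training split (scaling fit on the
    training clusters only) and held-out clusters are scored with the
    class-level coefficient medians; passing ``posteriors`` skips the refit
    and scores every dataset with that fit's class medians.
    """
    results: list[CVResult] = []
    for d, clusters in enumerate(cluster_datasets, start=1):
        train, test = split_clusters(clusters, config.test_frac, rng)
        if not test or not train:
            raise ValueError(f"dataset {d}: empty train or test split")
        raw = np.vstack([c.x_raw for c in train])
        _, info = scale_design(raw)
        test_s = apply_scaling(test, info)

        if posteriors is None:
            train_s = apply_scaling(train, info)
            fit = run_ssf_mcmc_single(
                train_s,
                config.mcmc,
                rng,
                class_names=class_names,
                priors=config.priors,
                dataset_index=d,
            )
        else:
            fit = posteriors

        cn = fit.meta["class_names"]
        beta_med = np.median(fit.params["beta"], axis=0)  # (C, 8)
        coefs: dict[str, np.ndarray] = {}
        if config.use_individual and posteriors is None:
            alpha_med = np.median(fit.params["alpha"], axis=0)
            for i, a in enumerate(fit.meta["animal_ids"]):
                coefs[a] = alpha_med[i]
        for c in test_s:
            if c.animal_id not in coefs:
                coefs[c.animal_id] = beta_med[cn.index(c.class_label)]

        counts = cv_bin_counts(test_s, coefs, rng, n_rows=config.n_rows)
        rho = spearman_bin_correlation(counts)
        results.append(
            CVResult(
                dataset_index=d,
                bin_counts=counts,
                rho=rho,
                n_test_clusters=len(test),
            )
        )

    rhos = np.array([r.rho for r in results])
    return {
        "per_dataset": results,
        "rho_median": float(np.median(rhos)),
        "rho_lo": float(np.quantile(rhos, 0.025)),
        "rho_hi": float(np.quantile(rhos, 0.975)),
        "n_datasets": len(results),
    }
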