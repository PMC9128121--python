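"""Hierarchical conditional-logistic step-selection model.

Each used location is paired with A available locations generated from the
animal's own movement kernel: a (k, g, r) triple is drawn from the
individual's movement posterior, then A step lengths ~ Weibull(k, g) and A
bearings ~ wrapped Cauchy centred on the previous bearing displace the
previous used location.  The used+available set is a *cluster*; the choice
probability of the used row is a softmax of linear covariate scores, and
individual coefficient vectors alpha_i are shrunk toward class-level beta_c:

    P(used) = exp(alpha_i . x_used) / sum_rows exp(alpha_i . x_row)
    alpha_ij ~ Normal(beta_cj, sigma_j),   beta_cj ~ Normal(0, 100),
    sigma_j ~ Gamma(0.01, 0.01)  (shape-rate on the SD, shared across classes)

Covariates are centred and scaled by their pooled means/SDs per imputed
dataset; quadratic terms are built on the raw scale and scaled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .covariates import (
    COVARIATE_NAMES,
    CovariateStack,
    DesignInfo,
    N_COVARIATES,
    extract_covariates_batch,
)
from .distributions import gamma_logpdf, sample_wrapped_cauchy
from .movement import MCMCConfig, _Adaptive, compare_classes  # noqa: F401
from .preprocess import PathRealization
from .samples import PosteriorSamples, split_rhat
from .synthetic import TruePath

DEFAULT_A = 25  # > 20 available locations per used location is sufficient


@dataclass(frozen=True)
class SSFPriors:
    """Prior settings; the readings of the two vague priors are switchable."""

    beta_scale: float = 100.0
    beta_scale_is_sd: bool = True  # False: read Normal(0, 100) as precision
    sigma_shape: float = 0.01
    sigma_rate: float = 0.01
    sigma_prior_on_sd: bool = True  # False: Gamma prior on the precision

    @property
    def beta_var(self) -> float:
        return self.beta_scale**2 if self.beta_scale_is_sd else 1.0 / self.beta_scale


@dataclass
class Cluster:
    """One used location with its available sample and covariate matrix.

    ``x_raw`` has 1 + A rows (row 0 = used) and 8 covariate columns in the
    fixed order of :data:`bearmove.covariates.COVARIATE_NAMES`.
    """

    animal_id: str
    class_label: str
    time: np.datetime64
    used_xy: np.ndarray
    prev_xy: np.ndarray
    theta_prev: float
    avail_xy: np.ndarray  # (A, 2)
    x_raw: np.ndarray  # (1 + A, 8)
    x_scaled: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.x_raw.shape[0]

    def design(self) -> np.ndarray:
        return self.x_scaled if self.x_scaled is not None else self.x_raw


def generate_available(
    ind_posterior: dict[str, np.ndarray],
    s_prev,
    theta_prev: float,
    A: int = DEFAULT_A,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """A available endpoints from one posterior draw of the movement kernel.

    Draws one (k, g, r) triple from the individual's posterior arrays, then A
    lengths ~ Weibull(k, g) and A bearings ~ wrapped Cauchy(theta_prev, r),
    and displaces ``s_prev``.  Returns the points and the sampled triple.
    """
    rng = np.random.default_rng() if rng is None else rng
    for key in ("k", "g", "r"):
        if key not in ind_posterior or len(np.atleast_1d(ind_posterior[key])) == 0:
            raise ValueError(f"missing posterior draws for {key!r}")
    ks = np.atleast_1d(np.asarray(ind_posterior["k"], float))
    gs = np.atleast_1d(np.asarray(ind_posterior["g"], float))
    rs = np.atleast_1d(np.asarray(ind_posterior["r"], float))
    j = int(rng.integers(ks.size))
    k, g, r = float(ks[j]), float(gs[j]), float(rs[j])
    lengths = g * rng.weibull(k, size=A)
    angles = sample_wrapped_cauchy(theta_prev, r, A, rng)
    pts = np.asarray(s_prev, float) + lengths[:, None] * np.column_stack(
        [np.cos(angles), np.sin(angles)]
    )
    return pts, (k, g, r)


def build_clusters(
    path: PathRealization | TruePath,
    ind_posterior: dict[str, np.ndarray],
    stack: CovariateStack,
    A: int = DEFAULT_A,
    rng: np.random.Generator | None = None,
) -> list[Cluster]:
    """Clusters for every used location of a regular path (index >= 2).

    The previous bearing needed to orient the availability kernel requires
    two preceding locations, so the first two path locations seed the first
    cluster.  Available points that would fall off the grid are clamped to
    the grid edge; points on land are kept and receive covariates.
    """
    rng = np.random.default_rng() if rng is None else rng
    xy = np.asarray(path.xy, float)
    times = np.asarray(path.times, dtype="datetime64[ns]")
    clusters = []
    lo = np.array([stack.grid.x0, stack.grid.y0]) + 1e-6
    hi = lo + np.array([stack.grid.width, stack.grid.height]) - 2e-6
    for t in range(2, xy.shape[0]):
        s_prev = xy[t - 1]
        d = xy[t - 1] - xy[t - 2]
        theta_prev = float(np.arctan2(d[1], d[0]))
        avail, _ = generate_available(ind_posterior, s_prev, theta_prev, A=A, rng=rng)
        avail = np.clip(avail, lo, hi)
        pts = np.vstack([np.clip(xy[t], lo, hi), avail])
        x_raw = extract_covariates_batch(pts, times[t].astype("datetime64[D]"), stack)
        clusters.append(
            Cluster(
                animal_id=path.animal_id,
                class_label=path.class_label,
                time=times[t],
                used_xy=xy[t].copy(),
                prev_xy=s_prev.copy(),
                theta_prev=theta_prev,
                avail_xy=avail,
                x_raw=x_raw,
            )
        )
    return clusters


def scale_design(raw: np.ndarray) -> tuple[np.ndarray, DesignInfo]:
    """Centre and scale each covariate column over the full used+available pool."""
    raw = np.asarray(raw, dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    if np.any(sds <= 0):
        bad = [COVARIATE_NAMES[j] for j in np.where(sds <= 0)[0]]
        raise ValueError(f"constant covariate column(s): {bad}; cannot scale")
    info = DesignInfo(means=means, sds=sds)
    return info.apply(raw), info


def apply_scaling(clusters: list[Cluster], info: DesignInfo) -> list[Cluster]:
    return [replace(c, x_scaled=info.apply(c.x_raw)) for c in clusters]


def scale_clusters(clusters: list[Cluster]) -> tuple[list[Cluster], DesignInfo]:
    """Fit the scaling on all rows of all clusters and apply it."""
    raw = np.vstack([c.x_raw for c in clusters])
    _, info = scale_design(raw)
    return apply_scaling(clusters, info), info


def permute_cluster_covariates(
    clusters: list[Cluster], rng: np.random.Generator
) -> list[Cluster]:
    """Null model: permute covariate rows within each cluster.

    Breaks the used/available association while preserving each cluster's
    covariate pool; fitted coefficients should then be indistinguishable
    from zero.
    """
    out = []
    for c in clusters:
        perm = rng.permutation(c.n_rows)
        out.append(
            replace(
                c,
                x_raw=c.x_raw[perm],
                x_scaled=None if c.x_scaled is None else c.x_scaled[perm],
            )
        )
    return out


def choice_loglik(alpha: np.ndarray, cluster: Cluster) -> float:
    """Log choice probability of the used row: alpha.x_used - logsumexp(all)."""
    lp = cluster.design() @ np.asarray(alpha, float)
    return float(lp[0] - logsumexp(lp))


@dataclass
class SSFState:
    """One point of the step-selection parameter space."""

    beta: np.ndarray  # (C, 8)
    sigma: np.ndarray  # (8,)
    alpha: np.ndarray  # (n_animals, 8)


def ssf_log_posterior(
    state: SSFState,
    clusters: list[Cluster],
    animal_ids: list[str],
    class_names: list[str],
    priors: SSFPriors = SSFPriors(),
) -> float:
    """Reference log posterior for the hierarchical conditional logit."""
    if np.any(state.sigma <= 0):
        return -np.inf
    aidx = {a: i for i, a in enumerate(animal_ids)}
    out = 0.0
    for c in clusters:
        out += choice_loglik(state.alpha[aidx[c.animal_id]], c)
    cls_of = {}
    for c in clusters:
        cls_of[c.animal_id] = class_names.index(c.class_label)
    for a, i in aidx.items():
        bc = state.beta[cls_of[a]]
        out += float(
            np.sum(
                -0.5 * np.log(2 * np.pi)
                - np.log(state.sigma)
                - 0.5 * ((state.alpha[i] - bc) / state.sigma) ** 2
            )
        )
    bv = priors.beta_var
    out += float(np.sum(-0.5 * np.log(2 * np.pi * bv) - 0.5 * state.beta**2 / bv))
    if priors.sigma_prior_on_sd:
        out += float(np.sum(gamma_logpdf(state.sigma, priors.sigma_shape, priors.sigma_rate)))
    else:
        prec = 1.0 / state.sigma**2
        out += float(
            np.sum(
                gamma_logpdf(prec, priors.sigma_shape, priors.sigma_rate)
                + np.log(2.0 / state.sigma**3)
            )
        )
    return out


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


class _SSFData:
    """Padded per-animal design tensors for vectorized updates."""

    def __init__(self, clusters: list[Cluster], class_names=None):
        if not clusters:
            raise ValueError("no clusters")
        self.animal_ids = sorted({c.animal_id for c in clusters})
        labels = {c.animal_id: c.class_label for c in clusters}
        self.class_names = (
            list(class_names) if class_names else sorted({c.class_label for c in clusters})
        )
        self.cls = np.array(
            [self.class_names.index(labels[a]) for a in self.animal_ids]
        )
        self.n = len(self.animal_ids)
        self.C = len(self.class_names)
        per = {a: [] for a in self.animal_ids}
        rows = {c.n_rows for c in clusters}
        if len(rows) != 1:
            raise ValueError("all clusters must have the same number of rows")
        self.R = rows.pop()
        for c in clusters:
            per[c.animal_id].append(c.design())
        cmax = max(len(v) for v in per.values())
        self.X = np.zeros((self.n, cmax, self.R, N_COVARIATES))
        self.mask = np.zeros((self.n, cmax), dtype=bool)
        for i, a in enumerate(self.animal_ids):
            for c_i, x in enumerate(per[a]):
                self.X[i, c_i] = x
                self.mask[i, c_i] = True
        self.n_by_class = np.bincount(self.cls, minlength=self.C)

    def cll(self, LP: np.ndarray) -> np.ndarray:
        """Masked conditional-logit log likelihood per animal, given scores."""
        u = LP.max(axis=2, keepdims=True)
        lse = u[..., 0] + np.log(np.exp(LP - u).sum(axis=2))
        return np.where(self.mask, LP[..., 0] - lse, 0.0).sum(axis=1)


def run_ssf_mcmc_single(
    clusters: list[Cluster],
    config: MCMCConfig,
    rng: np.random.Generator,
    class_names=None,
    priors: SSFPriors = SSFPriors(),
    dataset_index: int = 1,
) -> PosteriorSamples:
    """One chain of the hierarchical conditional-logit sampler.

    The hierarchy is sampled in its non-centred parameterization
    alpha_ij = beta_cj + sigma_j z_ij with z_ij ~ Normal(0, 1), which avoids
    the funnel the Gamma(0.01, 0.01) SD prior creates at sigma -> 0.  All
    blocks are adaptive random-walk Metropolis, vectorized across animals
    (z), classes (beta), and covariates (sigma).
    """
    sd = _SSFData(clusters, class_names=class_names)
    n, C, J = sd.n, sd.C, N_COVARIATES
    z = np.zeros((n, J))
    beta = np.zeros((C, J))
    sigma = np.full(J, 0.3)
    cls_onehot = np.zeros((C, n), dtype=bool)
    cls_onehot[sd.cls, np.arange(n)] = True

    def alpha_of():
        return beta[sd.cls] + sigma[None, :] * z

    LP = np.einsum("acrj,aj->acr", sd.X, alpha_of())
    cll = sd.cll(LP)

    ad_z = _Adaptive(np.full((n, J), 0.5))
    ad_b = _Adaptive(np.full((C, J), 0.3))
    ad_s = _Adaptive(np.full(J, 0.5))
    bv = priors.beta_var

    total = config.adapt + config.burnin + config.iters
    keep_from = config.adapt + config.burnin
    n_saved = config.n_saved
    draws = {
        "beta": np.empty((n_saved, C, J)),
        "sigma": np.empty((n_saved, J)),
        "alpha": np.empty((n_saved, n, J)),
    }
    saved = 0

    def sigma_prior_ll(s):
        if priors.sigma_prior_on_sd:
            return gamma_logpdf(s, priors.sigma_shape, priors.sigma_rate)
        return gamma_logpdf(1.0 / s**2, priors.sigma_shape, priors.sigma_rate) + np.log(
            2.0 / s**3
        )

    for it in range(total):
        adapting = it < config.adapt
        acc_z = np.zeros((n, J))
        acc_b = np.zeros((C, J))
        acc_s = np.zeros(J)

        for j in range(J):
            # ---- latent individual effects z_.j ---------------------------
            step = np.exp(ad_z.log_scale[:, j]) * rng.standard_normal(n)
            LPp = LP + (sigma[j] * step)[:, None, None] * sd.X[..., j]
            cll_p = sd.cll(LPp)
            z_new = z[:, j] + step
            delta = cll_p - cll - 0.5 * (z_new**2 - z[:, j] ** 2)
            acc = np.log(rng.uniform(size=n)) < delta
            z[acc, j] = z_new[acc]
            LP = np.where(acc[:, None, None], LPp, LP)
            cll = np.where(acc, cll_p, cll)
            acc_z[:, j] = acc

            # ---- class coefficients beta_.j (moves all alpha in class) ----
            bstep = np.exp(ad_b.log_scale[:, j]) * rng.standard_normal(C)
            shift = bstep[sd.cls]
            LPp = LP + shift[:, None, None] * sd.X[..., j]
            cll_p = sd.cll(LPp)
            b_new = beta[:, j] + bstep
            dcll = cls_onehot @ (cll_p - cll)
            dprior = -0.5 * (b_new**2 - beta[:, j] ** 2) / bv
            acc = np.log(rng.uniform(size=C)) < dcll + dprior
            beta[acc, j] = b_new[acc]
            acc_i = acc[sd.cls]
            LP = np.where(acc_i[:, None, None], LPp, LP)
            cll = np.where(acc_i, cll_p, cll)
            acc_b[:, j] = acc

            # ---- inter-individual SD sigma_j (log RW) ---------------------
            sprop = sigma[j] * np.exp(float(np.exp(ad_s.log_scale[j])) * rng.standard_normal())
            LPp = LP + ((sprop - sigma[j]) * z[:, j])[:, None, None] * sd.X[..., j]
            cll_p = sd.cll(LPp)
            delta = (
                (cll_p - cll).sum()
                + float(sigma_prior_ll(np.array(sprop)) - sigma_prior_ll(np.array(sigma[j])))
                + np.log(sprop)
                - np.log(sigma[j])
            )
            if np.log(rng.uniform()) < delta:
                sigma[j] = sprop
                LP, cll = LPp, cll_p
                acc_s[j] = 1.0

        ad_z.record(acc_z, adapting)
        ad_b.record(acc_b, adapting)
        ad_s.record(acc_s, adapting)

        if it >= keep_from and (it - keep_from) % config.thin == 0 and saved < n_saved:
            draws["beta"][saved] = beta
            draws["sigma"][saved] = sigma
            draws["alpha"][saved] = alpha_of()
            saved += 1

    for name in draws:
        draws[name] = draws[name][:saved]

    rhat = {
        f"beta[{cn},{COVARIATE_NAMES[j]}]": split_rhat(draws["beta"][:, c, j])
        for c, cn in enumerate(sd.class_names)
        for j in range(J)
    }
    meta = {
        "config": config,
        "animal_ids": sd.animal_ids,
        "class_names": sd.class_names,
        "class_of_animal": [sd.class_names[c] for c in sd.cls],
        "acceptance": {
            "z": ad_z.acceptance_rate(),
            "beta": ad_b.acceptance_rate(),
            "sigma": ad_s.acceptance_rate(),
        },
        "split_rhat": rhat,
    }
    return PosteriorSamples(
        params=draws, dataset_index=np.full(saved, dataset_index), meta=meta
    )


def run_ssf_mcmc(
    cluster_datasets: list[list[Cluster]],
    config: MCMCConfig,
    rng: np.random.Generator,
    class_names=None,
    priors: SSFPriors = SSFPriors(),
    scale: bool = True,
) -> tuple[PosteriorSamples, pd.DataFrame, list[DesignInfo | None]]:
    """Fit each imputed dataset, pool the draws, and summarize.

    Datasets are scaled independently (each is an independent fit); the
    per-dataset :class:`DesignInfo` is returned for prediction-time reuse.
    Returns (pooled samples, summary table, design infos).
    """
    chains = []
    infos: list[DesignInfo | None] = []
    for d, clusters in enumerate(cluster_datasets, start=1):
        if scale:
            clusters, info = scale_clusters(clusters)
        else:
            info = None
        infos.append(info)
        chains.append(
            run_ssf_mcmc_single(
                clusters,
                config,
                rng,
                class_names=class_names,
                priors=priors,
                dataset_index=d,
            )
        )
    pooled = PosteriorSamples.concat(chains) if len(chains) > 1 else chains[0]
    cn = chains[0].meta["class_names"] if chains else []
    summary = summarize_ssf(pooled, cn)
    return pooled, summary, infos


def summarize_ssf(pooled: PosteriorSamples, class_names: list[str]) -> pd.DataFrame:
    """Median, 95% CI, and CI-excludes-zero flag per covariate and class."""
    beta = pooled.params["beta"]
    rows = []
    for c, cname in enumerate(class_names):
        for j, cov in enumerate(COVARIATE_NAMES):
            lo, med, hi = np.quantile(beta[:, c, j], [0.025, 0.5, 0.975])
            rows.append(
                {
                    "parameter": cov,
                    "class": cname,
                    "median": med,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "excludes_zero": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)
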