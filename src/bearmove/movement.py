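"""Hierarchical Bayesian movement model: Weibull steps, wrapped-Cauchy turns.

Per-individual step lengths follow Weibull(k_i, g_i) and bearings follow a
wrapped Cauchy centred on the previous bearing with concentration r_i (the
directional persistence).  Individual parameters are tied to class-level
parameters through method-of-moments hyper-distributions:

    g_i | c ~ Gamma(gamma_c^2/sigma_gamma^2, gamma_c/sigma_gamma^2)
    k_i | c ~ Gamma(kappa_c^2/sigma_kappa^2, kappa_c/sigma_kappa^2)
    r_i | c ~ Beta(mom(phi_c, sigma_phi))

with uniform priors on the class parameters and inter-individual SDs:
gamma_c ~ U(0, 5e5), kappa_c ~ U(0, 10), phi_c ~ U(0, 1),
sigma_gamma ~ U(0, 5e4), sigma_kappa ~ U(0, 5), sigma_phi ~ U(0, 0.5).
Each animal's first angle theta_{i,1} ~ U(-pi, pi) and initial step
s_{i,1} ~ U(0, 1e5) are free parameters; s_{i,1} carries no likelihood under
the Weibull model as written and is retained for fidelity only.

Sampling is single-block adaptive random-walk Metropolis within Gibbs,
vectorized across individuals (individual parameters are conditionally
independent given the class level, so joint proposals with element-wise
acceptance are valid).  Proposal scales adapt toward ~35% acceptance during
an adaptation phase and are frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .distributions import (
    beta_logpdf,
    gamma_logpdf,
    mean_step_length,
    mom_beta_params,
    wrap_angle,
)
from .preprocess import StepSeries
from .samples import PosteriorSamples, split_rhat

# uniform prior supports for the population level
GAMMA_MAX = 5.0e5
KAPPA_MAX = 10.0
SIGMA_GAMMA_MAX = 5.0e4
SIGMA_KAPPA_MAX = 5.0
SIGMA_PHI_MAX = 0.5
S1_MAX = 1.0e5

TWO_PI = 2.0 * np.pi


@dataclass
class MovementState:
    """One point in the movement-model parameter space."""

    kappa: np.ndarray  # (C,)
    gamma_: np.ndarray  # (C,)
    phi: np.ndarray  # (C,)
    sigma_kappa: float
    sigma_gamma: float
    sigma_phi: float
    k: np.ndarray  # (n,)
    g: np.ndarray  # (n,)
    r: np.ndarray  # (n,)
    theta1: np.ndarray  # (n,)
    s1: np.ndarray  # (n,)


@dataclass(frozen=True)
class MCMCConfig:
    """Schedule of the Metropolis-within-Gibbs sampler."""

    adapt: int = 5_000
    burnin: int = 100_000
    iters: int = 100_000
    thin: int = 100

    @staticmethod
    def desk_movement() -> "MCMCConfig":
        return MCMCConfig(adapt=600, burnin=1_500, iters=2_000, thin=2)

    @property
    def n_saved(self) -> int:
        return self.iters // self.thin


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


class _MovementData:
    """Padded, masked arrays for vectorized likelihood evaluation."""

    def __init__(self, series: list[StepSeries], class_names=None, angle_mode="bearing"):
        if not series:
            raise ValueError("no step series provided")
        if angle_mode not in ("bearing", "turn_autoregressive"):
            raise ValueError(f"unknown angle_mode {angle_mode!r}")
        self.angle_mode = angle_mode
        self.animal_ids = [s.animal_id for s in series]
        labels = [s.class_label for s in series]
        self.class_names = list(class_names) if class_names else sorted(set(labels))
        self.cls = np.array([self.class_names.index(c) for c in labels])
        n = len(series)
        self.n = n
        self.C = len(self.class_names)

        tmax = max(s.lengths.size for s in series)
        self.L = np.full((n, tmax), 1.0)
        self.Lvalid = np.zeros((n, tmax), dtype=bool)
        for i, s in enumerate(series):
            self.L[i, : s.lengths.size] = np.maximum(s.lengths, 1e-8)
            self.Lvalid[i, : s.lengths.size] = s.step_valid
        self.logL = np.log(self.L)

        # angle sequence: bearings (default) or literal turn angles
        firsts, seqs, valids = [], [], []
        for s in series:
            if self.angle_mode == "bearing":
                seq = s.bearings
                sv = s.step_valid[: seq.size]
            else:
                seq, sv = s.deviations()
            if seq.size and sv.size and sv[0]:
                firsts.append((True, float(seq[0])))
            elif seq.size:
                firsts.append((True, float(seq[0])))
            else:
                firsts.append((False, 0.0))
            dev = wrap_angle(np.diff(seq))
            dv = sv[:-1] & sv[1:] if sv.size > 1 else np.zeros(0, bool)
            seqs.append(dev)
            valids.append(dv[: dev.size])
        self.has_first = np.array([f[0] for f in firsts])
        self.first_angle = np.array([f[1] for f in firsts])
        dmax = max((d.size for d in seqs), default=0)
        dmax = max(dmax, 1)
        self.cos_dev = np.zeros((n, dmax))
        self.dev_valid = np.zeros((n, dmax), dtype=bool)
        for i, (d, v) in enumerate(zip(seqs, valids)):
            self.cos_dev[i, : d.size] = np.cos(d)
            self.dev_valid[i, : d.size] = v

    # -- likelihood pieces, all returning per-animal (n,) arrays ------------

    def weibull_ll(self, k: np.ndarray, g: np.ndarray) -> np.ndarray:
        d = self.logL - np.log(g)[:, None]
        term = (
            np.log(k)[:, None]
            - np.log(g)[:, None]
            + (k[:, None] - 1.0) * d
            - np.exp(k[:, None] * d)
        )
        return np.where(self.Lvalid, term, 0.0).sum(axis=1)

    def angle_ll(self, r: np.ndarray, theta1: np.ndarray) -> np.ndarray:
        base = np.log1p(-r * r) - np.log(TWO_PI)
        first = np.where(
            self.has_first,
            base - np.log1p(r * r - 2.0 * r * np.cos(self.first_angle - theta1)),
            0.0,
        )
        dens = base[:, None] - np.log1p(r[:, None] ** 2 - 2.0 * r[:, None] * self.cos_dev)
        return first + np.where(self.dev_valid, dens, 0.0).sum(axis=1)


# ---------------------------------------------------------------------------
# reference log posterior
# ---------------------------------------------------------------------------


def _in_support(state: MovementState) -> bool:
    s = state
    ok = (
        np.all((s.kappa > 0) & (s.kappa < KAPPA_MAX))
        and np.all((s.gamma_ > 0) & (s.gamma_ < GAMMA_MAX))
        and np.all((s.phi > 0) & (s.phi < 1))
        and 0 < s.sigma_kappa < SIGMA_KAPPA_MAX
        and 0 < s.sigma_gamma < SIGMA_GAMMA_MAX
        and 0 < s.sigma_phi < SIGMA_PHI_MAX
        and np.all(s.k > 0)
        and np.all(s.g > 0)
        and np.all((s.r > 0) & (s.r < 1))
        and np.all((s.theta1 > -np.pi) & (s.theta1 <= np.pi))
        and np.all((s.s1 > 0) & (s.s1 < S1_MAX))
    )
    if not ok:
        return False
    return bool(np.all(s.sigma_phi**2 < s.phi * (1.0 - s.phi)))


def _hyper_ll(state: MovementState, cls: np.ndarray) -> float:
    a_g, b_g = mom_gamma_params_vec(state.gamma_, state.sigma_gamma)
    a_k, b_k = mom_gamma_params_vec(state.kappa, state.sigma_kappa)
    out = gamma_logpdf(state.g, a_g[cls], b_g[cls]).sum()
    out += gamma_logpdf(state.k, a_k[cls], b_k[cls]).sum()
    a_r = np.empty(state.phi.size)
    b_r = np.empty(state.phi.size)
    for c in range(state.phi.size):
        a_r[c], b_r[c] = mom_beta_params(state.phi[c], state.sigma_phi)
    out += beta_logpdf(state.r, a_r[cls], b_r[cls]).sum()
    return float(out)


def mom_gamma_params_vec(mean: np.ndarray, sd: float):
    var = sd * sd
    return np.asarray(mean) ** 2 / var, np.asarray(mean) / var


def movement_log_posterior(
    state: MovementState,
    data: list[StepSeries],
    class_names=None,
    angle_mode: str = "bearing",
    include_likelihood: bool = True,
) -> float:
    """Full log posterior density (up to the flat-prior constant).

    Sum of the Weibull step likelihood, the wrapped-Cauchy angle likelihood
    (the first angle conditioned on theta_{i,1}), the Gamma/Gamma/Beta
    hyper-densities, and the flat-prior support indicator; -inf outside the
    support.  Reference implementation used by the tests; the sampler uses
    equivalent incremental updates.
    """
    if not data:
        raise ValueError("empty data")
    if not _in_support(state):
        return -np.inf
    md = _MovementData(data, class_names=class_names, angle_mode=angle_mode)
    out = _hyper_ll(state, md.cls)
    if include_likelihood:
        out += float(md.weibull_ll(state.k, state.g).sum())
        out += float(md.angle_ll(state.r, state.theta1).sum())
    return out


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


class _Adaptive:
    """Batch adaptive scale for one proposal block (scalar or array)."""

    def __init__(self, scale, batch: int = 50):
        self.log_scale = np.log(np.asarray(scale, dtype=float))
        self.batch = batch
        self.acc = np.zeros_like(self.log_scale)
        self.count = 0
        self.batch_no = 0
        self.post_acc = np.zeros_like(self.log_scale)
        self.post_count = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def record(self, accepted, adapting: bool):
        a = np.asarray(accepted, dtype=float)
        if adapting:
            self.acc = self.acc + a
            self.count += 1
            if self.count >= self.batch:
                self.batch_no += 1
                delta = min(0.1, 1.0 / np.sqrt(self.batch_no))
                rate = self.acc / self.count
                self.log_scale = self.log_scale + np.where(rate > 0.35, delta, -delta)
                self.acc = np.zeros_like(self.log_scale)
                self.count = 0
        else:
            self.post_acc = self.post_acc + a
            self.post_count += 1

    def acceptance_rate(self) -> float:
        if self.post_count == 0:
            return np.nan
        return float(np.mean(self.post_acc) / self.post_count)


def _beta_feasible(phi: np.ndarray, sigma_phi: float) -> np.ndarray:
    return sigma_phi**2 < phi * (1.0 - phi)


def run_movement_mcmc(
    data: list[StepSeries],
    config: MCMCConfig,
    rng: np.random.Generator,
    class_names=None,
    prior_only: bool = False,
    angle_mode: str = "bearing",
    dataset_index: int = 1,
    save_individual: bool = True,
) -> PosteriorSamples:
    """Metropolis-within-Gibbs sampling of the movement hierarchy.

    With ``prior_only=True`` the data likelihood is dropped and the sampler
    explores the joint prior (the marginals of the class parameters are then
    the stated uniforms — a sampler self-check).
    """
    md = _MovementData(data, class_names=class_names, angle_mode=angle_mode)
    n, C = md.n, md.C
    like = 0.0 if prior_only else 1.0

    # initial state from the data
    mean_l = np.array(
        [max(np.mean(md.L[i][md.Lvalid[i]]) if md.Lvalid[i].any() else 1e4, 1.0) for i in range(n)]
    )
    k = np.full(n, 1.5)
    g = np.minimum(mean_l, GAMMA_MAX * 0.5)
    r = np.full(n, 0.3)
    theta1 = md.first_angle.copy()
    s1 = np.full(n, S1_MAX / 2.0)
    kappa = np.full(C, 2.0)
    gam = np.array(
        [np.clip(np.mean(g[md.cls == c]) if (md.cls == c).any() else 5e4, 1e3, GAMMA_MAX - 1) for c in range(C)]
    )
    phi = np.full(C, 0.3)
    sk, sg, sp = 0.4, 6000.0, 0.08

    # cached per-animal terms
    wll = md.weibull_ll(k, g)
    all_ = md.angle_ll(r, theta1)

    def hyper_k(kv, kap, s):
        a, b = mom_gamma_params_vec(kap, s)
        return gamma_logpdf(kv, a[md.cls], b[md.cls])

    def hyper_g(gv, ga, s):
        a, b = mom_gamma_params_vec(ga, s)
        return gamma_logpdf(gv, a[md.cls], b[md.cls])

    def hyper_r(rv, ph, s):
        a = (ph**2 - ph**3 - ph * s * s) / (s * s)
        b = (ph - 2 * ph**2 + ph**3 - s * s + ph * s * s) / (s * s)
        return beta_logpdf(rv, a[md.cls], b[md.cls])

    hk = hyper_k(k, kappa, sk)
    hg = hyper_g(g, gam, sg)
    hr = hyper_r(r, phi, sp)

    ad = {
        "k": _Adaptive(np.full(n, 0.3)),
        "g": _Adaptive(np.full(n, 0.3)),
        "r": _Adaptive(np.full(n, 0.6)),
        "theta1": _Adaptive(np.full(n, 0.8)),
        "kappa": _Adaptive(np.full(C, 0.3)),
        "gamma": _Adaptive(np.full(C, 4000.0)),
        "phi": _Adaptive(np.full(C, 0.06)),
        "sigma_kappa": _Adaptive(0.15),
        "sigma_gamma": _Adaptive(2000.0),
        "sigma_phi": _Adaptive(0.03),
    }

    total = config.adapt + config.burnin + config.iters
    keep_from = config.adapt + config.burnin
    n_saved = config.n_saved
    draws = {
        "kappa": np.empty((n_saved, C)),
        "gamma": np.empty((n_saved, C)),
        "phi": np.empty((n_saved, C)),
        "sigma_kappa": np.empty(n_saved),
        "sigma_gamma": np.empty(n_saved),
        "sigma_phi": np.empty(n_saved),
    }
    if save_individual:
        draws["k"] = np.empty((n_saved, n))
        draws["g"] = np.empty((n_saved, n))
        draws["r"] = np.empty((n_saved, n))
    saved = 0

    def metropolis_vec(delta, size):
        return np.log(rng.uniform(size=size)) < delta

    for it in range(total):
        adapting = it < config.adapt

        # ---- individual Weibull shape k (log RW) --------------------------
        prop = k * np.exp(ad["k"].scale * rng.standard_normal(n))
        wll_p = md.weibull_ll(prop, g)
        hk_p = hyper_k(prop, kappa, sk)
        delta = like * (wll_p - wll) + (hk_p - hk) + (np.log(prop) - np.log(k))
        acc = metropolis_vec(delta, n)
        k = np.where(acc, prop, k)
        wll = np.where(acc, wll_p, wll)
        hk = np.where(acc, hk_p, hk)
        ad["k"].record(acc, adapting)

        # ---- individual Weibull scale g (log RW) --------------------------
        prop = g * np.exp(ad["g"].scale * rng.standard_normal(n))
        wll_p = md.weibull_ll(k, prop)
        hg_p = hyper_g(prop, gam, sg)
        delta = like * (wll_p - wll) + (hg_p - hg) + (np.log(prop) - np.log(g))
        acc = metropolis_vec(delta, n)
        g = np.where(acc, prop, g)
        wll = np.where(acc, wll_p, wll)
        hg = np.where(acc, hg_p, hg)
        ad["g"].record(acc, adapting)

        # ---- individual persistence r (logit RW) --------------------------
        lo = np.log(r) - np.log1p(-r)
        prop = 1.0 / (1.0 + np.exp(-(lo + ad["r"].scale * rng.standard_normal(n))))
        prop = np.clip(prop, 1e-12, 1 - 1e-12)
        all_p = md.angle_ll(prop, theta1)
        hr_p = hyper_r(prop, phi, sp)
        jac = np.log(prop) + np.log1p(-prop) - np.log(r) - np.log1p(-r)
        delta = like * (all_p - all_) + (hr_p - hr) + jac
        acc = metropolis_vec(delta, n)
        r = np.where(acc, prop, r)
        all_ = np.where(acc, all_p, all_)
        hr = np.where(acc, hr_p, hr)
        ad["r"].record(acc, adapting)

        # ---- initial angle theta1 (circular RW, uniform prior) ------------
        prop = wrap_angle(theta1 + ad["theta1"].scale * rng.standard_normal(n))
        all_p = md.angle_ll(r, prop)
        delta = like * (all_p - all_)
        acc = metropolis_vec(delta, n)
        theta1 = np.where(acc, prop, theta1)
        all_ = np.where(acc, all_p, all_)
        ad["theta1"].record(acc, adapting)

        # ---- initial step s1: likelihood-inert, direct prior draw ---------
        s1 = rng.uniform(0.0, S1_MAX, size=n)

        # ---- class-level kappa_c ------------------------------------------
        prop = kappa + ad["kappa"].scale * rng.standard_normal(C)
        ok = (prop > 0) & (prop < KAPPA_MAX)
        propc = np.where(ok, prop, kappa)
        hk_p = hyper_k(k, propc, sk)
        dsum = np.bincount(md.cls, weights=hk_p - hk, minlength=C)
        delta = np.where(ok, dsum, -np.inf)
        acc = metropolis_vec(delta, C)
        kappa = np.where(acc, propc, kappa)
        if acc.any():
            hk = np.where(acc[md.cls], hk_p, hk)
        ad["kappa"].record(acc, adapting)

        # ---- class-level gamma_c ------------------------------------------
        prop = gam + ad["gamma"].scale * rng.standard_normal(C)
        ok = (prop > 0) & (prop < GAMMA_MAX)
        propc = np.where(ok, prop, gam)
        hg_p = hyper_g(g, propc, sg)
        dsum = np.bincount(md.cls, weights=hg_p - hg, minlength=C)
        delta = np.where(ok, dsum, -np.inf)
        acc = metropolis_vec(delta, C)
        gam = np.where(acc, propc, gam)
        if acc.any():
            hg = np.where(acc[md.cls], hg_p, hg)
        ad["gamma"].record(acc, adapting)

        # ---- class-level phi_c --------------------------------------------
        prop = phi + ad["phi"].scale * rng.standard_normal(C)
        ok = (prop > 0) & (prop < 1) & _beta_feasible(np.clip(prop, 1e-6, 1 - 1e-6), sp)
        propc = np.where(ok, prop, phi)
        hr_p = hyper_r(r, propc, sp)
        dsum = np.bincount(md.cls, weights=hr_p - hr, minlength=C)
        delta = np.where(ok, dsum, -np.inf)
        acc = metropolis_vec(delta, C)
        phi = np.where(acc, propc, phi)
        if acc.any():
            hr = np.where(acc[md.cls], hr_p, hr)
        ad["phi"].record(acc, adapting)

        # ---- global SDs ----------------------------------------------------
        prop = sk + float(ad["sigma_kappa"].scale) * rng.standard_normal()
        if 0 < prop < SIGMA_KAPPA_MAX:
            hk_p = hyper_k(k, kappa, prop)
            if np.log(rng.uniform()) < (hk_p - hk).sum():
                sk, hk = prop, hk_p
                ad["sigma_kappa"].record(1.0, adapting)
            else:
                ad["sigma_kappa"].record(0.0, adapting)
        else:
            ad["sigma_kappa"].record(0.0, adapting)

        prop = sg + float(ad["sigma_gamma"].scale) * rng.standard_normal()
        if 0 < prop < SIGMA_GAMMA_MAX:
            hg_p = hyper_g(g, gam, prop)
            if np.log(rng.uniform()) < (hg_p - hg).sum():
                sg, hg = prop, hg_p
                ad["sigma_gamma"].record(1.0, adapting)
            else:
                ad["sigma_gamma"].record(0.0, adapting)
        else:
            ad["sigma_gamma"].record(0.0, adapting)

        prop = sp + float(ad["sigma_phi"].scale) * rng.standard_normal()
        if 0 < prop < SIGMA_PHI_MAX and _beta_feasible(phi, prop).all():
            hr_p = hyper_r(r, phi, prop)
            if np.log(rng.uniform()) < (hr_p - hr).sum():
                sp, hr = prop, hr_p
                ad["sigma_phi"].record(1.0, adapting)
            else:
                ad["sigma_phi"].record(0.0, adapting)
        else:
            ad["sigma_phi"].record(0.0, adapting)

        # ---- save ----------------------------------------------------------
        if it >= keep_from and (it - keep_from) % config.thin == 0 and saved < n_saved:
            draws["kappa"][saved] = kappa
            draws["gamma"][saved] = gam
            draws["phi"][saved] = phi
            draws["sigma_kappa"][saved] = sk
            draws["sigma_gamma"][saved] = sg
            draws["sigma_phi"][saved] = sp
            if save_individual:
                draws["k"][saved] = k
                draws["g"][saved] = g
                draws["r"][saved] = r
            saved += 1

    for name in draws:
        draws[name] = draws[name][:saved]

    rhat = {}
    for c, cname in enumerate(md.class_names):
        rhat[f"kappa[{cname}]"] = split_rhat(draws["kappa"][:, c])
        rhat[f"gamma[{cname}]"] = split_rhat(draws["gamma"][:, c])
        rhat[f"phi[{cname}]"] = split_rhat(draws["phi"][:, c])
    for name in ("sigma_kappa", "sigma_gamma", "sigma_phi"):
        rhat[name] = split_rhat(draws[name])
    bad = {k_: v for k_, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        warnings.warn(f"split-R-hat above 1.1 for {sorted(bad)}", RuntimeWarning)

    meta = {
        "config": config,
        "angle_mode": angle_mode,
        "prior_only": prior_only,
        "animal_ids": md.animal_ids,
        "class_names": md.class_names,
        "class_of_animal": [md.class_names[c] for c in md.cls],
        "acceptance": {name: a.acceptance_rate() for name, a in ad.items()},
        "split_rhat": rhat,
    }
    return PosteriorSamples(
        params=draws,
        dataset_index=np.full(saved, dataset_index),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# pooling and class comparison
# ---------------------------------------------------------------------------


def pool_and_summarize(
    samples: list[PosteriorSamples] | PosteriorSamples,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate draws across imputed datasets and summarize.

    Reports the median and equal-tailed 95% credible interval for each class
    parameter, plus the derived mean step length gamma*Gamma(1+1/kappa)
    computed per draw.
    """
    pooled = (
        PosteriorSamples.concat(samples) if isinstance(samples, list) else samples
    )
    if class_names is None:
        metas = pooled.meta.get("pooled_from", [pooled.meta])
        class_names = metas[0].get("class_names")
    C = pooled.params["kappa"].shape[1]
    class_names = class_names or [f"class{i}" for i in range(C)]

    rows = []

    def add(name, cls, x):
        lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append(
            {"parameter": name, "class": cls, "median": med, "ci_lo": lo, "ci_hi": hi}
        )

    for c, cname in enumerate(class_names):
        add("kappa", cname, pooled.params["kappa"][:, c])
        add("gamma", cname, pooled.params["gamma"][:, c])
        add("phi", cname, pooled.params["phi"][:, c])
        add(
            "step_length",
            cname,
            mean_step_length(pooled.params["kappa"][:, c], pooled.params["gamma"][:, c]),
        )
    for name in ("sigma_kappa", "sigma_gamma", "sigma_phi"):
        add(name, "", pooled.params[name])
    return pd.DataFrame(rows)


def compare_classes(summary: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 95% CI overlap per parameter and class pair.

    ``overlap_width`` = min(upper limits) - max(lower limits); positive means
    the intervals overlap by that amount, negative is the gap between them.
    """
    rows = []
    df = summary[summary["class"] != ""]
    for param, grp in df.groupby("parameter", sort=False):
        classes = list(grp["class"])
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                a = grp.iloc[i]
                b = grp.iloc[j]
                width = min(a["ci_hi"], b["ci_hi"]) - max(a["ci_lo"], b["ci_lo"])
                rows.append(
                    {
                        "parameter": param,
                        "class_a": classes[i],
                        "class_b": classes[j],
                        "overlap": bool(width > 0),
                        "overlap_width": float(width),
                    }
                )
    return pd.DataFrame(rows)
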