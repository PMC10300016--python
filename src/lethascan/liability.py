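"""Single-trait liability threshold animal model and EBV deregression.

The model is l = X beta + Z a + e on an unobserved liability l, with
contemporary-group fixed effects beta, additive animal effects
a ~ N(0, A sigma2_a) through the pedigree relationship matrix A, and
e ~ N(0, I). A binary record y is 1 iff its liability exceeds the threshold.
For identifiability the residual variance is fixed at 1 and the threshold at
0; heritability h2 = sigma2_a / (sigma2_a + 1) is scale-free.

Fitting is by Gibbs sampling: truncated-normal draws for the liabilities,
single-site Gauss-Seidel draws over the mixed-model equations for beta and a
(the animal-breeding standard), and a scaled-inverse-chi-square draw for
sigma2_a. Posterior means give EBVs; prediction-error variance gives
reliability r2 = 1 - PEV/sigma2_a.

EBVs are deregressed by the parent-average-removal method of Garrick,
Taylor & Fernando (2009) before association analysis; animals below the
accuracy floor are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .pedigree import Pedigree

logger = logging.getLogger(__name__)


def prepare_traits(df: pd.DataFrame, min_cg: int = 5) -> pd.DataFrame:
    """Drop contemporary groups with fewer than ``min_cg`` records or without
    variation in the binary score; returns the surviving records.

    ``df`` holds one trait: columns animal, value (strictly 0/1), cg.
    """
    if not df["value"].isin([0, 1]).all():
        raise ValueError("trait values must be strictly binary 0/1")
    sizes = df.groupby("cg")["value"].agg(["size", "nunique"])
    keep = sizes[(sizes["size"] >= min_cg) & (sizes["nunique"] > 1)].index
    out = df[df["cg"].isin(keep)].reset_index(drop=True)
    logger.info(
        "prepare_traits: %d/%d records in %d/%d contemporary groups retained",
        len(out), len(df), len(keep), sizes.shape[0],
    )
    if out.empty:
        raise ValueError("no records survive contemporary-group editing")
    return out


@njit(cache=True)
def _gs_sample_sweep(indptr, indices, data, rhs, sol, normals):
    """One single-site Gibbs sweep over the MME: for each effect j draw from
    N((rhs_j - offdiag . sol)/C_jj, 1/C_jj) given all other effects."""
    n = sol.shape[0]
    for j in range(n):
        s = rhs[j]
        cjj = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            col = indices[k]
            if col == j:
                cjj = data[k]
            else:
                s -= data[k] * sol[col]
        mean = s / cjj
        sol[j] = mean + normals[j] / np.sqrt(cjj)


@njit(cache=True)
def _gs_solve_sweep(indptr, indices, data, rhs, sol):
    """One Gauss-Seidel solver sweep (no noise), for the linear-limit oracle."""
    n = sol.shape[0]
    for j in range(n):
        s = rhs[j]
        cjj = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            col = indices[k]
            if col == j:
                cjj = data[k]
            else:
                s -= data[k] * sol[col]
        sol[j] = s / cjj


def _truncated_normal(mean, y, rng):
    """Draw liabilities ~ N(mean,1) truncated to (-inf,0] for y=0, (0,inf) for y=1."""
    u = rng.random(mean.shape[0])
    p0 = ndtr(-mean)  # P(l <= 0)
    # map u into the allowed CDF slice, then invert
    lo = np.where(y == 1, p0, 0.0)
    hi = np.where(y == 1, 1.0, p0)
    q = lo + u * (hi - lo)
    q = np.clip(q, 1e-14, 1.0 - 1e-14)
    return mean + ndtri(q)


@dataclass
class GibbsResult:
    """Posterior summaries of one threshold-model fit."""

    ids: list
    ebv: np.ndarray
    ebv_sd: np.ndarray
    pev: np.ndarray
    reliability: np.ndarray
    sigma2_a: float
    sigma2_a_sd: float
    h2: float
    h2_sd: float
    h2_samples: np.ndarray
    diverged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.ids,
                "ebv": self.ebv,
                "ebv_sd": self.ebv_sd,
                "pev": self.pev,
                "reliability": self.reliability,
            }
        )


class GibbsThresholdModel(BaseEstimator):
    """Liability threshold animal model fitted by Gibbs sampling.

    Parameters
    ----------
    n_iter, burn_in, thin : chain control (post-burn-in samples every ``thin``
        iterations enter the posterior summaries).
    prior_df, prior_scale : scaled-inverse-chi-square prior on sigma2_a
        (weakly informative; prior mean prior_df*prior_scale/(prior_df-2)).
    start_sigma2_a : chain start for the additive variance.
    estimate_variance : if False, sigma2_a stays fixed at ``start_sigma2_a``.
    observed_liability : if True the response is taken as the liability itself
        (continuous records, no truncation) — the linear-limit mode whose
        posterior means coincide with the mixed-model-equations solution.
    use_inbreeding : Quaas-adjusted A-inverse if True.
    sigma2_a_cap : divergence flag threshold for the sampled variance.
    seed : chain seed (mandatory source of all randomness).

    Attributes
    ----------
    result_ : GibbsResult; ebv_, reliability_, h2_, sigma2_a_ : shortcuts.
    """

    def __init__(
        self,
        n_iter: int = 6000,
        burn_in: int = 1500,
        thin: int = 5,
        prior_df: float = 4.0,
        prior_scale: float = 0.2,
        start_sigma2_a: float = 0.5,
        estimate_variance: bool = True,
        observed_liability: bool = False,
        use_inbreeding: bool = True,
        sigma2_a_cap: float = 50.0,
        seed: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        self.start_sigma2_a = start_sigma2_a
        self.estimate_variance = estimate_variance
        self.observed_liability = observed_liability
        self.use_inbreeding = use_inbreeding
        self.sigma2_a_cap = sigma2_a_cap
        self.seed = seed

    def fit(self, data: pd.DataFrame, pedigree: Pedigree) -> "GibbsThresholdModel":
        """Fit on prepared records (columns animal, value, cg) and a pedigree
        containing every recorded animal."""
        rng = np.random.default_rng(self.seed)
        animals = data["animal"].astype(str).to_numpy()
        missing = [a for a in dict.fromkeys(animals) if a not in pedigree]
        if missing:
            raise ValueError(
                f"{len(missing)} recorded animals missing from pedigree "
                f"(first: {missing[:3]})"
            )
        y = data["value"].to_numpy(dtype=float)
        cg_codes, cg_levels = pd.factorize(data["cg"], sort=True)
        n_cg = len(cg_levels)
        n_anim = len(pedigree)
        anim_idx = np.array([pedigree.index_of(a) for a in animals])
        n_rec = len(y)
        n_eff = n_cg + n_anim

        # design W = [X Z] as CSR, one 1 per record and block
        rows = np.repeat(np.arange(n_rec), 2)
        cols = np.empty(2 * n_rec, dtype=np.int64)
        cols[0::2] = cg_codes
        cols[1::2] = n_cg + anim_idx
        W = sparse.csr_matrix(
            (np.ones(2 * n_rec), (rows, cols)), shape=(n_rec, n_eff)
        )
        WtW = (W.T @ W).tocsr()
        rf = pedigree.relationship_factors(use_inbreeding=self.use_inbreeding)
        K = sparse.block_diag(
            [sparse.csr_matrix((n_cg, n_cg)), rf.a_inverse], format="csr"
        )
        # union sparsity so the data arrays stay aligned across lambda updates
        pattern = ((WtW != 0) + (K != 0)).tocsr()
        pattern.sort_indices()
        coo = pattern.tocoo()
        base = pattern.astype(float).copy()
        base.data = np.asarray(WtW[coo.row, coo.col]).ravel()
        kmat = pattern.astype(float).copy()
        kmat.data = np.asarray(K[coo.row, coo.col]).ravel()
        indptr, indices = base.indptr, base.indices
        diag_probe = base.diagonal() + kmat.diagonal()
        if np.any(diag_probe <= 0):
            raise ValueError(
                "mixed-model equations not positive definite: an effect has no "
                "information (pedigree/design fault)"
            )

        sol = np.zeros(n_eff)
        sigma2_a = float(self.start_sigma2_a)
        if self.observed_liability:
            liab = y.astype(float).copy()
        else:
            liab = np.where(y == 1, 0.5, -0.5)

        keep = [
            it
            for it in range(self.n_iter)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0
        ]
        n_keep = len(keep)
        if n_keep == 0:
            raise ValueError("chain keeps no samples; check n_iter/burn_in/thin")
        keep_set = set(keep)

        a_sum = np.zeros(n_anim)
        a_sumsq = np.zeros(n_anim)
        s2_samples = np.empty(n_keep)
        ks = 0
        nu, S2 = float(self.prior_df), float(self.prior_scale)
        diverged = False
        ainv = rf.a_inverse

        for it in range(self.n_iter):
            if not self.observed_liability:
                mean = sol[n_cg + anim_idx] + sol[cg_codes]
                liab = _truncated_normal(mean, y, rng)
            rhs = W.T @ liab
            lam = 1.0 / sigma2_a
            data_c = base.data + lam * kmat.data
            normals = rng.standard_normal(n_eff)
            _gs_sample_sweep(indptr, indices, data_c, rhs, sol, normals)
            if self.estimate_variance:
                a = sol[n_cg:]
                ssq = float(a @ (ainv @ a))
                df_post = n_anim + nu
                sigma2_a = (ssq + nu * S2) / rng.chisquare(df_post)
                if sigma2_a > self.sigma2_a_cap:
                    diverged = True
            if it in keep_set:
                a = sol[n_cg:]
                a_sum += a
                a_sumsq += a * a
                s2_samples[ks] = sigma2_a
                ks += 1

        ebv = a_sum / n_keep
        pev = np.maximum(a_sumsq / n_keep - ebv**2, 0.0)
        s2_hat = float(s2_samples.mean())
        rel = np.clip(1.0 - pev / s2_hat, 0.0, 1.0)
        h2_samples = s2_samples / (s2_samples + 1.0)
        self.result_ = GibbsResult(
            ids=list(pedigree.ids),
            ebv=ebv,
            ebv_sd=np.sqrt(pev),
            pev=pev,
            reliability=rel,
            sigma2_a=s2_hat,
            sigma2_a_sd=float(s2_samples.std()),
            h2=float(h2_samples.mean()),
            h2_sd=float(h2_samples.std()),
            h2_samples=h2_samples,
            diverged=diverged,
        )
        if diverged:
            logger.warning(
                "sigma2_a exceeded %.1f during sampling; chain flagged divergent",
                self.sigma2_a_cap,
            )
        return self

    # convenience accessors
    @property
    def ebv_(self):
        return self.result_.ebv

    @property
    def reliability_(self):
        return self.result_.reliability

    @property
    def h2_(self):
        return self.result_.h2

    @property
    def sigma2_a_(self):
        return self.result_.sigma2_a


def gibbs_threshold_model(
    data: pd.DataFrame, ped: Pedigree, **params
) -> GibbsResult:
    """Functional wrapper over :class:`GibbsThresholdModel`."""
    return GibbsThresholdModel(**params).fit(data, ped).result_


def deregress(
    res: GibbsResult,
    ped: Pedigree,
    h2: float,
    min_acc: float = 0.40,
    c: float = 0.5,
) -> pd.DataFrame:
    """Garrick-style deregression of EBVs with parent-average removal.

    Implements the parent-average-removal recipe of Garrick, Taylor &
    Fernando (2009), Genet Sel Evol 41:55, Appendix:

        lambda  = (1 - h2)/h2
        alpha   = 1/(0.5 - r2_PA)
        delta   = (0.5 - r2_PA)/(1 - r2_i)
        Z'Z_PA  = lambda*(0.5*alpha - 4) + 0.5*lambda*sqrt(alpha^2 + 16/delta)
        Z'Z_i   = delta*Z'Z_PA + 2*lambda*(2*delta - 1)
        y_i     = -2*lambda*g_PA + (Z'Z_i + 2*lambda)*g_i
        dEBV    = y_i / Z'Z_i
        r2_DRP  = 1 - lambda/(Z'Z_i + lambda)
        weight  = (1 - h2) / ((c + (1 - r2_DRP)/r2_DRP) * h2)

    with g_PA the parent-average EBV and r2_PA = (r2_sire + r2_dam)/4. For an
    animal with both parents unknown there is no parent-average equation and
    the deregression degenerates to dEBV = EBV/r2 with r2_DRP = r2. ``c`` is
    the fraction of genetic variance not explained by markers. Animals whose
    deregressed accuracy sqrt(r2_DRP) falls below ``min_acc``, or whose
    reliability does not exceed the parent average (no own information), are
    dropped (the latter with a log entry).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0,1)")
    lam = (1.0 - h2) / h2
    idx = {a: i for i, a in enumerate(res.ids)}
    rows = []
    n_skipped = 0
    for i, animal in enumerate(res.ids):
        r2 = float(res.reliability[i])
        if r2 <= 0.0:
            continue
        s, d = ped.sire_of(animal), ped.dam_of(animal)
        r2_s = float(res.reliability[idx[s]]) if s in idx else 0.0
        r2_d = float(res.reliability[idx[d]]) if d in idx else 0.0
        g_s = float(res.ebv[idx[s]]) if s in idx else 0.0
        g_d = float(res.ebv[idx[d]]) if d in idx else 0.0
        no_parents = (s not in idx) and (d not in idx)
        if no_parents:
            debv = res.ebv[i] / r2
            r2_drp = r2
        else:
            r2_pa = (r2_s + r2_d) / 4.0
            if r2 <= r2_pa:
                n_skipped += 1
                continue
            g_pa = (g_s + g_d) / 2.0
            alpha = 1.0 / (0.5 - r2_pa)
            delta = (0.5 - r2_pa) / (1.0 - r2)
            zpz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(
                alpha * alpha + 16.0 / delta
            )
            zpz_i = delta * zpz_pa + 2.0 * lam * (2.0 * delta - 1.0)
            if zpz_i <= 0:
                n_skipped += 1
                continue
            y_i = -2.0 * lam * g_pa + (zpz_i + 2.0 * lam) * res.ebv[i]
            debv = y_i / zpz_i
            r2_drp = 1.0 - lam / (zpz_i + lam)
        acc = np.sqrt(max(r2_drp, 0.0))
        if acc < min_acc:
            continue
        weight = (1.0 - h2) / ((c + (1.0 - r2_drp) / r2_drp) * h2)
        rows.append(
            {"animal": animal, "debv": float(debv), "accuracy": float(acc), "weight": float(weight)}
        )
    if n_skipped:
        logger.info(
            "deregress: %d animals skipped (reliability not above parent average)",
            n_skipped,
        )
    return pd.DataFrame(rows, columns=["animal", "debv", "accuracy", "weight"])
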