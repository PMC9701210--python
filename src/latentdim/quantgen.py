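"""Twin-based variance decomposition of latent scores (AE model).

Phenotypes measured on twins and their families are modelled as

    y ~ Normal(W beta, 2*Phi*sigma2_A + I*sigma2_E)

where ``2*Phi`` is the kinship (coefficient-of-relationship) matrix — 1 on
the diagonal and for MZ co-twins, 0.5 for DZ co-twins and full siblings,
0 across families — ``sigma2_A`` is the additive-genetic and ``sigma2_E``
the unique-environment variance, and W holds fixed-effect covariates.
Narrow-sense heritability is h2 = sigma2_A / (sigma2_A + sigma2_E).  The
bivariate extension decomposes the phenotypic correlation of two traits
into a genetic correlation rho_g (weighting the kinship structure) and an
environmental correlation rho_e (weighting the identity structure).

Fitting is maximum likelihood: the kinship matrix is block-diagonal by
family, each family block is eigendecomposed once, and in the rotated
basis the covariance is diagonal (univariate) or 2x2-block diagonal
(bivariate), so each likelihood evaluation is linear in the sample size.
Fixed effects are profiled out by generalised least squares at every
variance-parameter evaluation.  The LRT against sigma2_A = 0 uses the
50:50 mixture of a point mass at zero and chi-square(1), the standard
reference distribution for a variance component on the boundary; the
tests of rho_g = 0 and rho_e = 0 are interior and use plain chi-square(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "BivariateComponents",
    "build_kinship",
    "fit_ae_univariate",
    "fit_ae_bivariate",
    "falconer_estimate",
    "heritability_of_dimension",
]

LOGLIK_TOL = 1e-8
_VAR_FLOOR = 1e-8
_RHO_BOUND = 0.99999


@dataclass
class KinshipMatrix:
    """2*Phi with the family block structure retained for fast likelihoods."""

    matrix: np.ndarray
    ids: list[str]
    family_slices: list[np.ndarray]  # positional indices per family

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("kinship matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("kinship diagonal must be 1")


def build_kinship(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Kinship 2*Phi from a pedigree table (id, family_id, pair_id,
    zygosity): MZ co-twins 1, same-family members 0.5, unrelated 0."""
    ped = pedigree.reset_index(drop=True)
    for col in ("id", "family_id", "zygosity"):
        if col not in ped.columns:
            raise ValueError(f"pedigree is missing column {col!r}")
    if ped["id"].duplicated().any():
        raise ValueError("duplicate participant ids in pedigree")
    n = len(ped)
    K = np.zeros((n, n))
    slices = []
    for fam, idx in ped.groupby("family_id", sort=False).indices.items():
        idx = np.asarray(idx)
        sub = ped.iloc[idx]
        block = np.full((len(idx), len(idx)), 0.5)
        np.fill_diagonal(block, 1.0)
        if "pair_id" in sub.columns:
            pairs = sub[(sub["pair_id"] != "") & sub["pair_id"].notna()]
            for pid, pidx in pairs.groupby("pair_id").indices.items():
                if len(pidx) > 2:
                    raise ValueError(f"twin pair {pid!r} has >2 members")
                z = set(pairs.iloc[pidx]["zygosity"])
                if len(z) > 1:
                    raise ValueError(f"twin pair {pid!r} has mixed zygosity")
                if len(pidx) == 2 and z == {"MZ"}:
                    a, b = pidx
                    block[a, b] = block[b, a] = 1.0
        K[np.ix_(idx, idx)] = block
        slices.append(idx)
    # MZ pairs make 2*Phi singular but still PSD
    return KinshipMatrix(matrix=K, ids=list(ped["id"]), family_slices=slices)


@dataclass
class _RotatedData:
    """Per-family eigenbasis of 2*Phi with data and design pre-rotated."""

    lam: np.ndarray  # eigenvalues, concatenated over families
    y: np.ndarray  # rotated phenotype(s), (n,) or (n, 2)
    W: np.ndarray  # rotated design, (n, k)


def _rotate(kin: KinshipMatrix, y: np.ndarray, W: np.ndarray) -> _RotatedData:
    lam_all, y_rot, W_rot = [], [], []
    for idx in kin.family_slices:
        lam, Q = np.linalg.eigh(kin.matrix[np.ix_(idx, idx)])
        lam_all.append(np.maximum(lam, 0.0))
        y_rot.append(Q.T @ y[idx])
        W_rot.append(Q.T @ W[idx])
    return _RotatedData(
        lam=np.concatenate(lam_all),
        y=np.concatenate(y_rot),
        W=np.vstack(W_rot),
    )


def _check_design(W: np.ndarray, n: int) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[0] != n:
        raise ValueError("covariate design not aligned with phenotype")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("degenerate (rank-deficient) covariate design")
    return W


def _univariate_nll(theta: np.ndarray, rot: _RotatedData) -> float:
    s2a, s2e = np.exp(theta)
    w = s2a * rot.lam + s2e
    Wt = rot.W / w[:, None]
    beta = np.linalg.solve(rot.W.T @ Wt, Wt.T @ rot.y)
    resid = rot.y - rot.W @ beta
    n = rot.y.shape[0]
    return 0.5 * (np.sum(np.log(w)) + np.sum(resid**2 / w) + n * np.log(2 * np.pi))


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    loglik: float
    loglik_null: float
    lrt: float
    p: float
    beta: np.ndarray
    n: int


def _fit_e_only(rot: _RotatedData) -> tuple[float, np.ndarray]:
    """sigma2_A = 0 reduces to OLS with the ML variance estimate."""
    beta, *_ = np.linalg.lstsq(rot.W, rot.y, rcond=None)
    resid = rot.y - rot.W @ beta
    n = rot.y.shape[0]
    s2 = float(np.sum(resid**2) / n)
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + n)
    return ll, beta


def fit_ae_univariate(
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
) -> VarianceComponents:
    """ML fit of the univariate AE model with a boundary-mixture LRT.

    ``covariates`` may be None (intercept only); an intercept column is
    always prepended.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if n != len(kinship.ids):
        raise ValueError("phenotype not aligned with kinship")
    if n < 30:
        raise ValueError("need n >= 30 for a stable variance decomposition")
    related = any(len(idx) > 1 for idx in kinship.family_slices)
    if not related:
        raise ValueError(
            "no related pairs: additive-genetic variance is not identifiable"
        )
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), _check_design(covariates, n)]
    )
    rot = _rotate(kinship, y, W)

    var_y = max(float(np.var(y)), _VAR_FLOOR)
    lo, hi = np.log(_VAR_FLOOR * var_y), np.log(10.0 * var_y)
    best = None
    for h2_start in (0.2, 0.5, 0.8):
        x0 = np.log(np.array([h2_start * var_y, (1 - h2_start) * var_y]))
        res = optimize.minimize(
            _univariate_nll, x0, args=(rot,), method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)], options={"ftol": LOGLIK_TOL},
        )
        if best is None or res.fun < best.fun:
            best = res
    s2a, s2e = np.exp(best.x)
    ll = -best.fun
    ll0, _ = _fit_e_only(rot)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = 1.0 if lrt <= 0 else 0.5 * float(chi2.sf(lrt, 1))
    w = s2a * rot.lam + s2e
    Wt = rot.W / w[:, None]
    beta = np.linalg.solve(rot.W.T @ Wt, Wt.T @ rot.y)
    return VarianceComponents(
        sigma2_a=float(s2a), sigma2_e=float(s2e),
        h2=float(s2a / (s2a + s2e)), loglik=ll, loglik_null=ll0,
        lrt=lrt, p=p, beta=beta, n=n,
    )


# ---------------------------------------------------------------------------
# bivariate AE model
# ---------------------------------------------------------------------------


def _biv_cov_blocks(theta: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Per-eigencoordinate 2x2 covariance blocks, shape (n, 2, 2)."""
    s2ax, s2ex, s2ay, s2ey = np.exp(theta[:4])
    rg, re = np.tanh(theta[4]), np.tanh(theta[5])
    c11 = s2ax * lam + s2ex
    c22 = s2ay * lam + s2ey
    c12 = rg * np.sqrt(s2ax * s2ay) * lam + re * np.sqrt(s2ex * s2ey)
    C = np.empty((lam.size, 2, 2))
    C[:, 0, 0] = c11
    C[:, 1, 1] = c22
    C[:, 0, 1] = C[:, 1, 0] = c12
    return C


def _biv_nll(theta: np.ndarray, rot: _RotatedData) -> float:
    C = _biv_cov_blocks(theta, rot.lam)
    det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] ** 2
    if np.any(det <= 0):
        return np.inf
    i11 = C[:, 1, 1] / det
    i22 = C[:, 0, 0] / det
    i12 = -C[:, 0, 1] / det
    W, y = rot.W, rot.y  # y is (n, 2)
    # GLS normal equations for stacked (beta_x, beta_y)
    A11 = W.T @ (W * i11[:, None])
    A22 = W.T @ (W * i22[:, None])
    A12 = W.T @ (W * i12[:, None])
    b1 = W.T @ (i11 * y[:, 0] + i12 * y[:, 1])
    b2 = W.T @ (i12 * y[:, 0] + i22 * y[:, 1])
    k = W.shape[1]
    A = np.block([[A11, A12], [A12, A22]])
    b = np.concatenate([b1, b2])
    beta = np.linalg.solve(A, b)
    rx = y[:, 0] - W @ beta[:k]
    ry = y[:, 1] - W @ beta[k:]
    quad = i11 * rx**2 + 2 * i12 * rx * ry + i22 * ry**2
    n = rot.lam.size
    return 0.5 * (np.sum(np.log(det)) + np.sum(quad) + 2 * n * np.log(2 * np.pi))


@dataclass
class BivariateComponents:
    h2_x: float
    h2_y: float
    rho_g: float
    rho_e: float
    p_rho_g: float
    p_rho_e: float
    loglik: float
    sigma2: dict = field(default_factory=dict)
    n: int = 0

    @property
    def phenotypic_corr(self) -> float:
        """Implied phenotypic correlation:
        sqrt(h2x*h2y)*rho_g + sqrt((1-h2x)(1-h2y))*rho_e."""
        return (
            np.sqrt(self.h2_x * self.h2_y) * self.rho_g
            + np.sqrt((1 - self.h2_x) * (1 - self.h2_y)) * self.rho_e
        )


def _biv_optimise(
    rot: _RotatedData, fixed: dict[int, float], var_scale: tuple[float, float]
) -> tuple[float, np.ndarray]:
    """Minimise the bivariate NLL with some parameters frozen."""
    vx, vy = var_scale
    zb = np.arctanh(_RHO_BOUND)
    bounds_full = [
        (np.log(_VAR_FLOOR * vx), np.log(10 * vx)),
        (np.log(_VAR_FLOOR * vx), np.log(10 * vx)),
        (np.log(_VAR_FLOOR * vy), np.log(10 * vy)),
        (np.log(_VAR_FLOOR * vy), np.log(10 * vy)),
        (-zb, zb),
        (-zb, zb),
    ]
    free = [i for i in range(6) if i not in fixed]

    def full_theta(x):
        theta = np.empty(6)
        for j, i in enumerate(free):
            theta[i] = x[j]
        for i, v in fixed.items():
            theta[i] = v
        return theta

    def nll(x):
        return _biv_nll(full_theta(x), rot)

    starts = []
    for h2s in (0.3, 0.6):
        t0 = np.array([
            np.log(h2s * vx), np.log((1 - h2s) * vx),
            np.log(h2s * vy), np.log((1 - h2s) * vy),
            0.0, 0.0,
        ])
        starts.append([t0[i] for i in free])
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[bounds_full[i] for i in free], options={"ftol": LOGLIK_TOL},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, full_theta(best.x)


def fit_ae_bivariate(
    phenotype_x: np.ndarray,
    phenotype_y: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
) -> BivariateComponents:
    """ML fit of the bivariate AE model with LRTs for rho_g=0 and rho_e=0."""
    x = np.asarray(phenotype_x, dtype=float)
    y = np.asarray(phenotype_y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n or n != len(kinship.ids):
        raise ValueError("phenotypes not aligned with kinship")
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), _check_design(covariates, n)]
    )
    rot = _rotate(kinship, np.column_stack([x, y]), W)
    scale = (max(float(np.var(x)), _VAR_FLOOR), max(float(np.var(y)), _VAR_FLOOR))

    ll, theta = _biv_optimise(rot, fixed={}, var_scale=scale)
    ll_ng, _ = _biv_optimise(rot, fixed={4: 0.0}, var_scale=scale)
    ll_ne, _ = _biv_optimise(rot, fixed={5: 0.0}, var_scale=scale)

    s2ax, s2ex, s2ay, s2ey = np.exp(theta[:4])
    return BivariateComponents(
        h2_x=float(s2ax / (s2ax + s2ex)),
        h2_y=float(s2ay / (s2ay + s2ey)),
        rho_g=float(np.tanh(theta[4])),
        rho_e=float(np.tanh(theta[5])),
        p_rho_g=float(chi2.sf(max(0.0, 2 * (ll - ll_ng)), 1)),
        p_rho_e=float(chi2.sf(max(0.0, 2 * (ll - ll_ne)), 1)),
        loglik=ll,
        sigma2={"a_x": float(s2ax), "e_x": float(s2ex),
                "a_y": float(s2ay), "e_y": float(s2ey)},
        n=n,
    )


def falconer_estimate(
    phenotype: np.ndarray, pedigree: pd.DataFrame
) -> float:
    """Closed-form twin oracle: h2 = 2 (r_MZ - r_DZ) from within-pair
    correlations.  Independent of the ML machinery; used for cross-checks."""
    ped = pedigree.reset_index(drop=True)
    y = np.asarray(phenotype, dtype=float)
    corrs = {}
    for zyg in ("MZ", "DZ"):
        pairs = []
        sel = ped[ped["zygosity"] == zyg]
        for _, idx in sel.groupby("pair_id").indices.items():
            if len(idx) == 2:
                pairs.append(y[sel.index[idx]])
        if len(pairs) < 2:
            raise ValueError(f"not enough complete {zyg} pairs")
        a = np.array(pairs)
        # double-entered intraclass-style correlation
        both = np.concatenate([a, a[:, ::-1]])
        corrs[zyg] = float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])
    return 2.0 * (corrs["MZ"] - corrs["DZ"])


def heritability_of_dimension(
    result,
    cohort,
    use_holdout_scores: bool = False,
    extended_covariates: bool = False,
) -> dict:
    """Variance decomposition of one latent dimension's scores.

    Fits univariate AE models for the brain and behaviour scores and the
    bivariate model between them.  The default covariates are age and
    gender; the extended set adds the TIV analogue, age^2 and the
    age-by-gender interactions.  ``use_holdout_scores`` switches to scores
    from the splits where each participant was held out (the sensitivity
    variant; participants never held out are dropped).
    """
    meta = cohort.metadata.reset_index(drop=True)
    suffix = "_holdout" if use_holdout_scores else ""
    sc = result.scores.set_index("id")
    brain = sc[f"brain_score{suffix}"].reindex(meta["id"]).to_numpy()
    behav = sc[f"behaviour_score{suffix}"].reindex(meta["id"]).to_numpy()
    keep = np.isfinite(brain) & np.isfinite(behav)
    meta = meta[keep].reset_index(drop=True)
    brain, behav = brain[keep], behav[keep]

    kin = build_kinship(meta[["id", "family_id", "pair_id", "zygosity"]])
    age = meta["age"].to_numpy(float)
    gender = meta["gender"].to_numpy(float)
    if extended_covariates:
        tiv = cohort.size_totals.set_index("id")["tiv"].reindex(meta["id"]).to_numpy(float)
        cov = np.column_stack([
            tiv, age, age**2, gender, age * gender, age**2 * gender,
        ])
    else:
        cov = np.column_stack([age, gender])
    return {
        "brain": fit_ae_univariate(brain, cov, kin),
        "behaviour": fit_ae_univariate(behav, cov, kin),
        "bivariate": fit_ae_bivariate(brain, behav, cov, kin),
        "n": int(keep.sum()),
    }
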