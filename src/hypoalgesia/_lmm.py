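"""REML estimation of linear mixed models with typed residual variances.

This is the numerical engine behind the stacked mediation model: a linear
mixed model

    z_i = X_i beta + U_i gamma_i + eps_i,      gamma_i ~ N(0, Psi),

for participant (group) i, where each row carries a *type* (mediator row or
outcome row) and residuals are independent with a type-specific variance,
eps_ij ~ N(0, sigma^2_{type(j)}).  Estimation is restricted maximum
likelihood with beta profiled out by GLS.

Parameterization
----------------
Psi = Lambda Lambda' with Lambda lower triangular, diagonal stored on the
log scale (so Psi stays positive semi-definite for any unconstrained
parameter vector, and Lambda -> 0 is reachable); residual variances are
log-parameterized.  Structural zeros in Lambda (a diagonal or block Psi) are
imposed through a boolean lower-triangular mask.

All per-group data enter only through cross-products (sufficient
statistics), accumulated once in :class:`GroupStats`; one objective/gradient
evaluation is a handful of batched (J, q, q) operations via the Woodbury
identity, independent of the number of rows.  Participant-level bootstrap
resampling is then just an index into the group axis.

The analytic gradient follows the standard REML score
``tr(P dV) - r'V^-1 (dV) V^-1 r`` with ``P = V^-1 - V^-1 X M^-1 X' V^-1``,
reduced to the same cross-products; it is verified against finite
differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

__all__ = ["GroupStats", "LMMFit", "fit_lmm", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the REML optimum after restarts."""


@dataclass
class GroupStats:
    """Per-group, per-row-type cross-products of (X, U, z).

    Shapes: ``n (J,T)``, ``Sxx (J,T,p,p)``, ``Sxu (J,T,p,q)``,
    ``Suu (J,T,q,q)``, ``Sxz (J,T,p)``, ``Suz (J,T,q)``, ``Szz (J,T)``.
    """

    n: np.ndarray
    Sxx: np.ndarray
    Sxu: np.ndarray
    Suu: np.ndarray
    Sxz: np.ndarray
    Suz: np.ndarray
    Szz: np.ndarray
    group_ids: np.ndarray
    x_names: list[str]
    u_names: list[str]
    #: per-column RMS of X; cross-products are stored for the equilibrated
    #: design X diag(1/x_scale) and estimates are mapped back on report
    x_scale: np.ndarray | None = None

    @property
    def J(self) -> int:
        return self.n.shape[0]

    @property
    def T(self) -> int:
        return self.n.shape[1]

    @property
    def p(self) -> int:
        return self.Sxx.shape[2]

    @property
    def q(self) -> int:
        return self.Suu.shape[2]

    @property
    def n_rows(self) -> int:
        return int(self.n.sum())

    @classmethod
    def from_arrays(
        cls,
        groups: np.ndarray,
        row_type: np.ndarray,
        X: np.ndarray,
        U: np.ndarray,
        z: np.ndarray,
        x_names: list[str] | None = None,
        u_names: list[str] | None = None,
        n_types: int | None = None,
    ) -> "GroupStats":
        groups = np.asarray(groups)
        row_type = np.asarray(row_type, dtype=int)
        X = np.asarray(X, dtype=float)
        U = np.asarray(U, dtype=float)
        z = np.asarray(z, dtype=float)
        # equilibrate X columns (raw trial-number covariates otherwise push
        # the GLS normal matrix towards numerical indefiniteness)
        x_scale = np.sqrt(np.mean(X * X, axis=0))
        x_scale[x_scale < 1e-12] = 1.0
        X = X / x_scale
        gids = np.unique(groups)
        T = int(n_types if n_types is not None else row_type.max() + 1)
        J, p, q = len(gids), X.shape[1], U.shape[1]
        out = cls(
            n=np.zeros((J, T)),
            Sxx=np.zeros((J, T, p, p)),
            Sxu=np.zeros((J, T, p, q)),
            Suu=np.zeros((J, T, q, q)),
            Sxz=np.zeros((J, T, p)),
            Suz=np.zeros((J, T, q)),
            Szz=np.zeros((J, T)),
            group_ids=gids,
            x_names=list(x_names) if x_names else [f"x{i}" for i in range(p)],
            u_names=list(u_names) if u_names else [f"u{i}" for i in range(q)],
            x_scale=x_scale,
        )
        for j, g in enumerate(gids):
            in_g = groups == g
            for t in range(T):
                m = in_g & (row_type == t)
                if not m.any():
                    continue
                Xt, Ut, zt = X[m], U[m], z[m]
                out.n[j, t] = m.sum()
                out.Sxx[j, t] = Xt.T @ Xt
                out.Sxu[j, t] = Xt.T @ Ut
                out.Suu[j, t] = Ut.T @ Ut
                out.Sxz[j, t] = Xt.T @ zt
                out.Suz[j, t] = Ut.T @ zt
                out.Szz[j, t] = zt @ zt
        return out

    def take(self, idx: np.ndarray) -> "GroupStats":
        """Select groups (with repetition) along the group axis — the
        participant-level bootstrap operation."""
        idx = np.asarray(idx, dtype=int)
        return GroupStats(
            n=self.n[idx],
            Sxx=self.Sxx[idx],
            Sxu=self.Sxu[idx],
            Suu=self.Suu[idx],
            Sxz=self.Sxz[idx],
            Suz=self.Suz[idx],
            Szz=self.Szz[idx],
            group_ids=np.arange(len(idx)),
            x_names=self.x_names,
            u_names=self.u_names,
            x_scale=self.x_scale,
        )


@dataclass
class LMMFit:
    """Fitted mixed model: GLS fixed effects at the REML variance optimum."""

    beta: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    df_resid: int
    psi: np.ndarray
    sigma2: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    reml_neg2: float
    converged: bool
    grad_inf: float
    n_iter: int
    x_names: list[str]
    u_names: list[str]
    objective_trajectory: list[float] = field(default_factory=list)
    singular_psi: bool = False

    def fixef(self) -> dict[str, float]:
        return dict(zip(self.x_names, map(float, self.beta)))

    def psi_entry(self, name_a: str, name_b: str) -> float:
        ia, ib = self.u_names.index(name_a), self.u_names.index(name_b)
        return float(self.psi[ia, ib])


class _REMLProblem:
    def __init__(
        self,
        stats: GroupStats,
        psi_mask: np.ndarray | None = None,
        zero_psi: bool = False,
    ):
        self.s = stats
        q = stats.q
        self.zero_psi = zero_psi
        if zero_psi:
            # Psi pinned at exactly 0: only residual variances are estimated
            psi_mask = np.zeros((q, q), dtype=bool)
            self.mask = psi_mask
            self.rows = self.cols = np.empty(0, dtype=int)
            self.is_diag = np.empty(0, dtype=bool)
            self.n_lam = 0
            self.n_par = stats.T
            return
        if psi_mask is None:
            psi_mask = np.tril(np.ones((q, q), dtype=bool))
        psi_mask = np.asarray(psi_mask, dtype=bool) & np.tril(np.ones((q, q), dtype=bool))
        if not psi_mask.diagonal().all():
            raise ValueError("psi_mask must include every diagonal element")
        self.mask = psi_mask
        rows, cols = np.nonzero(psi_mask)
        self.rows, self.cols = rows, cols
        self.is_diag = rows == cols
        self.n_lam = len(rows)
        self.n_par = self.n_lam + stats.T

    def lam_of(self, theta: np.ndarray) -> np.ndarray:
        q = self.s.q
        lam = np.zeros((q, q))
        vals = np.array(theta[: self.n_lam], dtype=float)
        vals = np.where(self.is_diag, np.exp(vals), vals)
        lam[self.rows, self.cols] = vals
        return lam

    def obj_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        s = self.s
        q, p, T = s.q, s.p, s.T
        lam = self.lam_of(theta)
        rho = np.asarray(theta[self.n_lam :], dtype=float)
        w = np.exp(-rho)

        A = np.einsum("t,jtab->jab", w, s.Suu)
        B = np.einsum("t,jtab->jab", w, s.Sxu)
        d = np.einsum("t,jta->ja", w, s.Suz)
        Csum = np.einsum("t,jtab->ab", w, s.Sxx)
        esum = np.einsum("t,jta->a", w, s.Sxz)
        fsum = float(np.einsum("t,jt->", w, s.Szz))
        ntot = s.n.sum(axis=0)

        AL = A @ lam
        K = np.eye(q) + lam.T @ AL  # (J,q,q), PD by construction
        Kinv = np.linalg.inv(K)
        sign, logdetK = np.linalg.slogdet(K)
        logdetK = float(logdetK.sum())

        BL = B @ lam
        Ld = d @ lam
        Kinv_BLT = Kinv @ np.swapaxes(BL, 1, 2)  # (J,q,p) = K^-1 Lam' B'
        Kinv_Ld = np.einsum("jab,jb->ja", Kinv, Ld)

        M = Csum - np.einsum("jpa,jar->pr", BL, Kinv_BLT)
        v = esum - np.einsum("jpa,ja->p", BL, Kinv_Ld)
        quadz = fsum - float(np.einsum("ja,ja->", Ld, Kinv_Ld))

        M = 0.5 * (M + M.T)
        try:
            Mc = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            # extreme line-search probe lost positive definiteness to
            # cancellation; report a huge value so the optimizer backtracks
            return 1e15, np.zeros(self.n_par)
        beta = np.linalg.solve(M, v)
        Q = quadz - float(v @ beta)
        logdetM = 2.0 * float(np.log(np.diag(Mc)).sum())
        obj = logdetK + float(ntot @ rho) + logdetM + Q

        # ---- gradient ----
        Minv = np.linalg.inv(M)
        m = d - np.einsum("jpa,p->ja", B, beta)  # U'R^-1 r
        Lm = m @ lam
        Kinv_Lm = np.einsum("jab,jb->ja", Kinv, Lm)
        h = np.einsum("ab,jb->ja", lam, Kinv_Lm)  # Lam K^-1 Lam' m
        Ug = m - np.einsum("jab,jb->ja", A, h)  # U'V^-1 r

        Kinv_ALT = Kinv @ np.swapaxes(AL, 1, 2)
        Wq = A - AL @ Kinv_ALT  # U'V^-1 U
        H = np.swapaxes(B, 1, 2) - AL @ Kinv_BLT  # U'V^-1 X

        G_psi = (
            Wq.sum(axis=0)
            - np.einsum("jap,pr,jbr->ab", H, Minv, H)
            - np.einsum("ja,jb->ab", Ug, Ug)
        )
        GL = 2.0 * G_psi @ lam
        g_lam = GL[self.rows, self.cols]
        g_lam = np.where(self.is_diag, g_lam * np.diag(lam)[self.rows], g_lam)

        Theta = np.einsum("ab,jbp->jap", lam, Kinv_BLT)  # Lam K^-1 Lam' B'
        g_rho = np.zeros(T)
        for t in range(T):
            Suu_t, Sxu_t = s.Suu[:, t], s.Sxu[:, t]
            LSuuL = np.einsum("ab,jbc,cd->jad", lam.T, Suu_t, lam)
            term1 = ntot[t] - w[t] * float(np.einsum("jab,jba->", Kinv, LSuuL))
            SxuTh = np.einsum("jpa,jaq->pq", Sxu_t, Theta)
            ThSuuTh = np.einsum("jap,jab,jbq->pq", Theta, Suu_t, Theta)
            Pt = w[t] * (s.Sxx[:, t].sum(axis=0) - SxuTh - SxuTh.T + ThSuuTh)
            term2 = float(np.einsum("pq,qp->", Minv, Pt))
            rss = (
                s.Szz[:, t]
                - 2.0 * s.Sxz[:, t] @ beta
                + np.einsum("jpq,p,q->j", s.Sxx[:, t], beta, beta)
            )
            ruz = s.Suz[:, t] - np.einsum("jpa,p->ja", Sxu_t, beta)
            term3 = w[t] * float(
                rss.sum()
                - 2.0 * np.einsum("ja,ja->", ruz, h)
                + np.einsum("ja,jab,jb->", h, Suu_t, h)
            )
            g_rho[t] = term1 - term2 - term3
        return obj, np.concatenate([g_lam, g_rho])

    def beta_cov(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """GLS beta-hat and its covariance (X'V^-1X)^-1 at given theta."""
        s = self.s
        lam = self.lam_of(theta)
        rho = np.asarray(theta[self.n_lam :], dtype=float)
        w = np.exp(-rho)
        q = s.q
        A = np.einsum("t,jtab->jab", w, s.Suu)
        B = np.einsum("t,jtab->jab", w, s.Sxu)
        d = np.einsum("t,jta->ja", w, s.Suz)
        Csum = np.einsum("t,jtab->ab", w, s.Sxx)
        esum = np.einsum("t,jta->a", w, s.Sxz)
        K = np.eye(q) + lam.T @ (A @ lam)
        Kinv = np.linalg.inv(K)
        BL = B @ lam
        Kinv_BLT = Kinv @ np.swapaxes(BL, 1, 2)
        M = Csum - np.einsum("jpa,jar->pr", BL, Kinv_BLT)
        v = esum - np.einsum("jpa,ja->p", BL, np.einsum("jab,jb->ja", Kinv, d @ lam))
        beta = np.linalg.solve(M, v)
        return beta, np.linalg.inv(M)

    def start(self) -> np.ndarray:
        """Data-driven start: pooled OLS residual variances, modest
        random-effect scales, zero covariances."""
        s = self.s
        Sxx = s.Sxx.sum(axis=(0, 1))
        Sxz = s.Sxz.sum(axis=(0, 1))
        beta = np.linalg.solve(Sxx + 1e-10 * np.eye(s.p), Sxz)
        rho0 = np.zeros(s.T)
        rv = np.zeros(s.T)
        for t in range(s.T):
            rss = (
                s.Szz[:, t].sum()
                - 2.0 * s.Sxz[:, t].sum(axis=0) @ beta
                + beta @ s.Sxx[:, t].sum(axis=0) @ beta
            )
            nt = max(s.n[:, t].sum(), 1.0)
            rv[t] = max(rss / nt, 1e-8)
            rho0[t] = np.log(0.8 * rv[t])
        sd0 = 0.4 * np.sqrt(rv.mean())
        theta0 = np.zeros(self.n_par)
        theta0[: self.n_lam][self.is_diag] = np.log(max(sd0, 1e-4))
        theta0[self.n_lam :] = rho0
        return theta0


def fit_lmm(
    stats: GroupStats,
    psi_mask: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    *,
    zero_psi: bool = False,
    max_restarts: int = 3,
    track_objective: bool = False,
    gtol: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> LMMFit:
    """REML fit; quasi-Newton (L-BFGS-B) with jittered restarts on failure.

    ``theta0`` warm-starts the optimizer (used heavily by the bootstrap).
    ``track_objective`` records the objective at each accepted iterate,
    which is monotone non-increasing for the line-searched quasi-Newton
    steps.  The convergence flag requires the final gradient sup-norm below
    1e-4 (the optimizer itself targets ``gtol``); failures return the best
    point found, flagged, with no silent fallback.
    """
    prob = _REMLProblem(stats, psi_mask, zero_psi=zero_psi)
    q = stats.q
    bounds = [(-12.0, 4.0) if d else (-8.0, 8.0) for d in prob.is_diag]
    bounds += [(-18.0, 6.0)] * stats.T
    base = prob.start() if theta0 is None else np.asarray(theta0, dtype=float).copy()
    base = np.clip(base, [b[0] for b in bounds], [b[1] for b in bounds])
    rng = rng or np.random.default_rng(0)

    best = None
    for attempt in range(max_restarts + 1):
        x0 = base if attempt == 0 else base + rng.normal(0.0, 0.4, size=len(base))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        traj: list[float] = []
        cb = (lambda xk: traj.append(prob.obj_grad(xk)[0])) if track_objective else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                prob.obj_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                callback=cb,
                options={"maxiter": 800, "ftol": 1e-13, "gtol": gtol, "maxcor": 25},
            )
        ginf = float(np.max(np.abs(res.jac)))
        ok = bool(res.success or ginf < 1e-4)
        if best is None or res.fun < best[0].fun - 1e-9:
            best = (res, ginf, ok, traj)
        if ok:
            best = (res, ginf, ok, traj)
            break

    res, ginf, ok, traj = best
    lam = prob.lam_of(res.x)
    psi = lam @ lam.T
    sigma2 = np.exp(res.x[prob.n_lam :])
    beta, cov = prob.beta_cov(res.x)
    se = np.sqrt(np.diag(cov))
    if stats.x_scale is not None:
        beta = beta / stats.x_scale
        se = se / stats.x_scale
    df = stats.n_rows - stats.p
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    singular = bool(not zero_psi and np.min(np.abs(np.diag(lam))) < 1e-5)
    if singular:
        warnings.warn(
            "random-effect covariance is at (or near) a singular boundary",
            stacklevel=2,
        )
    return LMMFit(
        beta=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        df_resid=df,
        psi=psi,
        sigma2=sigma2,
        lam=lam,
        theta=np.asarray(res.x, dtype=float),
        reml_neg2=float(res.fun),
        converged=ok,
        grad_inf=ginf,
        n_iter=int(res.nit),
        x_names=stats.x_names,
        u_names=stats.u_names,
        objective_trajectory=traj,
        singular_psi=singular,
    )
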