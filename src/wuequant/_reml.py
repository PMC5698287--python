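"""Dense multivariate REML engine for two-way genotype x environment trials.

Model (per trait, possibly several traits jointly)::

    y_ijk = mu + E_j + G_i + GE_ij + eps_ijk

with environment fixed and genotype, genotype-x-environment and residual
random.  For m traits the three random strata carry unstructured m x m
covariance matrices ``Sigma_g``, ``Sigma_ge``, ``Sigma_e``; observations are
stacked trait-major so the marginal covariance is::

    V = Sigma_g (x) Z_g Z_g' + Sigma_ge (x) Z_ge Z_ge' + Sigma_e (x) I_N

The restricted likelihood is maximised by Fisher scoring on the expected
information, with monotone EM fallback steps whenever a scoring proposal
leaves the positive-semidefinite cone or decreases the restricted
log-likelihood.  EM steps can never decrease it, which is asserted.

Everything is dense; the trials this targets have a few hundred plants, so
the (mN)^3 Cholesky per iteration is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MvRemlFit", "fit_mv_reml", "moment_start"]

# relative floor on stratum variances, as a fraction of phenotypic variance
FLOOR_FRAC = 1e-12
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MvRemlFit:
    """Converged REML solution for one or more traits."""

    sigma: dict[str, np.ndarray]        # stratum -> m x m covariance block
    loglik: float                       # restricted log-likelihood (with constant)
    converged: bool
    n_iter: int
    param_index: list[tuple[str, int, int]]  # vech order of asy_cov rows
    asy_cov: np.ndarray                 # inverse expected information
    beta: np.ndarray                    # GLS fixed effects, trait-major
    beta_cov: np.ndarray
    blup: dict[str, np.ndarray]         # stratum -> q x m predicted effects
    degenerate: bool = False
    n_em_steps: int = 0
    floor: float = 0.0
    trace: list[float] = field(default_factory=list)

    @property
    def m(self) -> int:
        return next(iter(self.sigma.values())).shape[0]


class _State:
    """Quantities derived from one evaluation of the restricted likelihood."""

    __slots__ = ("sigmas", "loglik", "P", "p", "G", "T", "U", "Viy", "XtViX_cf")

    def __init__(self, sigmas, loglik, P, p, G, T, U, Viy, XtViX_cf):
        self.sigmas = sigmas
        self.loglik = loglik
        self.P = P
        self.p = p
        self.G = G
        self.T = T
        self.U = U
        self.Viy = Viy
        self.XtViX_cf = XtViX_cf


def _vech_pairs(m: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(m) for b in range(a, m)]


def _psd_project(S: np.ndarray, floor: float) -> np.ndarray:
    """Clamp eigenvalues at `floor`, keeping the matrix symmetric."""
    S = 0.5 * (S + S.T)
    if S.shape[0] == 1:
        return np.array([[max(S[0, 0], floor)]])
    w, Q = np.linalg.eigh(S)
    return (Q * np.maximum(w, floor)) @ Q.T


def _evaluate(y, Xf, Klist, sigmas, m, N):
    """Build V, the REML projection P, and the per-stratum score ingredients."""
    mN = m * N
    V = np.zeros((mN, mN))
    for Sig, K in zip(sigmas, Klist):
        V += np.kron(Sig, K)
    cf = cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = cho_solve(cf, np.eye(mN), check_finite=False)
    ViX = Vinv @ Xf
    XtViX = Xf.T @ ViX
    cfx = cho_factor(XtViX, lower=True, check_finite=False)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    P = Vinv - ViX @ cho_solve(cfx, ViX.T, check_finite=False)
    p = P @ y
    ll = -0.5 * (logdet_v + logdet_x + y @ p + (mN - Xf.shape[1]) * _LOG2PI)
    n_strata = len(Klist)
    return _State(sigmas, ll, P, p, [None] * n_strata, [None] * n_strata,
                  [None] * n_strata, Vinv @ y, cfx)


def _stratum_terms(state, Zlist, m, N):
    """Fill U (Z' P y per trait), G (quadratic forms) and T (traces)."""
    p = state.p
    P = state.P
    p_blocks = [p[a * N:(a + 1) * N] for a in range(m)]
    for s, Z in enumerate(Zlist):
        if Z is None:  # residual stratum, Z = I
            U = np.stack(p_blocks)                      # m x N
            T = np.array([[np.trace(P[a * N:(a + 1) * N, b * N:(b + 1) * N])
                           for b in range(m)] for a in range(m)])
        else:
            U = np.stack([Z.T @ pb for pb in p_blocks])  # m x q
            T = np.empty((m, m))
            for a in range(m):
                for b in range(a, m):
                    Pab = P[a * N:(a + 1) * N, b * N:(b + 1) * N]
                    T[a, b] = T[b, a] = np.sum((Z.T @ Pab) * Z.T)
        state.U[s] = U
        state.G[s] = U @ U.T
        state.T[s] = T


def _score_vector(state, pairs, n_strata):
    s_vec = []
    for s in range(n_strata):
        D = state.G[s] - state.T[s]
        for (a, b) in pairs:
            s_vec.append(0.5 * D[a, b] * (1.0 if a == b else 2.0))
    return np.array(s_vec)


def _information(state, Zlist, pairs, m, N):
    """Expected information 0.5 tr(P V_i P V_j) over all vech parameters."""
    n_strata = len(Zlist)
    P = state.P

    # C[s][s2][a][b] = Z_s' P_ab Z_s2   (residual stratum uses Z = I)
    ZtP = []  # per stratum: list over (a, b) of Z_s' P_ab
    for s, Z in enumerate(Zlist):
        rows = {}
        for a in range(m):
            for b in range(m):
                Pab = P[a * N:(a + 1) * N, b * N:(b + 1) * N]
                rows[(a, b)] = Pab if Z is None else Z.T @ Pab
        ZtP.append(rows)
    C = {}
    for s in range(n_strata):
        for s2 in range(n_strata):
            blocks = {}
            Z2 = Zlist[s2]
            for key, M in ZtP[s].items():
                blocks[key] = M if Z2 is None else M @ Z2
            C[(s, s2)] = blocks

    npar = n_strata * len(pairs)
    info = np.zeros((npar, npar))
    basis = []
    for s in range(n_strata):
        for (a, b) in pairs:
            A = np.zeros((m, m))
            A[a, b] = A[b, a] = 1.0
            basis.append((s, A))
    for i, (s, A) in enumerate(basis):
        for j, (s2, B) in enumerate(basis):
            if j < i:
                continue
            blocks = C[(s, s2)]
            tot = 0.0
            # tr(P (A x K_s) P (B x K_s2)) =
            #   sum_{a,b,c,d} A[c,b] B[d,a] <C[b,d], C[c,a]>_F
            for a in range(m):
                for b in range(m):
                    for c in range(m):
                        if A[c, b] == 0.0:
                            continue
                        for d in range(m):
                            if B[d, a] == 0.0:
                                continue
                            tot += A[c, b] * B[d, a] * np.sum(
                                blocks[(b, d)] * blocks[(c, a)])
            info[i, j] = info[j, i] = 0.5 * tot
    return info


def _em_step(state, qlist, floor, n_strata):
    new = []
    for s in range(n_strata):
        Sig = state.sigmas[s]
        D = state.G[s] - state.T[s]
        cand = Sig + (Sig @ D @ Sig) / qlist[s]
        new.append(_psd_project(cand, floor))
    return new


def moment_start(Y, g_idx, e_idx, floor):
    """Balanced-ANOVA mean cross-product start values (MANOVA estimators).

    Returns ``None`` when the design is not balanced, in which case the
    caller falls back to an equal split of the phenotypic covariance.
    """
    N, m = Y.shape
    g_lv, g_code = np.unique(g_idx, return_inverse=True)
    e_lv, e_code = np.unique(e_idx, return_inverse=True)
    g, t = len(g_lv), len(e_lv)
    cell = g_code * t + e_code
    counts = np.bincount(cell, minlength=g * t)
    if counts.min() != counts.max() or counts.min() < 2:
        return None
    r = int(counts[0])

    cell_mean = np.zeros((g * t, m))
    for a in range(m):
        cell_mean[:, a] = np.bincount(cell, weights=Y[:, a]) / r
    gm = cell_mean.reshape(g, t, m)
    g_mean = gm.mean(axis=1)                 # g x m
    e_mean = gm.mean(axis=0)                 # t x m
    grand = g_mean.mean(axis=0)

    resid = Y - cell_mean[cell]
    M_err = resid.T @ resid / (g * t * (r - 1))
    inter = gm - g_mean[:, None, :] - e_mean[None, :, :] + grand
    M_ge = r * np.einsum("ijk,ijl->kl", inter, inter) / ((g - 1) * (t - 1))
    dev_g = g_mean - grand
    M_g = r * t * (dev_g.T @ dev_g) / (g - 1)

    Sig_e = _psd_project(M_err, floor)
    Sig_ge = _psd_project((M_ge - M_err) / r, floor)
    Sig_g = _psd_project((M_g - M_ge) / (r * t), floor)
    return [Sig_g, Sig_ge, Sig_e]


def fit_mv_reml(
    Y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    stratum_names: tuple[str, ...] = ("genotype", "gxe"),
    *,
    max_iter: int = 2000,
    rtol: float = 1e-8,
    init: str = "equal",
    g_idx: np.ndarray | None = None,
    e_idx: np.ndarray | None = None,
) -> MvRemlFit:
    """Maximise the restricted likelihood of the multi-stratum model.

    Parameters
    ----------
    Y
        N x m matrix of trait values (one column per trait).
    X
        N x p fixed-effect design (environment cell means).
    Z_list
        Incidence matrices of the random strata, residual excluded.
    stratum_names
        Names matching ``Z_list``; the residual stratum is appended as
        ``"residual"``.
    init
        ``"equal"`` splits the phenotypic covariance equally over strata;
        ``"moment"`` starts from the balanced-ANOVA (MANOVA) estimators when
        the design is balanced.  Both reach the same optimum; ``"moment"``
        just saves iterations on balanced data.
    g_idx, e_idx
        Genotype / environment codes per row, required for ``init="moment"``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    N, m = Y.shape
    y = Y.T.ravel()  # trait-major stacking
    Xf = np.kron(np.eye(m), np.asarray(X, dtype=float))
    names = list(stratum_names) + ["residual"]
    n_strata = len(names)
    Zs = [np.asarray(Z, dtype=float) for Z in Z_list] + [None]
    Klist = [Z @ Z.T for Z in Z_list] + [np.eye(N)]
    qlist = [Z.shape[1] for Z in Z_list] + [N]
    pairs = _vech_pairs(m)
    param_index = [(names[s], a, b) for s in range(n_strata) for (a, b) in pairs]

    var_p = np.var(Y, axis=0, ddof=1)
    scale = float(np.max(var_p)) if np.max(var_p) > 0 else 1.0
    floor = FLOOR_FRAC * scale

    if np.max(var_p) <= 0.0:
        # constant data: boundary solution, no likelihood surface to climb
        zero = np.full((m, m), 0.0)
        sig = {nm: zero.copy() for nm in names}
        sig["residual"] = np.eye(m) * floor
        npar = n_strata * len(pairs)
        return MvRemlFit(
            sigma=sig, loglik=np.nan, converged=True, n_iter=0,
            param_index=param_index, asy_cov=np.zeros((npar, npar)),
            beta=np.linalg.lstsq(Xf, y, rcond=None)[0],
            beta_cov=np.zeros((Xf.shape[1], Xf.shape[1])),
            blup={nm: np.zeros((q, m)) for nm, q in zip(names, qlist)},
            degenerate=True, floor=floor)

    S_p = np.atleast_2d(np.cov(Y.T))
    start = None
    if init == "moment":
        if g_idx is None or e_idx is None:
            raise ValueError("moment init requires g_idx and e_idx")
        start = moment_start(Y, g_idx, e_idx, floor)
    if start is None:
        start = [_psd_project(S_p / n_strata, floor) for _ in range(n_strata)]

    diag_pos = [s * len(pairs) + i for s in range(n_strata)
                for i, (a, b) in enumerate(pairs) if a == b]

    def _unpack(theta):
        cand = []
        k = 0
        for s in range(n_strata):
            S_new = np.zeros((m, m))
            for (a, b) in pairs:
                S_new[a, b] = S_new[b, a] = theta[k]
                k += 1
            cand.append(_psd_project(S_new, floor))
        return cand

    state = _evaluate(y, Xf, Klist, start, m, N)
    _stratum_terms(state, Zs, m, N)
    trace = [state.loglik]
    n_em = 0
    converged = False
    it = 0
    scoring_fails = 0
    grow_ok = True
    for it in range(1, max_iter + 1):
        new_state = None
        # after repeated rejections (an EM crawl against the PSD boundary)
        # only re-try scoring occasionally — the proposals keep failing and
        # the information matrix is the expensive part of an iteration
        try_scoring = scoring_fails < 3 or it % 10 == 0
        theta = np.concatenate([
            [state.sigmas[s][a, b] for (a, b) in pairs]
            for s in range(n_strata)])
        if try_scoring:
            score = _score_vector(state, pairs, n_strata)
            info = _information(state, Zs, pairs, m, N)
            # active set: variance parameters pinned at the floor whose
            # score pushes them further down stay fixed
            active = [k for k in diag_pos
                      if theta[k] <= floor * 4 and score[k] < 0.0]
            free = np.array([k for k in range(len(theta)) if k not in active],
                            dtype=int)
            step = np.zeros_like(theta)
            if free.size:
                sub_info = info[np.ix_(free, free)]
                try:
                    step[free] = np.linalg.solve(sub_info, score[free])
                except np.linalg.LinAlgError:
                    step[free] = np.linalg.lstsq(sub_info, score[free],
                                                 rcond=None)[0]
            if np.any(step):
                # damped scoring: halve the step until the (projected)
                # proposal improves the restricted likelihood
                for damp in (1.0, 0.5, 0.25, 0.125):
                    st2 = _evaluate(y, Xf, Klist,
                                    _unpack(theta + damp * step), m, N)
                    if (np.isfinite(st2.loglik)
                            and st2.loglik >= state.loglik
                            - 1e-10 * (abs(state.loglik) + 1.0)):
                        _stratum_terms(st2, Zs, m, N)
                        new_state = st2
                        break
            scoring_fails = 0 if new_state is not None else scoring_fails + 1
        if new_state is None:
            # EM fallback with a line search along the EM direction: halve
            # toward the current point when the projected full step fails
            # (the monotonicity guarantee only covers the unprojected
            # step), and over-relax (double) while the likelihood keeps
            # improving — plain EM crawls with a near-unit rate against a
            # rank-deficiency boundary, and step expansion breaks the crawl
            em_cand = _em_step(state, qlist, floor, n_strata)

            def em_eval(alpha):
                cand = [_psd_project(
                    (1 - alpha) * state.sigmas[s] + alpha * em_cand[s],
                    floor) for s in range(n_strata)]
                return _evaluate(y, Xf, Klist, cand, m, N)

            alpha, best = 1.0, None
            while alpha >= 1e-4:
                st3 = em_eval(alpha)
                if (np.isfinite(st3.loglik) and st3.loglik >= state.loglik
                        - 1e-12 * (abs(state.loglik) + 1.0)):
                    best = st3
                    break
                alpha *= 0.5
            # over-relaxation probes are gated on their own recent success:
            # against a PSD-cone boundary they fail systematically and
            # would double the cost of every crawl iteration
            if best is not None and alpha == 1.0 and (grow_ok or it % 20 == 0):
                grow = 2.0
                grew = False
                while grow <= 32.0:
                    st4 = em_eval(grow)
                    if np.isfinite(st4.loglik) and st4.loglik > best.loglik:
                        best = st4
                        grew = True
                        grow *= 2.0
                    else:
                        break
                grow_ok = grew
            if best is not None:
                _stratum_terms(best, Zs, m, N)
                new_state = best
                n_em += 1
            else:
                # no ascent direction left: constrained boundary optimum
                converged = True
                break
        delta = abs(new_state.loglik - state.loglik)
        state = new_state
        trace.append(state.loglik)
        if delta < rtol * (abs(state.loglik) + 1.0):
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations; "
            f"last loglik {state.loglik:.6g}, trace tail {trace[-5:]}")

    info = _information(state, Zs, pairs, m, N)
    asy_cov = np.linalg.pinv(info, hermitian=True)

    XtViy = Xf.T @ state.Viy
    beta = cho_solve(state.XtViX_cf, XtViy, check_finite=False)
    beta_cov = cho_solve(state.XtViX_cf, np.eye(Xf.shape[1]), check_finite=False)

    blup = {}
    for s, nm in enumerate(names):
        U = state.U[s]                        # m x q
        blup[nm] = (state.sigmas[s] @ U).T    # q x m
    sig = {nm: state.sigmas[s].copy() for s, nm in enumerate(names)}
    return MvRemlFit(
        sigma=sig, loglik=float(state.loglik), converged=True, n_iter=it,
        param_index=param_index, asy_cov=asy_cov, beta=beta,
        beta_cov=beta_cov, blup=blup, degenerate=False, n_em_steps=n_em,
        floor=floor, trace=trace)
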