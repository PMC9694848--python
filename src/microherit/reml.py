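"""Restricted maximum likelihood machinery for multi-trait animal models.

The model for T traits recorded once on each of n animals is

    y_t = X_t b_t + a_t + e_t,   a ~ N(0, A (x) P),   e ~ N(0, I (x) R),

with P and R the T x T genetic and residual covariance matrices and A
the relationship matrix among the phenotyped animals.  Because every
animal carries one record per trait, the REML likelihood depends on A
only through its phenotyped block, and a single symmetric
eigendecomposition A = U diag(d) U' rotates the system into n
independent T x T blocks with covariance d_m P + R.  All EM and
average-information (AI) quantities are then O(n T^3) per iteration,
which makes permutation refits and Monte-Carlo replicates cheap.

EM updates are the exact conditional-expectation (ECM) form, so the
REML log-likelihood is non-decreasing along the EM path; AI steps are
Newton-type with step-halving and an EM fallback whenever a step
leaves the positive-definite cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultiTraitREML", "VarianceComponents", "MMESolution", "solve_mme"]

_PSD_FLOOR = 1e-8


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    """Genetic (P) and residual (R) covariance estimates with SEs.

    ``cov_params`` is the inverse average-information matrix over the
    stacked parameter vector (vech P, vech R) in the order given by
    ``param_names``; it is the asymptotic covariance used for all
    delta-method standard errors.
    """

    P: np.ndarray
    R: np.ndarray
    cov_params: np.ndarray | None
    param_names: list[str]
    loglik: float
    converged: bool
    n_iterations: int
    message: str = ""
    loglik_path: list[float] = field(default_factory=list)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    @property
    def se(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(len(self.param_names), np.nan)
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))


def _vech_basis(T: int) -> list[tuple[str, int, int]]:
    basis = [("P", i, j) for i in range(T) for j in range(i, T)]
    basis += [("R", i, j) for i in range(T) for j in range(i, T)]
    return basis


def _pack(P: np.ndarray, R: np.ndarray, basis) -> np.ndarray:
    return np.array([(P if w == "P" else R)[i, j] for w, i, j in basis])


def _unpack(theta: np.ndarray, T: int, basis) -> tuple[np.ndarray, np.ndarray]:
    P = np.zeros((T, T))
    R = np.zeros((T, T))
    for val, (w, i, j) in zip(theta, basis):
        M = P if w == "P" else R
        M[i, j] = M[j, i] = val
    return P, R


def _project_psd(M: np.ndarray) -> np.ndarray:
    """Eigenvalue floor at _PSD_FLOOR x trace (parameter-space guard)."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    floor = _PSD_FLOOR * max(np.trace(M), _PSD_FLOOR)
    if w[0] >= floor:
        return M
    w = np.maximum(w, floor)
    return (V * w) @ V.T


class MultiTraitREML:
    """REML engine for one frame (Y, per-trait X) and one relationship.

    Parameters
    ----------
    Y : (n, T) responses, complete cases.
    Xs : list of (n, p_t) fixed-effect design matrices, full column rank.
    A : (n, n) relationship among the n phenotyped animals, or None if
        ``eig`` is given.
    eig : optional precomputed ``(d, U)`` eigendecomposition of A; pass
        this to share the decomposition across many refits (permutation
        tests, per-OTU scans).
    """

    def __init__(self, Y, Xs, A=None, eig=None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.n, self.T = Y.shape
        self.Xs = [np.atleast_2d(np.asarray(X, dtype=float)) for X in Xs]
        if len(self.Xs) != self.T:
            raise ValueError("need one design matrix per trait")
        for X in self.Xs:
            if X.shape[0] != self.n:
                raise ValueError("design rows must match records")
        if eig is None:
            if A is None:
                raise ValueError("supply A or its eigendecomposition")
            A = np.asarray(A, dtype=float)
            d, U = np.linalg.eigh(0.5 * (A + A.T))
            eig = (d, U)
        self.d, self.U = np.maximum(np.asarray(eig[0], float), 1e-10), eig[1]
        self.Ytil = self.U.T @ Y
        p_sizes = [X.shape[1] for X in self.Xs]
        self.p = int(np.sum(p_sizes))
        self.Xstack = np.zeros((self.n, self.T, self.p))
        off = 0
        self._offsets = []
        for t, X in enumerate(self.Xs):
            self.Xstack[:, t, off : off + X.shape[1]] = self.U.T @ X
            self._offsets.append((off, off + X.shape[1]))
            off += X.shape[1]
        self.basis = _vech_basis(self.T)
        self.df = self.n * self.T - self.p

    # -- permutation / scan support ------------------------------------
    def set_trait(self, t: int, y: np.ndarray) -> None:
        """Replace trait t's response (rotated internally)."""
        self.Ytil[:, t] = self.U.T @ np.asarray(y, dtype=float)

    # -- likelihood pieces ---------------------------------------------
    def _common(self, P, R):
        # quadratic forms go through reshaped BLAS products; the per-block
        # T x T work stays batched
        d = self.d
        n, T, p = self.n, self.T, self.p
        Sig = d[:, None, None] * P[None] + R[None]
        S = np.linalg.inv(Sig)
        SX = np.matmul(S, self.Xstack)
        Xf = self.Xstack.reshape(n * T, p)
        SXf = SX.reshape(n * T, p)
        XtSX = Xf.T @ SXf
        Sy = np.matmul(S, self.Ytil[:, :, None])[:, :, 0]
        XtSy = Xf.T @ Sy.reshape(n * T)
        try:
            F = np.linalg.inv(XtSX)
        except np.linalg.LinAlgError as exc:
            raise RemlError("singular fixed-effect GLS system") from exc
        b = F @ XtSy
        r = self.Ytil - (Xf @ b).reshape(n, T)
        w = np.matmul(S, r[:, :, None])[:, :, 0]
        sign1, ld1 = np.linalg.slogdet(Sig)
        sign2, ld2 = np.linalg.slogdet(XtSX)
        if np.any(sign1 <= 0) or sign2 <= 0:
            raise RemlError("non-positive-definite covariance in likelihood")
        yPy = float(np.sum(r * w))
        ll = -0.5 * (float(ld1.sum()) + float(ld2) + yPy)
        return {"S": S, "SX": SX, "F": F, "b": b, "r": r, "w": w, "loglik": ll}

    def loglik(self, P, R) -> float:
        return self._common(P, R)["loglik"]

    def gls(self, P, R):
        c = self._common(P, R)
        return c["b"], c["F"], c["loglik"]

    def _M(self, c):
        S, SX, F = c["S"], c["SX"], c["F"]
        n, T, p = self.n, self.T, self.p
        # F is PD (inverse of the GLS information); route the congruence
        # SX F SX' through its Cholesky factor and one BLAS product
        try:
            L = np.linalg.cholesky(0.5 * (F + F.T))
        except np.linalg.LinAlgError:
            return S - np.einsum("ntp,pq,nuq->ntu", SX, F, SX)
        B = (SX.reshape(n * T, p) @ L).reshape(n, T, p)
        return S - np.matmul(B, B.transpose(0, 2, 1))

    # -- EM -------------------------------------------------------------
    def em_step(self, P, R):
        c = self._common(P, R)
        w = c["w"]
        Q = np.einsum("nt,nu->ntu", w, w) - self._M(c)
        sum_dQ = np.einsum("n,ntu->tu", self.d, Q)
        sum_Q = Q.sum(axis=0)
        P_new = P + P @ sum_dQ @ P / self.n
        R_new = R + R @ sum_Q @ R / self.n
        return _project_psd(P_new), _project_psd(R_new), c["loglik"]

    def run_em(self, P0, R0, n_rounds: int = 100):
        """Exactly ``n_rounds`` EM updates; the REML log-likelihood must
        be non-decreasing along the path (checked every step)."""
        P, R = _project_psd(np.atleast_2d(P0)), _project_psd(np.atleast_2d(R0))
        path = []
        prev = -np.inf
        for it in range(n_rounds):
            P, R, ll = self.em_step(P, R)
            if not np.isfinite(ll):
                raise RemlError(f"non-finite REML log-likelihood at EM round {it}")
            if ll < prev - 1e-6 * (1.0 + abs(prev)):
                raise RemlError(
                    f"EM log-likelihood decreased at round {it}: {prev} -> {ll}"
                )
            path.append(ll)
            prev = ll
        return P, R, path

    # -- AI -------------------------------------------------------------
    def _score_ai(self, P, R, c):
        d, w = self.d, c["w"]
        M = self._M(c)
        trM_d = np.einsum("n,ntu->tu", d, M)
        trM_1 = M.sum(axis=0)
        ww_d = np.einsum("n,nt,nu->tu", d, w, w)
        ww_1 = np.einsum("nt,nu->tu", w, w)
        K = len(self.basis)
        score = np.zeros(K)
        Fk = np.zeros((K, self.n, self.T))
        for k, (which, i, j) in enumerate(self.basis):
            g = (trM_d - ww_d) if which == "P" else (trM_1 - ww_1)
            score[k] = -0.5 * g[i, j] if i == j else -g[i, j]
            mult = d if which == "P" else np.ones(self.n)
            Fk[k, :, i] += mult * w[:, j]
            if i != j:
                Fk[k, :, j] += mult * w[:, i]
        S, SX, F = c["S"], c["SX"], c["F"]
        n, T, p = self.n, self.T, self.p
        K = len(self.basis)
        Sf = np.matmul(S[None], Fk[:, :, :, None])[:, :, :, 0]
        Fkf = Fk.reshape(K, n * T)
        SXf = SX.reshape(n * T, p)
        XtSf = Fkf @ SXf  # (K, p)
        corr = (SXf @ (F @ XtSf.T)).T.reshape(K, n, T)
        PVf = Sf - corr
        AI = 0.5 * (Fkf @ PVf.reshape(K, n * T).T)
        return score, 0.5 * (AI + AI.T)

    def fit(
        self,
        P0,
        R0,
        em_rounds: int = 100,
        tol: float = 1e-10,
        max_iter: int = 100,
    ) -> VarianceComponents:
        """EM warm start followed by AI-REML to convergence.

        Convergence is declared when the relative change of the stacked
        parameter vector (vech P, vech R) drops below ``tol``.
        """
        T = self.T
        path: list[float] = []
        P, R = np.atleast_2d(np.asarray(P0, float)), np.atleast_2d(np.asarray(R0, float))
        if em_rounds > 0:
            P, R, path = self.run_em(P, R, em_rounds)
        theta = _pack(P, R, self.basis)
        converged = False
        message = ""
        n_iter = 0
        ll = self.loglik(P, R)
        best = (P, R, ll)
        score = ai = None
        n_rough = 0  # AI steps not accepted at full scale
        for it in range(max_iter):
            n_iter = it + 1
            c = self._common(P, R)
            ll = c["loglik"]
            path.append(ll)
            if ll > best[2]:
                best = (P, R, ll)
            score, ai = self._score_ai(P, R, c)
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                step = np.linalg.pinv(ai) @ score
            accepted = False
            scale = 1.0
            for _ in range(6):
                theta_new = theta + scale * step
                P_new, R_new = _unpack(theta_new, T, self.basis)
                P_new, R_new = _project_psd(P_new), _project_psd(R_new)
                try:
                    ll_new = self.loglik(P_new, R_new)
                except RemlError:
                    scale *= 0.5
                    continue
                # AI steps need not be monotone near a boundary; only a
                # severe likelihood drop triggers halving / EM fallback
                if np.isfinite(ll_new) and ll_new >= ll - max(2.0, 1e-4 * abs(ll)):
                    accepted = True
                    break
                scale *= 0.5
            if not accepted:
                P_new, R_new, ll_new = self.em_step(P, R)
            if not accepted or scale < 1.0:
                n_rough += 1
            theta_new = _pack(P_new, R_new, self.basis)
            rel = np.linalg.norm(theta_new - theta) / (np.linalg.norm(theta) + 1e-30)
            theta, P, R = theta_new, P_new, R_new
            if rel < tol:
                converged = True
                break
            if n_rough >= 3:
                # repeated rejected/halved AI steps: oscillatory surface,
                # hand over to the monotone EM finish below
                break
        if not converged:
            # oscillatory AI trajectories arise at boundary optima
            # (singular P); restart from the best state seen and let the
            # monotone EM map settle there
            P, R, _ = best
            em_tol = max(tol, 1e-7)
            prev_ll = -np.inf
            for it2 in range(300):
                theta_old = _pack(P, R, self.basis)
                P, R, ll_cur = self.em_step(P, R)
                n_iter += 1
                rel = np.linalg.norm(_pack(P, R, self.basis) - theta_old) / (
                    np.linalg.norm(theta_old) + 1e-30
                )
                if rel < em_tol or abs(ll_cur - prev_ll) < 1e-12 * (1 + abs(ll_cur)):
                    converged = True
                    message = (
                        "AI oscillated (likely boundary optimum); finished "
                        f"with monotone EM at tolerance {em_tol:g}"
                    )
                    break
                prev_ll = ll_cur
            theta = _pack(P, R, self.basis)
        if not converged:
            message = f"max_iter={max_iter} reached (last relative change above tol)"
        try:
            score, ai = self._score_ai(P, R, self._common(P, R))
        except RemlError:
            pass
        cov = None
        if ai is not None:
            # scale-free conditioning test (trait variances may differ by
            # orders of magnitude; only correlation-level collinearity
            # signals non-identifiability)
            dg = np.sqrt(np.abs(np.diag(ai)))
            dg[dg == 0] = 1.0
            cond = np.linalg.cond(ai / np.outer(dg, dg))
            if cond > 1e10:
                converged = False
                message = (
                    "average-information matrix ill-conditioned "
                    f"(cond={cond:.2e}); variance components not separately "
                    "identifiable"
                )
                cov = np.linalg.pinv(ai)
            else:
                cov = np.linalg.inv(ai)
        names = [f"{w}[{i},{j}]" for w, i, j in self.basis]
        return VarianceComponents(
            P=P,
            R=R,
            cov_params=cov,
            param_names=names,
            loglik=float(self.loglik(P, R)),
            converged=converged,
            n_iterations=n_iter,
            message=message,
            loglik_path=path,
        )


# ---------------------------------------------------------------------------
# Dense Henderson mixed-model equations
# ---------------------------------------------------------------------------


@dataclass
class MMESolution:
    """Solutions of Henderson's MME and the inverse coefficient matrix.

    ``u`` is (q, T): one column of breeding values per trait over the q
    animals of the relationship matrix.  ``Cinv`` is the full inverse
    coefficient matrix; its random-effect diagonal blocks are the
    prediction-error covariances of the breeding values.
    """

    b: np.ndarray
    u: np.ndarray
    Cinv: np.ndarray
    p: int
    q: int
    T: int

    def pev_block(self, t1: int = 0, t2: int | None = None) -> np.ndarray:
        t2 = t1 if t2 is None else t2
        i0 = self.p + t1 * self.q
        j0 = self.p + t2 * self.q
        return self.Cinv[i0 : i0 + self.q, j0 : j0 + self.q]


def solve_mme(
    Y,
    Xs,
    animal_index,
    Kinv,
    P,
    R,
) -> MMESolution:
    """Solve the multi-trait mixed-model equations directly (dense).

    Parameters
    ----------
    Y : (n, T) responses.
    Xs : per-trait fixed-effect designs, (n, p_t).
    animal_index : (n,) integer positions mapping each record to one of
        the q animals covered by ``Kinv``.
    Kinv : (q, q) inverse relationship matrix (A or H).
    P, R : genetic and residual covariance matrices (T x T), positive
        definite.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, T = Y.shape
    Xs = [np.atleast_2d(np.asarray(X, float)) for X in Xs]
    idx = np.asarray(animal_index, int)
    q = Kinv.shape[0]
    P = np.atleast_2d(np.asarray(P, float))
    R = np.atleast_2d(np.asarray(R, float))
    Rinv = np.linalg.inv(R)
    Pinv = np.linalg.inv(P)
    p_sizes = [X.shape[1] for X in Xs]
    p = int(np.sum(p_sizes))
    offs = np.concatenate([[0], np.cumsum(p_sizes)])
    W = np.zeros((n, q))
    W[np.arange(n), idx] = 1.0
    dim = p + T * q
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    WtW = W.T @ W
    for t in range(T):
        Xt = Xs[t]
        for u_ in range(T):
            Xu = Xs[u_]
            C[offs[t] : offs[t + 1], offs[u_] : offs[u_ + 1]] = Rinv[t, u_] * (Xt.T @ Xu)
            C[offs[t] : offs[t + 1], p + u_ * q : p + (u_ + 1) * q] = Rinv[t, u_] * (
                Xt.T @ W
            )
            C[p + t * q : p + (t + 1) * q, offs[u_] : offs[u_ + 1]] = Rinv[t, u_] * (
                W.T @ Xu
            )
            C[p + t * q : p + (t + 1) * q, p + u_ * q : p + (u_ + 1) * q] = (
                Rinv[t, u_] * WtW + Pinv[t, u_] * Kinv
            )
        rhs[offs[t] : offs[t + 1]] = Xt.T @ (Y @ Rinv[:, t])
        rhs[p + t * q : p + (t + 1) * q] = W.T @ (Y @ Rinv[:, t])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise RemlError("singular mixed-model coefficient matrix") from exc
    sol = Cinv @ rhs
    b = sol[:p]
    u = sol[p:].reshape(T, q).T
    return MMESolution(b=b, u=u, Cinv=Cinv, p=p, q=q, T=T)
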