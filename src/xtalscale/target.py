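"""Least-squares scaling target and its minimizers.

The target is

    Phi = sum_hl w_hl (I_hl - g_hl <I_h>)^2 + sum_i c_i (p_i - p0_i)^2

where ``<I_h>`` is the best least-squares estimate of the true intensity of
symmetry-unique reflection h,

    <I_h> = sum_l w_hl g_hl I_hl / sum_l w_hl g_hl^2,

re-evaluated at every objective evaluation (so Phi is a function of the
model parameters only; its gradient is exact by the envelope theorem), and
the second term collects the per-parameter restraints.  In reference mode
``<I_h>`` is fixed to externally supplied values.

Two minimization stages are provided: a quasi-Newton stage (L-BFGS) for the
bulk of the optimization, and a Levenberg-Marquardt full-matrix stage whose
normal-matrix inverse at convergence supplies the parameter covariance used
for uncertainty propagation.  Within the full-matrix stage the Jacobian
treats ``<I_h>`` as fixed at its value from the current outer iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp


def best_estimates(group_id: np.ndarray, g: np.ndarray, I: np.ndarray,
                   w: np.ndarray, n_groups: int | None = None) -> np.ndarray:
    """Best least-squares estimate <I_h> = sum(w g I)/sum(w g^2) per group.

    Groups with no observations get NaN.
    """
    group_id = np.asarray(group_id)
    if n_groups is None:
        n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    num = np.bincount(group_id, weights=w * g * I, minlength=n_groups)
    den = np.bincount(group_id, weights=w * g * g, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


@dataclass
class MinimizerResult:
    parameters: np.ndarray
    phi: float
    n_iter: int
    status: str                      # "converged" | "max_iter" | "degenerate"
    covariance: np.ndarray | None = None


class ScalingTarget:
    """The scaling least-squares target over a set of sweeps.

    Parameters
    ----------
    blocks : list of (model, table) pairs.  Each table must carry the
        normalized coordinates the model needs, a ``group_id`` column,
        working intensities in ``I_col`` and weights 1/``var_col``.
    n_groups : total number of symmetry groups (shared group_id space).
    reference : optional array of length n_groups with fixed <I_h> values
        (NaN where absent); observations in groups without a reference value
        are excluded from the data term but still receive scales.
    """

    def __init__(self, blocks, n_groups: int, I_col: str = "I_work",
                 var_col: str = "var_prime", reference: np.ndarray | None = None):
        self.blocks = [(model, table) for model, table in blocks]
        self.n_groups = n_groups
        self.caches = [model.prepare(table) for model, table in self.blocks]
        self.gid = np.concatenate(
            [t["group_id"].to_numpy() for _, t in self.blocks]) \
            if self.blocks else np.zeros(0, dtype=int)
        self.I = np.concatenate(
            [t[I_col].to_numpy(dtype=float) for _, t in self.blocks])
        var = np.concatenate(
            [t[var_col].to_numpy(dtype=float) for _, t in self.blocks])
        self.w = 1.0 / var
        self.reference = reference
        if reference is not None:
            ref_ok = np.isfinite(reference)
            self.in_target = ref_ok[self.gid]
        else:
            self.in_target = np.ones(len(self.gid), dtype=bool)
        # parameter layout
        self.offsets, off = [], 0
        for model, _ in self.blocks:
            self.offsets.append(off)
            off += model.n_params
        self.n_params = off
        cw, ct = [], []
        for model, _ in self.blocks:
            w_, t_ = model.restraints()
            cw.append(w_)
            ct.append(t_)
        self.restraint_w = np.concatenate(cw) if cw else np.zeros(0)
        self.restraint_t = np.concatenate(ct) if ct else np.zeros(0)

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> np.ndarray:
        return np.concatenate([m.parameters for m, _ in self.blocks])

    def set_parameters(self, x: np.ndarray) -> None:
        for (model, _), off in zip(self.blocks, self.offsets):
            model.parameters = x[off:off + model.n_params]

    # -- evaluation ---------------------------------------------------------
    def _scales(self, with_jacobian: bool = False):
        gs, js = [], []
        for (model, _), cache in zip(self.blocks, self.caches):
            if with_jacobian:
                g, J = model.inverse_scales(cache, with_jacobian=True)
                js.append(J)
            else:
                g = model.inverse_scales(cache)
            gs.append(g)
        g = np.concatenate(gs)
        if not with_jacobian:
            return g
        return g, sp.block_diag(js, format="csr")

    def ih_values(self, g: np.ndarray) -> np.ndarray:
        if self.reference is not None:
            return self.reference
        m = self.in_target
        return best_estimates(self.gid[m], g[m], self.I[m], self.w[m],
                              self.n_groups)

    def phi_and_gradient(self, x: np.ndarray):
        self.set_parameters(x)
        g, J = self._scales(with_jacobian=True)
        if np.any(~np.isfinite(g)) or np.any(g <= 0):
            return np.inf, np.zeros_like(x)
        Ih = self.ih_values(g)
        ih = np.where(np.isfinite(Ih[self.gid]), Ih[self.gid], 0.0)
        resid = np.where(self.in_target, self.I - g * ih, 0.0)
        phi = float(np.sum(self.w * resid ** 2))
        grad = np.asarray(
            J.T @ (-2.0 * self.w * resid * ih * self.in_target)).ravel()
        dp = x - self.restraint_t
        phi += float(np.sum(self.restraint_w * dp ** 2))
        grad += 2.0 * self.restraint_w * dp
        return phi, grad

    def phi(self, x: np.ndarray) -> float:
        return self.phi_and_gradient(x)[0]

    def residuals_and_jacobian(self, x: np.ndarray):
        """Weighted residual vector and Jacobian with <I_h> held fixed.

        Restraints are appended as extra residual rows, so the normal matrix
        (and hence the covariance) includes them.
        """
        self.set_parameters(x)
        g, J = self._scales(with_jacobian=True)
        Ih = self.ih_values(g)
        ih = np.where(np.isfinite(Ih[self.gid]), Ih[self.gid], 0.0)
        sw = np.sqrt(self.w) * self.in_target
        r = sw * (self.I - g * ih)
        bad = ~np.isfinite(r)
        if bad.any():
            import warnings
            warnings.warn(f"{int(bad.sum())} non-finite residual(s) excluded")
            r = np.where(bad, 0.0, r)
            sw = np.where(bad, 0.0, sw)
        Jr = sp.diags(-sw * ih) @ J
        rw = np.sqrt(self.restraint_w)
        r_restr = rw * (x - self.restraint_t)
        J_restr = sp.diags(rw)
        return (np.concatenate([r, r_restr]),
                sp.vstack([Jr, J_restr], format="csr"))


def minimize(target: ScalingTarget, stage: str = "quasi_newton",
             max_iter: int = 100, tol: float = 1e-6) -> MinimizerResult:
    """Minimize the scaling target.

    ``quasi_newton`` uses L-BFGS with the analytic gradient and reports no
    covariance; ``full_matrix`` runs a damped (Levenberg-Marquardt) normal-
    equations solve and reports the covariance as the inverse of the normal
    matrix at convergence.  Convergence: relative Phi change < ``tol``.
    """
    x0 = target.parameters
    if max_iter <= 0:
        return MinimizerResult(x0, target.phi(x0), 0, "converged")
    if stage == "quasi_newton":
        res = scipy.optimize.minimize(
            target.phi_and_gradient, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
        target.set_parameters(res.x)
        status = "converged" if res.success or res.status == 1 else "max_iter"
        return MinimizerResult(res.x, float(res.fun), int(res.nit), status)
    if stage != "full_matrix":
        raise ValueError(f"unknown minimization stage {stage!r}")
    x = x0.copy()
    phi = target.phi(x)
    lam = 1e-3
    status = "max_iter"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r, J = target.residuals_and_jacobian(x)
        A = (J.T @ J).toarray()
        gvec = np.asarray(J.T @ r).ravel()
        accepted = False
        diag = np.maximum(np.diag(A), 1e-12)
        for _ in range(20):
            M = A + lam * np.diag(diag)
            try:
                dx = np.linalg.solve(M, -gvec)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            phi_new = target.phi(x + dx)
            if np.isfinite(phi_new) and phi_new < phi:
                x = x + dx
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            status = "converged"
            break
        if (phi - phi_new) <= tol * max(abs(phi), 1e-300):
            phi = phi_new
            status = "converged"
            break
        phi = phi_new
    target.set_parameters(x)
    r, J = target.residuals_and_jacobian(x)
    A = (J.T @ J).toarray()
    phi = target.phi(x)
    evals = np.linalg.eigvalsh(A)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-300):
        import warnings
        warnings.warn("singular normal matrix: covariance omitted")
        cov = None
        status = "degenerate"
    else:
        cov = np.linalg.inv(A)
        # symmetrize against round-off
        cov = 0.5 * (cov + cov.T)
    return MinimizerResult(x, float(phi), n_iter, status, covariance=cov)


def propagate_uncertainties(result: MinimizerResult, target: ScalingTarget):
    """Per-observation var(g) and adjusted sigma^2 of the scaled intensity.

    var_g = J_row Cov J_row^T; the variance of the corrected intensity I/g
    follows by first-order propagation assuming independent errors:
    sigma^2(I/g) = sigma'^2/g^2 + I^2 var_g / g^4.
    """
    target.set_parameters(result.parameters)
    g, J = target._scales(with_jacobian=True)
    if result.covariance is None:
        var_g = np.zeros_like(g)
    else:
        JC = J @ result.covariance
        var_g = np.asarray(sp.csr_matrix(JC).multiply(J).sum(axis=1)).ravel()
        var_g = np.maximum(var_g, 0.0)
    var_prime = 1.0 / target.w
    var_scaled = var_prime / g ** 2 + target.I ** 2 * var_g / g ** 4
    return g, var_g, var_scaled


def anchor_mean_scale(models: list) -> float:
    """Pin the overall scale gauge: rescale so the first model's scale
    component has mean parameter 1.  Returns the factor applied.

    The data term of Phi is invariant to g -> alpha*g with <I_h> -> <I_h>/alpha,
    so this fixes the indeterminacy without changing the fit.
    """
    first = models[0]
    comp = first.components.get("scale") or first.components.get("kb")
    if comp is None:
        return 1.0
    mean = comp.params[0] if comp.kind == "kb" else float(np.mean(comp.params))
    if mean <= 0 or not np.isfinite(mean):
        return 1.0
    for model in models:
        c = model.components.get("scale") or model.components.get("kb")
        if c is None:
            continue
        if c.kind == "kb":
            c.params[0] /= mean
        else:
            c.params /= mean
    return mean
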