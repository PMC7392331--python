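"""Sequential best-worst conditional logit (McFadden) with effects coding.

Model: within a task with item set S, the probability that item b is
chosen best is exp(u_b)/sum_{j in S} exp(u_j); the worst item w is then
chosen from S\\{b} with probability exp(-u_w)/sum_{j in S\\{b}} exp(-u_j).
Both stages share one utility vector u, so the log-likelihood is a
conditional logit over stacked groups where worst-stage utilities enter
with weight -1.

Identification uses effects coding: one item is omitted and represented
as -1 in every indicator column, constraining the J utilities to sum to
zero.  After fitting the J-1 free coefficients, the omitted item's
coefficient is recovered as the negative sum of the others, with
standard error sqrt(1' V 1) — the square root of the sum of the
variance-covariance matrix.

The likelihood is globally concave; a Newton iteration with the
analytic gradient and observed information converges in a handful of
steps, and the variance-covariance matrix is the inverse observed
information at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .data import ChoiceLong

GRAD_TOL = 1e-8
LL_RELTOL = 1e-10


class ConvergenceError(RuntimeError):
    pass


class SeparationWarning(UserWarning):
    """An item was always or never chosen; its estimate may diverge."""


@dataclass
class ClogitFit:
    """Fitted sequential conditional logit.

    ``table`` columns: item_id, label, estimate, se, z, p, rank,
    omitted_flag.  The J reported estimates (including the recovered
    omitted level) sum to zero by construction.  ``beta``/``vcov`` are
    the J-1 free coefficients and their covariance.
    """

    catalogue: "object"
    omitted: str
    beta: np.ndarray  # (J-1,) free coefficients, catalogue order minus omitted
    vcov: np.ndarray  # (J-1, J-1)
    table: pd.DataFrame
    loglik: float
    iterations: int
    grad_norm: float
    converged: bool
    separation_flag: bool = False

    def utilities(self) -> pd.Series:
        """All J estimates (omitted level recovered), catalogue order."""
        return self.table.set_index("item_id")["estimate"]


def _stage_ll_grad_info(
    util: np.ndarray,
    items: np.ndarray,
    chosen: np.ndarray,
    sign: float,
    J: int,
    want_derivs: bool,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Log-likelihood (and full-space gradient/information) of one stage."""
    U = sign * util[items]  # (G, m)
    lse = logsumexp(U, axis=1)
    rows = np.arange(len(items))
    ll = float((U[rows, chosen] - lse).sum())
    if not want_derivs:
        return ll, None, None
    P = np.exp(U - lse[:, None])
    resid = -P
    resid[rows, chosen] += 1.0
    g = np.zeros(J)
    np.add.at(g, items.ravel(), sign * resid.ravel())
    # information contribution: sum_g diag(p) - p p'
    block = -P[:, :, None] * P[:, None, :]
    m = items.shape[1]
    block[:, np.arange(m), np.arange(m)] += P
    F = np.zeros((J, J))
    np.add.at(
        F,
        (
            np.broadcast_to(items[:, :, None], block.shape).ravel(),
            np.broadcast_to(items[:, None, :], block.shape).ravel(),
        ),
        block.ravel(),
    )
    return ll, g, F


def sequential_loglik(
    long: ChoiceLong, utilities: np.ndarray
) -> float:
    """Sequential best-worst log-likelihood at a full J utility vector."""
    utilities = np.asarray(utilities, dtype=float)
    J = len(long.catalogue)
    ll_b, _, _ = _stage_ll_grad_info(
        utilities, long.best_items, long.best_chosen, +1.0, J, False
    )
    ll_w, _, _ = _stage_ll_grad_info(
        utilities, long.worst_items, long.worst_chosen, -1.0, J, False
    )
    return ll_b + ll_w


def _full_derivs(
    long: ChoiceLong, util: np.ndarray, J: int
) -> tuple[float, np.ndarray, np.ndarray]:
    ll_b, g_b, F_b = _stage_ll_grad_info(
        util, long.best_items, long.best_chosen, +1.0, J, True
    )
    ll_w, g_w, F_w = _stage_ll_grad_info(
        util, long.worst_items, long.worst_chosen, -1.0, J, True
    )
    return ll_b + ll_w, g_b + g_w, F_b + F_w


def _check_separation(long: ChoiceLong, J: int) -> bool:
    """True if some item is always chosen or never chosen when offered."""
    rows_b = np.arange(long.n_records)
    chosen = np.bincount(
        long.best_items[rows_b, long.best_chosen], minlength=J
    ) + np.bincount(
        long.worst_items[rows_b, long.worst_chosen], minlength=J
    )
    offered = np.bincount(long.best_items.ravel(), minlength=J) + np.bincount(
        long.worst_items.ravel(), minlength=J
    )
    return bool(np.any((chosen == 0) | (chosen == offered)))


def fit_sequential_clogit(
    long: ChoiceLong,
    omitted: str | None = None,
    max_iter: int = 200,
) -> ClogitFit:
    """Maximum-likelihood fit of the sequential best-worst logit.

    Parameters
    ----------
    long
        Stacked best/worst choice groups from
        :func:`bwspref.data.expand_to_choice_long`.
    omitted
        Item id of the effects-coded reference level; defaults to the
        last catalogue item.  Recovered estimates are invariant to this
        choice.
    """
    catalogue = long.catalogue
    J = len(catalogue)
    if omitted is None:
        omitted = catalogue.ids[-1]
    o = catalogue.index(omitted)
    keep = np.array([j for j in range(J) if j != o])

    if _check_separation(long, J):
        warnings.warn(
            "an item is always or never chosen when offered; estimates "
            "may be unbounded",
            SeparationWarning,
        )
        separated = True
    else:
        separated = False

    def reduce_vec(g_full: np.ndarray) -> np.ndarray:
        return g_full[keep] - g_full[o]

    def reduce_mat(F: np.ndarray) -> np.ndarray:
        return (
            F[np.ix_(keep, keep)]
            - F[keep, o][:, None]
            - F[o, keep][None, :]
            + F[o, o]
        )

    beta = np.zeros(J - 1)
    util = np.zeros(J)
    ll, g_full, F = _full_derivs(long, util, J)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        g = reduce_vec(g_full)
        H = reduce_mat(F)  # observed information (positive semi-definite)
        if np.max(np.abs(g)) < GRAD_TOL:
            converged = True
            iterations -= 1
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            util_c = np.empty(J)
            util_c[keep] = cand
            util_c[o] = -cand.sum()
            ll_c, g_full_c, F_c = _full_derivs(long, util_c, J)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        rel_change = abs(ll_c - ll) / max(1.0, abs(ll))
        beta, util, ll, g_full, F = cand, util_c, ll_c, g_full_c, F_c
        if np.max(np.abs(reduce_vec(g_full))) < GRAD_TOL or (
            rel_change < LL_RELTOL
        ):
            converged = True
            break
    grad_norm = float(np.max(np.abs(reduce_vec(g_full))))
    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(|grad|_max = {grad_norm:.3e}, loglik = {ll:.6f})"
        )
    H = reduce_mat(F)
    vcov = np.linalg.inv(H)
    vcov = (vcov + vcov.T) / 2

    beta_omit, se_omit = recover_omitted(beta, vcov)
    est = np.empty(J)
    est[keep] = beta
    est[o] = beta_omit
    se = np.empty(J)
    se[keep] = np.sqrt(np.diag(vcov))
    se[o] = se_omit
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    from .counts import _rank_desc

    table = pd.DataFrame(
        {
            "item_id": catalogue.ids,
            "label": catalogue.labels,
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "rank": _rank_desc(est),
            "omitted_flag": [j == o for j in range(J)],
        }
    )
    return ClogitFit(
        catalogue=catalogue,
        omitted=omitted,
        beta=beta,
        vcov=vcov,
        table=table,
        loglik=float(ll),
        iterations=iterations,
        grad_norm=grad_norm,
        converged=converged,
        separation_flag=separated,
    )


def recover_omitted(
    beta: np.ndarray, vcov: np.ndarray
) -> tuple[float, float]:
    """Recover the effects-coded omitted level.

    beta_omit = -sum(beta); SE_omit = sqrt(sum of the variance-
    covariance matrix), i.e. the delta-method SE of (-1)' beta.
    """
    beta = np.asarray(beta, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if vcov.shape != (len(beta), len(beta)):
        raise ValueError(
            f"vcov shape {vcov.shape} does not match beta length {len(beta)}"
        )
    if not np.allclose(vcov, vcov.T, atol=1e-8):
        raise ValueError("vcov must be symmetric")
    var = float(vcov.sum())
    if var < -1e-12:
        raise FloatingPointError(
            f"summed variance-covariance is negative ({var:.3e}); "
            f"condition number {np.linalg.cond(vcov):.3e}"
        )
    return float(-beta.sum()), float(np.sqrt(max(var, 0.0)))


def rank_items(fit: ClogitFit) -> pd.DataFrame:
    """Items ordered by estimate, rank 1 first (ties by catalogue order)."""
    return fit.table.sort_values("rank", ignore_index=True)
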