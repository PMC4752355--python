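"""MCMC engines for the random-coefficient panel GLMM.

Two family-specific samplers over the latent structure

    eta_it = x_it' beta + b_i + alpha_t(i) [+ e_it]

with iid Gaussian individual intercepts b_i ~ N(0, sigma_b^2), a random-walk
of order 1 for the monthly effect alpha (shared path or one path per
individual), and — for the Poisson family — iid Gaussian observation-level
effects e_it ~ N(0, sigma_e^2) realizing the overdispersion.

* Gaussian family: blocked Gibbs.  beta, b and alpha have conjugate Gaussian
  conditionals (alpha via a banded Cholesky of its tridiagonal precision);
  the three scale parameters get log-scale random-walk MH steps under
  half-Normal priors.
* Poisson family: Metropolis-within-Gibbs with every block vectorized.  The
  e-field and the b vector have conditionally independent sites; alpha is
  updated in an even/odd checkerboard over months (the RW1 prior is Markov,
  so sites of one colour are conditionally independent given the other);
  beta moves jointly with a preconditioned random walk whose covariance
  comes from a maximum-likelihood GLM fit.

Both samplers include a *step-translation* move that proposes shifting mass
between a designated period coefficient (e.g. the post-2009 step) and the
RW1 path: eta is left invariant, so the move is accepted on the prior ratio
alone.  Without it, the near-collinearity of a step indicator with a free
monthly path makes that coefficient mix arbitrarily slowly.

Identifiability: after every update of b or alpha the block is re-centered
and its mean absorbed into the intercept, which leaves eta untouched and
realizes the sum-to-zero constraint on each RW1 path.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

__all__ = ["run_gaussian", "run_poisson"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _halfnormal_logpdf(s, scale):
    return -0.5 * (s / scale) ** 2


def _rw1_increment_ss(alpha):
    d = np.diff(alpha, axis=-1)
    return float(np.sum(d * d))


class _ScaleSampler:
    """Log-scale random-walk MH for an sd parameter with a half-Normal prior."""

    def __init__(self, value, prior_scale=1.0, step=0.3):
        self.log_s = float(np.log(value))
        self.prior_scale = prior_scale
        self.step = step
        self.n_acc = 0
        self.n_try = 0

    @property
    def value(self):
        return float(np.exp(self.log_s))

    def update(self, rng, ss, n):
        """``ss`` = sum of squares of the n Gaussian variates with sd s."""
        prop = self.log_s + rng.normal(0.0, self.step)

        def logpost(ls):
            s = np.exp(ls)
            return (
                -n * ls
                - 0.5 * ss / (s * s)
                + _halfnormal_logpdf(s, self.prior_scale)
                + ls  # Jacobian of the log transform
            )

        self.n_try += 1
        if np.log(rng.random()) < logpost(prop) - logpost(self.log_s):
            self.log_s = prop
            self.n_acc += 1

    def adapt(self):
        if self.n_try >= 25:
            rate = self.n_acc / self.n_try
            self.step *= np.exp(0.5 * (rate - 0.44))
            self.step = float(np.clip(self.step, 1e-3, 3.0))
            self.n_acc = self.n_try = 0


class _AdaptiveScalar:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, step, target):
        self.step = step
        self.target = target
        self.n_acc = 0.0
        self.n_try = 0

    def register(self, acc_rate):
        self.n_acc += acc_rate
        self.n_try += 1

    def adapt(self):
        if self.n_try >= 25:
            rate = self.n_acc / self.n_try
            self.step *= np.exp(0.6 * (rate - self.target))
            self.step = float(np.clip(self.step, 1e-4, 10.0))
            self.n_acc = 0.0
            self.n_try = 0


def _checkerboard_masks(T):
    even = np.arange(0, T, 2)
    odd = np.arange(1, T, 2)
    return even, odd


def _rw1_conditional(alpha, color, sigma):
    """Mean and sd of alpha[color] given the other colour under the RW1 prior."""
    T = alpha.shape[-1]
    mean = np.empty(alpha[..., color].shape)
    var = np.empty(len(color))
    for j, t in enumerate(color):
        if t == 0:
            mean[..., j] = alpha[..., 1]
            var[j] = sigma * sigma
        elif t == T - 1:
            mean[..., j] = alpha[..., T - 2]
            var[j] = sigma * sigma
        else:
            mean[..., j] = 0.5 * (alpha[..., t - 1] + alpha[..., t + 1])
            var[j] = 0.5 * sigma * sigma
    return mean, np.sqrt(var)


# --------------------------------------------------------------------------
# Gaussian family (identity link, constant residual variance)
# --------------------------------------------------------------------------

def run_gaussian(data, priors, n_iter, warmup, thin, rng, start=None, translate_col=None,
                 translate_post_mask=None):
    """Blocked Gibbs for the Gaussian-family panel model.

    ``data`` is the dict produced by the model class: X, y, ind (codes),
    tt (month codes), n_ind, T, has_iid, has_rw1, rw1_by_individual.
    Returns a dict of stacked post-warmup draws.
    """
    X, y = data["X"], data["y"]
    ind, tt = data["ind"], data["tt"]
    N, p = X.shape
    n_ind, T = data["n_ind"], data["T"]
    has_iid, has_rw1 = data["has_iid"], data["has_rw1"]
    by_ind = data.get("rw1_by_individual", False)

    XtX = X.T @ X
    prior_prec_beta = np.eye(p) / priors.beta_sd**2

    beta = np.zeros(p) if start is None else start.copy()
    b = np.zeros(n_ind)
    alpha = np.zeros((n_ind, T)) if by_ind else np.zeros(T)
    sig = _ScaleSampler(max(np.std(y), 0.1), priors.sd_scale)
    sig_b = _ScaleSampler(0.1, priors.sd_scale)
    sig_a = _ScaleSampler(0.05, priors.sd_scale)

    counts_i = np.bincount(ind, minlength=n_ind).astype(float)
    counts_t = np.bincount(tt, minlength=T).astype(float)
    const_ix = data.get("const_ix")

    n_keep = (n_iter - warmup) // thin
    out = {
        "beta": np.empty((n_keep, p)),
        "sigma": np.empty(n_keep),
        "sigma_b": np.empty(n_keep),
        "sigma_alpha": np.empty(n_keep),
        "alpha": np.empty((n_keep, T)),
    }
    kept = 0

    # flat cell index for by-individual paths (each obs belongs to one cell)
    cell = ind * T + tt if by_ind else None

    for it in range(n_iter):
        s2 = sig.value**2
        a_of_row = alpha[ind, tt] if by_ind else alpha[tt]

        # beta | rest
        r = y - b[ind] - a_of_row
        prec = XtX / s2 + prior_prec_beta
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ r / s2)
        beta = mean + np.linalg.solve(L.T, rng.normal(size=p))
        eta_fix = X @ beta

        # b | rest
        if has_iid:
            sb2 = max(sig_b.value**2, 1e-12)
            resid = y - eta_fix - a_of_row
            prec_b = counts_i / s2 + 1.0 / sb2
            mean_b = np.bincount(ind, weights=resid, minlength=n_ind) / s2 / prec_b
            b = mean_b + rng.normal(size=n_ind) / np.sqrt(prec_b)
            if const_ix is not None:
                m = b.mean()
                b -= m
                beta[const_ix] += m
            sig_b.update(rng, float(b @ b), n_ind)
            sig_b.adapt()
            for j, v_i in data.get("ind_const", []):
                beta, b, _ = _ind_translate_move(
                    beta, b, j, v_i, const_ix, max(sig_b.value, 1e-4),
                    priors.beta_sd, rng, 0.5 * max(sig_b.value, 1e-3),
                )
            eta_fix = X @ beta
            # joint (sigma_b, b) rescale against the Gaussian likelihood
            a_row = alpha[ind, tt] if by_ind else alpha[tt]
            r = y - eta_fix - b[ind] - a_row
            s_old = max(sig_b.value, 1e-8)
            log_s_new = np.log(s_old) + rng.normal(0.0, 0.15)
            s_new = float(np.exp(log_s_new))
            d_row = b[ind] * (s_new / s_old - 1.0)
            dlog = float(
                (2.0 * r @ d_row - d_row @ d_row) / (2 * s2)
                + _halfnormal_logpdf(s_new, priors.sd_scale)
                - _halfnormal_logpdf(s_old, priors.sd_scale)
                + (log_s_new - np.log(s_old))
            )
            if np.log(rng.random()) < dlog:
                b = b * (s_new / s_old)
                sig_b.log_s = log_s_new

        # alpha | rest
        if has_rw1:
            sa2 = max(sig_a.value**2, 1e-12)
            resid = y - eta_fix - b[ind]
            if by_ind:
                alpha = _gibbs_rw1_by_individual(
                    resid, cell, n_ind, T, s2, sa2, rng
                )
                m = alpha.mean()
                alpha -= m
                n_inc = n_ind * (T - 1)
                ss = _rw1_increment_ss(alpha)
            else:
                alpha = _gibbs_rw1_shared(resid, tt, counts_t, T, s2, sa2, rng)
                m = alpha.mean()
                alpha -= m
                n_inc = T - 1
                ss = _rw1_increment_ss(alpha)
            if const_ix is not None:
                beta[const_ix] += m
                eta_fix = X @ beta
            sig_a.update(rng, ss, n_inc)
            sig_a.adapt()

            if translate_col is not None:
                for _ in range(3):
                    beta, alpha, _acc = _translate_move(
                        beta, alpha, translate_col, const_ix, translate_post_mask,
                        sig_a.value, priors.beta_sd, rng,
                    )
                eta_fix = X @ beta

            # joint (sigma_alpha, alpha) rescale against the likelihood
            a_row = alpha[ind, tt] if by_ind else alpha[tt]
            r = y - eta_fix - b[ind] - a_row
            s_old = max(sig_a.value, 1e-8)
            log_s_new = np.log(s_old) + rng.normal(0.0, 0.3)
            s_new = float(np.exp(log_s_new))
            d_row = a_row * (s_new / s_old - 1.0)
            dlog = float(
                (2.0 * r @ d_row - d_row @ d_row) / (2 * s2)
                + _halfnormal_logpdf(s_new, priors.sd_scale)
                - _halfnormal_logpdf(s_old, priors.sd_scale)
                + (log_s_new - np.log(s_old))
            )
            if np.log(rng.random()) < dlog:
                alpha = alpha * (s_new / s_old)
                sig_a.log_s = log_s_new

        # residual sd
        a_of_row = alpha[ind, tt] if by_ind else alpha[tt]
        resid = y - eta_fix - b[ind] - a_of_row
        sig.update(rng, float(resid @ resid), N)
        sig.adapt()

        if it >= warmup and (it - warmup) % thin == 0 and kept < n_keep:
            out["beta"][kept] = beta
            out["sigma"][kept] = sig.value
            out["sigma_b"][kept] = sig_b.value
            out["sigma_alpha"][kept] = sig_a.value
            out["alpha"][kept] = alpha.mean(axis=0) if by_ind else alpha
            kept += 1

    return out


def _gibbs_rw1_shared(resid, tt, counts_t, T, s2, sa2, rng):
    """Sample a shared RW1 path from its tridiagonal Gaussian conditional."""
    # precision = Q/sa2 + diag(counts_t)/s2, Q the RW1 structure matrix
    diag = np.full(T, 2.0) / sa2
    diag[0] = diag[-1] = 1.0 / sa2
    diag += counts_t / s2
    off = np.full(T - 1, -1.0 / sa2)
    rhs = np.bincount(tt, weights=resid, minlength=T) / s2
    ab = np.zeros((2, T))
    ab[0, 1:] = off
    ab[1] = diag
    # upper-banded Cholesky: precision = U' U
    U = sla.cholesky_banded(ab, lower=False)
    mean = sla.cho_solve_banded((U, False), rhs)
    # sample: solve U x = z  (banded back-substitution)
    z = rng.normal(size=T)
    x = sla.solve_banded((0, 1), U, z)
    return mean + x


def _gibbs_rw1_by_individual(resid, cell, n_ind, T, s2, sa2, rng):
    """Independent tridiagonal path draws per individual (vectorized Thomas)."""
    counts = np.bincount(cell, minlength=n_ind * T).reshape(n_ind, T)
    rhs = np.bincount(cell, weights=resid, minlength=n_ind * T).reshape(n_ind, T) / s2
    diag = np.full((n_ind, T), 2.0) / sa2
    diag[:, 0] = diag[:, -1] = 1.0 / sa2
    diag += counts / s2
    off = -1.0 / sa2
    # vectorized symmetric tridiagonal Cholesky across individuals
    d = np.empty((n_ind, T))
    l = np.empty((n_ind, T - 1))
    d[:, 0] = np.sqrt(diag[:, 0])
    for t in range(1, T):
        l[:, t - 1] = off / d[:, t - 1]
        d[:, t] = np.sqrt(diag[:, t] - l[:, t - 1] ** 2)
    # solve L w = rhs, then L' mean = w
    w = np.empty((n_ind, T))
    w[:, 0] = rhs[:, 0] / d[:, 0]
    for t in range(1, T):
        w[:, t] = (rhs[:, t] - l[:, t - 1] * w[:, t - 1]) / d[:, t]
    mean = np.empty((n_ind, T))
    z = rng.normal(size=(n_ind, T))
    mean[:, -1] = w[:, -1] / d[:, -1]
    x = np.empty((n_ind, T))
    x[:, -1] = z[:, -1] / d[:, -1]
    for t in range(T - 2, -1, -1):
        mean[:, t] = (w[:, t] - l[:, t] * mean[:, t + 1]) / d[:, t]
        x[:, t] = (z[:, t] - l[:, t] * x[:, t + 1]) / d[:, t]
    return mean + x


def _ind_translate_move(beta, b, col_ix, v_i, const_ix, sigma_b, beta_sd, rng, step):
    """Shift mass between an individual-constant coefficient and b.

    Proposes beta[col] += d, b_i -= d * v_i (v_i the column's per-individual
    value); eta is invariant so only the Gaussian priors enter.  Returns the
    possibly-updated (beta, b) and whether the move was accepted.
    """
    d = rng.normal(0.0, step)
    new_beta = beta.copy()
    new_beta[col_ix] += d
    new_b = b - d * v_i
    m = new_b.mean()
    new_b -= m
    if const_ix is not None:
        new_beta[const_ix] += m
    sb2 = max(sigma_b**2, 1e-12)
    dprior = (b @ b - new_b @ new_b) / (2 * sb2)
    dprior += (beta[col_ix] ** 2 - new_beta[col_ix] ** 2) / (2 * beta_sd**2)
    if const_ix is not None:
        dprior += (beta[const_ix] ** 2 - new_beta[const_ix] ** 2) / (2 * beta_sd**2)
    if np.log(rng.random()) < dprior:
        return new_beta, new_b, True
    return beta, b, False


def _translate_move(beta, alpha, col, const_ix, post_mask, sigma_a, beta_sd, rng,
                    step=None):
    """Shift mass between the period coefficient and the RW1 path.

    Proposes beta[col] += d while subtracting d from alpha at post-period
    months; eta is invariant, so only prior terms enter the accept ratio.
    """
    d = rng.normal(0.0, step if step is not None else 0.5 * sigma_a + 0.01)
    new_beta = beta.copy()
    new_beta[col] += d
    shift = np.where(post_mask, -d, 0.0)
    new_alpha = alpha + shift  # broadcasts over paths if 2-D
    m = new_alpha.mean(axis=-1, keepdims=True)
    new_alpha = new_alpha - m
    if const_ix is not None:
        new_beta[const_ix] += float(np.mean(m))
    sa2 = sigma_a**2
    dprior = (_rw1_increment_ss(alpha) - _rw1_increment_ss(new_alpha)) / (2 * sa2)
    dprior += (beta[col] ** 2 - new_beta[col] ** 2) / (2 * beta_sd**2)
    if const_ix is not None:
        dprior += (beta[const_ix] ** 2 - new_beta[const_ix] ** 2) / (2 * beta_sd**2)
    if np.log(rng.random()) < dprior:
        return new_beta, new_alpha, True
    return beta, alpha, False


# --------------------------------------------------------------------------
# Poisson family (log link, observation-level overdispersion)
# --------------------------------------------------------------------------

def run_poisson(data, priors, n_iter, warmup, thin, rng, start=None, prop_chol=None,
                translate_col=None, translate_post_mask=None):
    """Vectorized Metropolis-within-Gibbs for the overdispersed Poisson model."""
    X, y = data["X"], data["y"].astype(float)
    ind, tt = data["ind"], data["tt"]
    N, p = X.shape
    n_ind, T = data["n_ind"], data["T"]
    has_iid, has_rw1 = data["has_iid"], data["has_rw1"]
    has_od = data["has_overdispersion"]
    by_ind = data.get("rw1_by_individual", False)
    const_ix = data.get("const_ix")

    beta = np.zeros(p) if start is None else start.copy()
    b = np.zeros(n_ind)
    alpha = np.zeros((n_ind, T)) if by_ind else np.zeros(T)
    e = np.zeros(N)
    sig_b = _ScaleSampler(0.2, priors.sd_scale)
    sig_a = _ScaleSampler(0.05, priors.sd_scale)
    sig_e = _ScaleSampler(0.1, priors.sd_scale)

    Sy_i = np.bincount(ind, weights=y, minlength=n_ind)
    if by_ind:
        cell = ind * T + tt
        Sy_cell = np.bincount(cell, weights=y, minlength=n_ind * T).reshape(n_ind, T)
    else:
        Sy_t = np.bincount(tt, weights=y, minlength=T)

    if prop_chol is None:
        prop_chol = np.eye(p) * 0.02
    step_beta = _AdaptiveScalar(1.0, 0.25)
    step_b = _AdaptiveScalar(0.3, 0.44)
    step_a = _AdaptiveScalar(0.1, 0.44)
    step_e = _AdaptiveScalar(0.5, 0.44)

    # individual-constant columns ride a ridge with b; give each a
    # translation move with its own tuned step
    ind_const = data.get("ind_const", [])
    step_tr = {j: _AdaptiveScalar(0.1, 0.44) for j, _ in ind_const}
    step_translate = _AdaptiveScalar(0.05, 0.44)

    beta_hist = []  # warmup draws for empirical proposal covariance

    eta = X @ beta + (alpha[ind, tt] if by_ind else alpha[tt]) + b[ind] + e
    mu = np.exp(eta)
    even, odd = _checkerboard_masks(T)

    n_keep = (n_iter - warmup) // thin
    out = {
        "beta": np.empty((n_keep, p)),
        "sigma_b": np.empty(n_keep),
        "sigma_alpha": np.empty(n_keep),
        "sigma_e": np.empty(n_keep),
        "alpha": np.empty((n_keep, T)),
    }
    kept = 0

    for it in range(n_iter):
        in_warmup = it < warmup

        # ---- observation-level effects (conditionally independent) -------
        if has_od:
            se2 = max(sig_e.value**2, 1e-12)
            d_e = rng.normal(0.0, step_e.step, N)
            dlog = y * d_e - mu * np.expm1(d_e) - ((e + d_e) ** 2 - e**2) / (2 * se2)
            acc = np.log(rng.random(N)) < dlog
            e = np.where(acc, e + d_e, e)
            eta = np.where(acc, eta + d_e, eta)
            mu = np.where(acc, mu * np.exp(d_e), mu)
            step_e.register(float(np.mean(acc)))
            if in_warmup:
                step_e.adapt()
            # center the field into the intercept (eta invariant)
            if const_ix is not None:
                m = e.mean()
                e -= m
                beta[const_ix] += m
            sig_e.update(rng, float(e @ e), N)
            sig_e.adapt()
            # joint (sigma_e, e) rescale move: e' = e * s'/s.  The e-prior
            # cancels against the Jacobian, so only the likelihood, the
            # half-Normal prior on s and the log-transform Jacobian remain.
            s_old = sig_e.value
            log_s_new = np.log(s_old) + rng.normal(0.0, 0.15)
            s_new = float(np.exp(log_s_new))
            fac = s_new / s_old - 1.0
            d_eta = e * fac
            dlog = float(
                y @ d_eta
                - mu @ np.expm1(d_eta)
                + _halfnormal_logpdf(s_new, priors.sd_scale)
                - _halfnormal_logpdf(s_old, priors.sd_scale)
                + (log_s_new - np.log(s_old))
            )
            if np.log(rng.random()) < dlog:
                e = e * (s_new / s_old)
                eta = eta + d_eta
                mu = mu * np.exp(d_eta)
                sig_e.log_s = log_s_new

        # ---- individual intercepts ---------------------------------------
        if has_iid:
            sb2 = max(sig_b.value**2, 1e-12)
            Smu_i = np.bincount(ind, weights=mu, minlength=n_ind)
            d_b = rng.normal(0.0, step_b.step, n_ind)
            dlog = (
                Sy_i * d_b
                - Smu_i * np.expm1(d_b)
                - ((b + d_b) ** 2 - b**2) / (2 * sb2)
            )
            acc = np.log(rng.random(n_ind)) < dlog
            d_eff = np.where(acc, d_b, 0.0)
            b = b + d_eff
            row_shift = d_eff[ind]
            eta = eta + row_shift
            mu = mu * np.exp(row_shift)
            step_b.register(float(np.mean(acc)))
            if in_warmup:
                step_b.adapt()
            # center into the intercept (eta invariant)
            if const_ix is not None:
                m = b.mean()
                b -= m
                beta[const_ix] += m
            sig_b.update(rng, float(b @ b), n_ind)
            sig_b.adapt()
            for j, v_i in ind_const:
                beta, b, acc_tr = _ind_translate_move(
                    beta, b, j, v_i, const_ix, max(sig_b.value, 1e-4),
                    priors.beta_sd, rng, step_tr[j].step,
                )
                step_tr[j].register(float(acc_tr))
                if in_warmup:
                    step_tr[j].adapt()
            # joint (sigma_b, b) rescale move (b-prior cancels the Jacobian)
            s_old = max(sig_b.value, 1e-8)
            log_s_new = np.log(s_old) + rng.normal(0.0, 0.15)
            s_new = float(np.exp(log_s_new))
            d_row = b[ind] * (s_new / s_old - 1.0)
            dlog = float(
                y @ d_row - mu @ np.expm1(d_row)
                + _halfnormal_logpdf(s_new, priors.sd_scale)
                - _halfnormal_logpdf(s_old, priors.sd_scale)
                + (log_s_new - np.log(s_old))
            )
            if np.log(rng.random()) < dlog:
                b = b * (s_new / s_old)
                eta = eta + d_row
                mu = mu * np.exp(d_row)
                sig_b.log_s = log_s_new

        # ---- RW1 path(s): checkerboard over months -----------------------
        if has_rw1:
            sa = max(sig_a.value, 1e-6)
            if by_ind:
                Smu_cell = np.bincount(cell, weights=mu, minlength=n_ind * T).reshape(n_ind, T)
                for color in (even, odd):
                    pm, psd = _rw1_conditional(alpha, color, sa)
                    cur = alpha[:, color]
                    d_a = rng.normal(0.0, step_a.step, size=cur.shape)
                    new = cur + d_a
                    dlog = (
                        Sy_cell[:, color] * d_a
                        - Smu_cell[:, color] * np.expm1(d_a)
                        - ((new - pm) ** 2 - (cur - pm) ** 2) / (2 * psd**2)
                    )
                    acc = np.log(rng.random(cur.shape)) < dlog
                    alpha[:, color] = np.where(acc, new, cur)
                    # update eta/mu rows touched by accepted cells
                    d_eff = np.where(acc, d_a, 0.0)
                    full = np.zeros((n_ind, T))
                    full[:, color] = d_eff
                    row_shift = full[ind, tt]
                    eta = eta + row_shift
                    mu = mu * np.exp(row_shift)
                    Smu_cell[:, color] *= np.exp(d_eff)
                    step_a.register(float(np.mean(acc)))
                m = alpha.mean()
                alpha -= m
                n_inc = n_ind * (T - 1)
            else:
                Smu_t = np.bincount(tt, weights=mu, minlength=T)
                for color in (even, odd):
                    pm, psd = _rw1_conditional(alpha, color, sa)
                    cur = alpha[color]
                    d_a = rng.normal(0.0, step_a.step, size=cur.shape)
                    new = cur + d_a
                    dlog = (
                        Sy_t[color] * d_a
                        - Smu_t[color] * np.expm1(d_a)
                        - ((new - pm) ** 2 - (cur - pm) ** 2) / (2 * psd**2)
                    )
                    acc = np.log(rng.random(cur.shape)) < dlog
                    d_eff = np.where(acc, d_a, 0.0)
                    alpha[color] = cur + d_eff
                    full = np.zeros(T)
                    full[color] = d_eff
                    row_shift = full[tt]
                    eta = eta + row_shift
                    mu = mu * np.exp(row_shift)
                    Smu_t[color] *= np.exp(d_eff)
                    step_a.register(float(np.mean(acc)))
                m = alpha.mean()
                alpha -= m
                n_inc = T - 1
            if const_ix is not None:
                beta[const_ix] += m
            if in_warmup:
                step_a.adapt()
            sig_a.update(rng, _rw1_increment_ss(alpha), n_inc)
            sig_a.adapt()

            if translate_col is not None:
                for _ in range(5):
                    beta, alpha, acc_t = _translate_move(
                        beta, alpha, translate_col, const_ix, translate_post_mask,
                        max(sig_a.value, 1e-4), priors.beta_sd, rng,
                        step=step_translate.step,
                    )
                    step_translate.register(float(acc_t))
                if in_warmup:
                    step_translate.adapt()

            # joint (sigma_alpha, alpha) rescale move
            s_old = max(sig_a.value, 1e-8)
            log_s_new = np.log(s_old) + rng.normal(0.0, 0.3)
            s_new = float(np.exp(log_s_new))
            fac = s_new / s_old - 1.0
            d_row = (alpha[ind, tt] if by_ind else alpha[tt]) * fac
            dlog = float(
                y @ d_row - mu @ np.expm1(d_row)
                + _halfnormal_logpdf(s_new, priors.sd_scale)
                - _halfnormal_logpdf(s_old, priors.sd_scale)
                + (log_s_new - np.log(s_old))
            )
            if np.log(rng.random()) < dlog:
                alpha = alpha * (s_new / s_old)
                eta = eta + d_row
                mu = mu * np.exp(d_row)
                sig_a.log_s = log_s_new

        # ---- fixed effects: preconditioned joint random walk -------------
        z = rng.normal(size=p)
        d_beta = step_beta.step * (prop_chol @ z)
        d_eta = X @ d_beta
        new_mu = mu * np.exp(d_eta)
        dlog = float(
            y @ d_eta
            - np.sum(new_mu - mu)
            - (np.sum((beta + d_beta) ** 2) - np.sum(beta**2)) / (2 * priors.beta_sd**2)
        )
        if np.log(rng.random()) < dlog:
            beta = beta + d_beta
            eta = eta + d_eta
            mu = new_mu
            step_beta.register(1.0)
        else:
            step_beta.register(0.0)
        if in_warmup:
            step_beta.adapt()
            beta_hist.append(beta.copy())
            # refresh the proposal shape from the warmup history (Haario-style)
            if it >= 300 and it % 200 == 0 and len(beta_hist) > 100:
                emp = np.cov(np.asarray(beta_hist[len(beta_hist) // 2 :]).T)
                emp = np.atleast_2d(emp) + 1e-10 * np.eye(p)
                try:
                    prop_chol = (2.4 / np.sqrt(p)) * np.linalg.cholesky(emp)
                    step_beta.step = 1.0
                except np.linalg.LinAlgError:
                    pass

        if it >= warmup and (it - warmup) % thin == 0 and kept < n_keep:
            out["beta"][kept] = beta
            out["sigma_b"][kept] = sig_b.value
            out["sigma_alpha"][kept] = sig_a.value
            out["sigma_e"][kept] = sig_e.value
            out["alpha"][kept] = alpha.mean(axis=0) if by_ind else alpha
            kept += 1

    return out
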