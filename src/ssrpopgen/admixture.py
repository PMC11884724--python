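"""Bayesian model-based clustering of multilocus genotypes.

Implements the admixture model with correlated allele frequencies: each
individual i carries ancestry proportions Q_i over K clusters; each allele
copy at locus l originates from cluster Z and is drawn from that cluster's
allele frequencies P_kl.  Cluster frequencies are tied to unknown ancestral
frequencies PA_l through per-cluster drift parameters F_k,

    P_kl ~ Dirichlet( PA_l * (1 - F_k) / F_k ),    PA_l ~ Dirichlet(lambda),

so small F_k keeps clusters close to the ancestral frequencies.  Ancestries
are Q_i ~ Dirichlet(alpha, ..., alpha) with a single alpha under a
uniform(0, 10) hyperprior.

Inference is by Gibbs sampling: Z | P,Q and Q | Z and P | Z are standard
conjugate updates; PA, F and alpha move by Metropolis steps.  Missing calls
contribute nothing to the likelihood.  The marginal data likelihood is
summarised as lnP(D) = mean(lnL) - var(lnL)/2 over post-burn-in sweeps, and
the number of clusters is selected with the Evanno ΔK statistic:
ΔK = |L''(K)| / sd(L(K)) over replicate runs, maximised over interior K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["AdmixtureRun", "EvannoTable", "run_admixture", "evanno", "align_labels"]

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-9


@dataclass
class AdmixtureRun:
    """Posterior summaries and traces for one (K, seed) chain."""

    k: int
    individuals: list[str]
    q: np.ndarray  # (n, K) posterior mean ancestry, rows sum to 1
    p: list[pd.DataFrame]  # per locus: clusters x alleles posterior mean
    alpha_trace: np.ndarray
    loglik_trace: np.ndarray
    ln_prob_data: float
    burnin: int
    reps: int
    seed: int | None

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.q,
            index=self.individuals,
            columns=[f"Cluster{c + 1}" for c in range(self.k)],
        )


@dataclass
class EvannoTable:
    """Mean lnP(D), its first/second differences and ΔK per K."""

    table: pd.DataFrame  # index K; columns mean_lnP, sd_lnP, L1, absL2, deltaK
    selected_k: int | None  # None when no ΔK is defined (inconclusive)


def _encode(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Integer-coded allele copies (n, L, 2), observation mask, allele labels."""
    n, L = matrix.n_individuals, matrix.n_loci
    coded = np.full((n, L, 2), -1, dtype=np.int64)
    labels: list[np.ndarray] = []
    present = ~matrix.missing_mask()
    for j in range(L):
        col = matrix.calls[:, j, :]
        alleles = np.unique(col[col != MISSING])
        labels.append(alleles)
        lut = {int(a): i for i, a in enumerate(alleles)}
        for i in range(n):
            if present[i, j]:
                coded[i, j, 0] = lut[int(col[i, 0])]
                coded[i, j, 1] = lut[int(col[i, 1])]
    return coded, present, labels


def _dirichlet_rows(rng: np.random.Generator, shape_params: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Sample Dirichlet rows along the last axis, honouring a validity mask."""
    g = rng.gamma(np.maximum(shape_params, 1e-6))
    g = np.where(valid, np.maximum(g, _P_FLOOR), 0.0)
    return g / g.sum(axis=-1, keepdims=True)


def run_admixture(
    matrix: GenotypeMatrix,
    k: int,
    burnin: int = 30000,
    reps: int = 15000,
    seed: int | None = None,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    alpha_proposal_sd: float = 0.025,
    drift_init: float = 0.01,
    lambda_prior: float = 1.0,
) -> AdmixtureRun:
    """Run one MCMC chain of the correlated-frequencies admixture model.

    ``burnin`` sweeps are discarded, ``reps`` sweeps are recorded.  The
    defaults mirror common practice for SSR panels (alpha initialised at
    1.0 with a uniform(0, 10) hyperprior and Metropolis step 0.025; drift
    initialised at 0.01; lambda = 1).  Identical seed and inputs give
    identical traces.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if burnin < 0 or reps < 0:
        raise ValueError("burnin and reps must be >= 0")
    if k > 1 and reps < 1:
        raise ValueError("reps must be >= 1 when K > 1")
    if burnin > reps and reps > 0:
        logger.info(
            "burn-in (%d) exceeds recorded sweeps (%d); unusual but honoured",
            burnin,
            reps,
        )
    coded, present, allele_labels = _encode(matrix)
    n, L, _ = coded.shape
    n_distinct = len({tuple(row.ravel()) for row in matrix.calls})
    if k > n_distinct:
        logger.warning(
            "K=%d exceeds the %d distinct multilocus genotypes", k, n_distinct
        )
    max_a = max(len(a) for a in allele_labels)
    valid = np.zeros((L, max_a), dtype=bool)
    for j, a in enumerate(allele_labels):
        valid[j, : len(a)] = True
    rng = np.random.default_rng(seed)

    obs = present[:, :, None] & np.ones((1, 1, 2), dtype=bool)  # (n, L, 2)
    safe = np.where(coded >= 0, coded, 0)
    n_copies = int(obs.sum())

    # pooled empirical frequencies initialise the ancestral vector
    pa = np.zeros((L, max_a))
    for j in range(L):
        counts = np.bincount(
            coded[:, j, :][coded[:, j, :] >= 0], minlength=max_a
        ).astype(float)
        pa[j] = (counts + lambda_prior) * valid[j]
    pa /= pa.sum(axis=1, keepdims=True)

    drift = np.full(k, drift_init)
    alpha = float(alpha_init)
    p = _dirichlet_rows(
        rng, np.broadcast_to(pa * 50.0, (k, L, max_a)).copy(), valid[None, :, :]
    )
    q = np.full((n, k), 1.0 / k)

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    alpha_tr = np.empty(reps)
    ll_tr = np.empty(reps)

    from scipy.special import gammaln

    def drift_loglik(c: int, f: float, logp_np: np.ndarray) -> float:
        """log Dirichlet(P_c. ; PA * (1-f)/f) over loci + logit Jacobian."""
        cc = (1.0 - f) / f
        ll = (
            L * gammaln(cc)
            - gammaln(np.where(valid, cc * pa, 1.0)).sum()
            + ((cc * pa - 1.0) * np.where(valid, logp_np[c], 0.0)).sum()
        )
        return float(ll + np.log(f * (1.0 - f)))

    total = burnin + reps
    for sweep in range(total):
        # --- Z | P, Q -----------------------------------------------------
        # prob[i,l,c,k] ∝ q[i,k] * p[k, l, x_ilc]
        p_at = p[:, np.arange(L)[None, :, None], safe]  # (k, n, L, 2)
        probs = np.moveaxis(p_at, 0, -1) * q[:, None, None, :]
        tot = probs.sum(axis=-1, keepdims=True)
        probs = probs / np.maximum(tot, 1e-300)
        u = rng.random(probs.shape[:-1] + (1,))
        z = (probs.cumsum(axis=-1) < u).sum(axis=-1)
        z = np.minimum(z, k - 1)
        z = np.where(obs, z, -1)

        # --- counts -------------------------------------------------------
        # ancestry counts per individual
        n_ik = np.zeros((n, k))
        for c in range(k):
            n_ik[:, c] = ((z == c) & obs).sum(axis=(1, 2))
        # allele counts per cluster/locus
        m = np.zeros((k, L, max_a))
        zz = z.reshape(n, -1)
        xx = safe.reshape(n, -1)
        oo = obs.reshape(n, -1)
        for c in range(k):
            sel = (zz == c) & oo
            for j in range(L):
                cols = slice(2 * j, 2 * j + 2)
                vals = xx[:, cols][sel[:, cols]]
                if vals.size:
                    m[c, j] = np.bincount(vals, minlength=max_a)

        # --- Q | Z --------------------------------------------------------
        if k == 1:
            q = np.ones((n, 1))
        else:
            q = _dirichlet_rows(rng, alpha + n_ik, np.ones((n, k), dtype=bool))

        # --- P | Z --------------------------------------------------------
        prior = pa[None, :, :] * ((1.0 - drift) / drift)[:, None, None]
        p = _dirichlet_rows(rng, prior + m, valid[None, :, :])

        # --- PA Metropolis (pairwise mass moves) --------------------------
        c_k = (1.0 - drift) / drift
        for j in range(L):
            a_count = int(valid[j].sum())
            if a_count < 2:
                continue
            a1, a2 = rng.choice(a_count, size=2, replace=False)
            delta = rng.uniform(0, 0.05)
            new1, new2 = pa[j, a1] + delta, pa[j, a2] - delta
            if new2 <= 0 or new1 >= 1:
                continue
            logp = 0.0
            for c in range(k):
                logp += (
                    gammaln(c_k[c] * pa[j, a1])
                    - gammaln(c_k[c] * new1)
                    + gammaln(c_k[c] * pa[j, a2])
                    - gammaln(c_k[c] * new2)
                    + c_k[c] * (new1 - pa[j, a1]) * np.log(p[c, j, a1])
                    + c_k[c] * (new2 - pa[j, a2]) * np.log(p[c, j, a2])
                )
            logp += (lambda_prior - 1.0) * (
                np.log(new1 / pa[j, a1]) + np.log(new2 / pa[j, a2])
            )
            if np.log(rng.random()) < logp:
                pa[j, a1], pa[j, a2] = new1, new2

        # --- F Metropolis (logit random walk, uniform(0,1) prior) ---------
        logp_np = np.log(np.maximum(p, _P_FLOOR)) * valid[None, :, :]
        for c in range(k):
            f_cur = drift[c]
            logit = np.log(f_cur / (1 - f_cur)) + rng.normal(0, 0.3)
            f_new = 1.0 / (1.0 + np.exp(-logit))
            log_ratio = drift_loglik(c, f_new, logp_np) - drift_loglik(
                c, f_cur, logp_np
            )
            if np.log(rng.random()) < log_ratio:
                drift[c] = f_new

        # --- alpha Metropolis ---------------------------------------------
        if k > 1:
            a_new = alpha + rng.normal(0, alpha_proposal_sd)
            if 0.0 < a_new < alpha_max:
                logq = np.log(np.maximum(q, _P_FLOOR)).sum()
                logp = n * (
                    gammaln(k * a_new)
                    - k * gammaln(a_new)
                    - gammaln(k * alpha)
                    + k * gammaln(alpha)
                ) + (a_new - alpha) * logq
                if np.log(rng.random()) < logp:
                    alpha = a_new

        # --- likelihood and recording -------------------------------------
        if sweep >= burnin:
            p_at = p[:, np.arange(L)[None, :, None], safe]
            mix = (np.moveaxis(p_at, 0, -1) * q[:, None, None, :]).sum(axis=-1)
            ll = float(np.log(np.maximum(mix, 1e-300))[obs].sum())
            r = sweep - burnin
            ll_tr[r] = ll
            alpha_tr[r] = alpha
            q_sum += q
            p_sum += p

    if reps > 0:
        q_mean = q_sum / reps
        q_mean /= q_mean.sum(axis=1, keepdims=True)
        p_mean = p_sum / reps
        p_mean /= np.maximum(p_mean.sum(axis=2, keepdims=True), 1e-300)
        ln_prob = float(np.mean(ll_tr) - np.var(ll_tr) / 2.0)
    else:
        q_mean = q
        p_mean = p
        ln_prob = np.nan
    p_frames = [
        pd.DataFrame(
            p_mean[:, j, : len(allele_labels[j])],
            index=[f"Cluster{c + 1}" for c in range(k)],
            columns=allele_labels[j],
        )
        for j in range(L)
    ]
    return AdmixtureRun(
        k=k,
        individuals=list(matrix.individuals),
        q=q_mean,
        p=p_frames,
        alpha_trace=alpha_tr[:reps],
        loglik_trace=ll_tr[:reps],
        ln_prob_data=ln_prob,
        burnin=burnin,
        reps=reps,
        seed=seed,
    )


def align_labels(runs: list[AdmixtureRun]) -> list[AdmixtureRun]:
    """Permute cluster labels so replicate runs agree with the first run.

    Greedy matching on the L1 similarity of Q columns; a no-op for K = 1.
    """
    if not runs:
        return runs
    k = runs[0].k
    for r in runs:
        if r.k != k:
            raise ValueError("all runs must share the same K")
        if r.individuals != runs[0].individuals:
            raise ValueError("all runs must share the same individuals")
    if k == 1:
        return runs
    ref = runs[0].q
    out = [runs[0]]
    for r in runs[1:]:
        cost = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                cost[a, b] = np.abs(ref[:, a] - r.q[:, b]).sum()
        perm = np.full(k, -1)
        used: set[int] = set()
        for a, b in sorted(
            ((a, b) for a in range(k) for b in range(k)), key=lambda ab: cost[ab]
        ):
            if perm[a] == -1 and b not in used:
                perm[a] = b
                used.add(b)
        q_new = r.q[:, perm]
        p_new = [frame.iloc[perm].set_axis(frame.index) for frame in r.p]
        out.append(
            AdmixtureRun(
                k=r.k,
                individuals=r.individuals,
                q=q_new,
                p=p_new,
                alpha_trace=r.alpha_trace,
                loglik_trace=r.loglik_trace,
                ln_prob_data=r.ln_prob_data,
                burnin=r.burnin,
                reps=r.reps,
                seed=r.seed,
            )
        )
    return out


def evanno(runs: list[AdmixtureRun]) -> EvannoTable:
    """ΔK model selection over replicate runs grouped by K.

    Requires at least three consecutive K values with at least two runs
    each.  ΔK is defined for interior K with nonzero run-to-run standard
    deviation; the selected K maximises ΔK, or is None (inconclusive) when
    no ΔK is defined.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.ln_prob_data)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for kk, vals in by_k.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 runs for K={kk}")
    mean_l = {kk: float(np.mean(by_k[kk])) for kk in ks}
    sd_l = {kk: float(np.std(by_k[kk], ddof=1)) for kk in ks}
    rows = []
    for kk in ks:
        l1 = mean_l[kk] - mean_l[kk - 1] if kk - 1 in mean_l else np.nan
        if kk - 1 in mean_l and kk + 1 in mean_l:
            l2 = abs(
                (mean_l[kk + 1] - mean_l[kk]) - (mean_l[kk] - mean_l[kk - 1])
            )
            if sd_l[kk] > 0:
                dk = l2 / sd_l[kk]
            else:
                logger.warning("sd(L) = 0 at K=%d; ΔK undefined there", kk)
                dk = np.nan
        else:
            l2, dk = np.nan, np.nan
        rows.append([mean_l[kk], sd_l[kk], l1, l2, dk])
    table = pd.DataFrame(
        rows,
        index=pd.Index(ks, name="K"),
        columns=["mean lnP(D)", "sd lnP(D)", "L'(K)", "|L''(K)|", "deltaK"],
    )
    dk_col = table["deltaK"].dropna()
    selected = int(dk_col.idxmax()) if len(dk_col) and dk_col.max() > 0 else None
    return EvannoTable(table=table, selected_k=selected)
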