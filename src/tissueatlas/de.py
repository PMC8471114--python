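"""One-vs-all differential expression by negative-binomial GLM likelihood-ratio tests.

For each focal tissue the counts of every gene are modelled as

    y_gs ~ NB(mu_gs, phi_g),   log mu_gs = log(libsize_s) + b0_g + b1_g * x_s

where x_s indicates membership of sample s in the focal tissue and phi_g is
the gene's overdispersion (variance mu + phi*mu^2). The null model drops the
indicator; the LRT statistic 2*(l_full - l_null) is referred to chi-square
with 1 df. ``log2fc = b1 / ln 2`` is the focal-vs-rest log2 fold-change.

Dispersions are method-of-moments estimates on library-size-normalized
counts, shrunk toward a trimmed-mean common value. Fitting is plain Fisher
scoring (IRLS), vectorized across genes; normalization is the library-size
offset (no TMM).

A gene is called differentially expressed when log2FC > 3 (strictly, signed:
upregulated in the focal tissue) and p < 0.05 (strictly); BH-adjusted
q-values are reported alongside but do not enter the call.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "estimate_dispersions",
    "nb_loglik",
    "one_vs_all_lrt",
    "de_all_tissues",
    "call_degs",
]

_DISPERSION_FLOOR = 1e-6


def estimate_dispersions(
    counts: pd.DataFrame,
    design: pd.DataFrame | None = None,
    n_common: float = 10.0,
    trim: float = 0.1,
) -> pd.Series:
    """Per-gene NB dispersion phi with shrinkage toward the common value.

    Raw phi_g = max(0, (s^2 - mu) / mu^2) on counts normalized to the mean
    library size. When a design is given the moments are pooled within
    tissue groups (weighted by residual degrees of freedom), so genuine
    between-tissue expression differences do not inflate the estimate. The
    gene estimate is averaged with the trimmed-mean common dispersion using
    weight w = n_common / (n_common + n_samples) on the common value, then
    floored at 1e-6. Genes with zero counts everywhere (or no group with a
    positive mean and >=2 replicates) have undefined dispersion and come
    back NaN; downstream tests skip them.
    """
    Y = counts.values.astype(float)
    n_samples = Y.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples to estimate dispersions")
    lib = Y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    norm = Y / lib * lib.mean()

    if design is None:
        groups = [np.arange(n_samples)]
    else:
        tissue_of = dict(zip(design["sample_id"], design["tissue"]))
        sample_tissues = np.array([tissue_of[s] for s in counts.columns])
        groups = [np.flatnonzero(sample_tissues == t) for t in np.unique(sample_tissues)]

    num = np.zeros(Y.shape[0])
    dof = np.zeros(Y.shape[0])
    for cols in groups:
        if cols.size < 2:
            continue
        mu_t = norm[:, cols].mean(axis=1)
        s2_t = norm[:, cols].var(axis=1, ddof=1)
        # E[mean^2] = mu^2 + var(mean), so mean^2 - s^2/n is the unbiased
        # estimate of mu^2; without it phi is biased low at few replicates
        denom = mu_t**2 - s2_t / cols.size
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_t = np.where((mu_t > 0) & (denom > 0), (s2_t - mu_t) / denom, np.nan)
        ok = np.isfinite(phi_t)
        num[ok] += (cols.size - 1) * phi_t[ok]
        dof[ok] += cols.size - 1
    with np.errstate(invalid="ignore"):
        raw = np.where(dof > 0, np.maximum(0.0, num / np.maximum(dof, 1)), np.nan)
    finite = raw[np.isfinite(raw)]
    common = float(stats.trim_mean(finite, trim)) if finite.size else 0.0
    w = n_common / (n_common + n_samples)
    phi = w * common + (1.0 - w) * raw
    phi = np.maximum(phi, _DISPERSION_FLOOR)
    return pd.Series(phi, index=counts.index, name="dispersion")


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood of one gene (Poisson limit for phi ~ 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    if phi < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def _fit_nb_glm(Y, X, offset, phi, max_iter=80, tol=1e-10):
    """Vectorized IRLS for an NB log-linear model with known dispersion.

    Y: genes x samples counts; X: samples x p design; offset: per-sample log
    library size; phi: per-gene dispersion. Returns (beta, loglik, converged).
    """
    G, S = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log((Y.sum(axis=1) + 0.5) / np.exp(offset).sum())
    phi_col = phi[:, None]
    delta = np.full(G, np.inf)
    for _ in range(max_iter):
        eta = np.clip(offset[None, :] + beta @ X.T, -40.0, 40.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("gs,sp,sq->gpq", W, X, X, optimize=True)
        XtWz = np.einsum("gs,sp,gs->gp", W, X, z, optimize=True)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        delta = np.abs(new - beta).max(axis=1)
        beta = new
        if (delta < tol).all():
            break
    converged = delta < 1e-6
    eta = np.clip(offset[None, :] + beta @ X.T, -40.0, 40.0)
    mu = np.exp(eta)
    ll = np.empty(G)
    for g in range(G):
        ll[g] = nb_loglik(Y[g], mu[g], float(phi[g]))
    return beta, ll, converged


def one_vs_all_lrt(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    focal_tissue: str,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """LRT of every gene for one focal tissue against all remaining samples.

    Returns a DataFrame indexed by gene with columns ``tissue``, ``log2fc``,
    ``lrt_stat``, ``p``, ``dispersion`` and ``converged``. Genes with zero
    counts in every sample are skipped: their statistics are NaN and they can
    never be called differentially expressed. Non-converged fits keep their
    fold-change estimate but report a missing p-value.
    """
    tissue_of = dict(zip(design["sample_id"], design["tissue"]))
    sample_tissues = np.array([tissue_of[s] for s in counts.columns])
    if focal_tissue not in sample_tissues:
        raise ValueError(f"focal tissue {focal_tissue!r} has no samples")
    x = (sample_tissues == focal_tissue).astype(float)
    if x.all():
        raise ValueError("no non-focal samples to contrast against")

    if dispersions is None:
        dispersions = estimate_dispersions(counts, design)
    phi_all = dispersions.reindex(counts.index).values

    Y = counts.values.astype(float)
    lib = Y.sum(axis=0)
    offset = np.log(lib)
    nonzero = Y.sum(axis=1) > 0
    usable = nonzero & np.isfinite(phi_all)

    out = pd.DataFrame(
        {
            "tissue": focal_tissue,
            "log2fc": np.nan,
            "lrt_stat": np.nan,
            "p": np.nan,
            "dispersion": phi_all,
            "converged": False,
        },
        index=counts.index,
    )
    if usable.any():
        Yu = Y[usable]
        phi = phi_all[usable]
        X_null = np.ones((len(x), 1))
        X_full = np.column_stack([np.ones_like(x), x])
        _, ll0, conv0 = _fit_nb_glm(Yu, X_null, offset, phi)
        beta1, ll1, conv1 = _fit_nb_glm(Yu, X_full, offset, phi)
        lrt = np.maximum(0.0, 2.0 * (ll1 - ll0))
        conv = conv0 & conv1
        p = np.where(conv, stats.chi2.sf(lrt, df=1), np.nan)
        out.loc[usable, "log2fc"] = beta1[:, 1] / np.log(2.0)
        out.loc[usable, "lrt_stat"] = lrt
        out.loc[usable, "p"] = p
        out.loc[usable, "converged"] = conv
    return out


def de_all_tissues(counts, design, dispersions=None) -> pd.DataFrame:
    """Run the one-vs-all LRT for every tissue; long-format result table."""
    if dispersions is None:
        dispersions = estimate_dispersions(counts, design)
    frames = []
    for tissue in sorted(design["tissue"].unique()):
        res = one_vs_all_lrt(counts, design, tissue, dispersions=dispersions)
        frames.append(res.rename_axis("gene_id").reset_index())
    return pd.concat(frames, ignore_index=True)


def call_degs(
    results: pd.DataFrame,
    log2fc_cutoff: float = 3.0,
    p_cutoff: float = 0.05,
    absolute: bool = False,
) -> pd.DataFrame:
    """Apply the joint fold-change/p-value rule and add BH q-values.

    Both inequalities are strict; a gene at log2FC exactly 3.0 is not a DEG.
    By default the rule is signed (upregulation in the focal tissue); set
    ``absolute=True`` to call strong downregulation as well. q-values are
    reported for reference only and do not enter ``is_deg``.
    """
    out = results.copy()
    p = out["p"].values.astype(float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    out["q"] = q
    fc = out["log2fc"].values.astype(float)
    effect = np.abs(fc) if absolute else fc
    out["is_deg"] = (effect > log2fc_cutoff) & (p < p_cutoff) & ok
    return out
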