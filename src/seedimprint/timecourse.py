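"""Time-course differential expression over the 0-8 DAP seed series.

Two stages are intersected, mirroring the common practice of requiring
agreement between a pairwise-contrast GLM analysis and a polynomial
time-series regression:

* **GLM-LRT stage** — per gene, a negative-binomial GLM with time point
  as a categorical factor (equivalent to combining the successive
  pairwise comparisons) is tested against an intercept-only null by
  likelihood-ratio test with #timepoints-1 degrees of freedom, with
  Benjamini-Hochberg control at FDR 0.01.
* **Polynomial stage** — per gene, an NB regression on polynomial time
  terms (numeric DAP, default degree 4) plus batch (maternal-plant)
  terms; a global LRT of the time terms is BH-corrected, surviving genes
  undergo backward elimination of time terms at alpha = 0.05, and a gene
  is flagged only when its selected model also reaches a deviance
  pseudo-R^2 of 0.6.

The DEG set is the intersection of the two stages' flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._nbglm import estimate_dispersions, fit_nb_glm
from .quantify import cpm


def _offsets(counts: pd.DataFrame, tmm: pd.Series | None,
             library_sizes: pd.Series | None = None) -> np.ndarray:
    if library_sizes is None:
        lib = counts.sum(axis=0).to_numpy(dtype=float)
    else:
        lib = library_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if tmm is not None:
        lib = lib * tmm.reindex(counts.columns).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("non-positive effective library size")
    return np.log(lib)


def _batch_dummies(design: pd.DataFrame) -> np.ndarray:
    batches = pd.Categorical(design["batch"])
    if len(batches.categories) < 2:
        return np.empty((len(design), 0))
    return pd.get_dummies(batches, drop_first=True).to_numpy(dtype=float)


def glm_lrt_stage(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.01,
    tmm: pd.Series | None = None,
    dispersions: np.ndarray | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Categorical-time NB GLM likelihood-ratio stage.

    `design` is indexed by sample with at least a numeric ``dap``
    column. Returns a per-gene frame with p, BH q and the DEG flag at
    ``q <= fdr``.
    """
    design = design.loc[counts.columns]
    dap = design["dap"].to_numpy()
    levels = np.unique(dap)
    if len(levels) < 2:
        raise ValueError("need at least two time points")
    offset = _offsets(counts, tmm, library_sizes)
    y_all = counts.to_numpy(dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(y_all, dap, np.exp(offset))
    X_full = pd.get_dummies(pd.Categorical(dap)).to_numpy(dtype=float)
    X_null = np.ones((len(dap), 1))
    df = len(levels) - 1
    stats, pvals = np.empty(len(counts)), np.empty(len(counts))
    for i in range(len(counts)):
        y = y_all[i]
        phi = float(dispersions[i])
        full = fit_nb_glm(y, X_full, offset, phi)
        null = fit_nb_glm(y, X_null, offset, phi)
        lrt = max(0.0, 2.0 * (full["loglik"] - null["loglik"]))
        stats[i] = lrt
        pvals[i] = chi2.sf(lrt, df)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {"lrt": stats, "p_glm": pvals, "q_glm": qvals, "glm_deg": qvals <= fdr},
        index=counts.index,
    )


def _poly_basis(dap: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial time basis (excluding the constant)."""
    t = (dap - dap.mean()) / (dap.std() if dap.std() > 0 else 1.0)
    V = np.vander(t, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q[:, 1:degree + 1] * np.sqrt(len(dap))


def polynomial_stage(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    r2_min: float = 0.6,
    fdr: float = 0.01,
    degree: int = 4,
    alpha_elim: float = 0.05,
    tmm: pd.Series | None = None,
    dispersions: np.ndarray | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Polynomial time-series NB regression stage with batch terms.

    Per gene: global LRT of all time terms against a batch-only null
    (BH FDR gate), then backward elimination of time terms at
    `alpha_elim`, then the deviance pseudo-R^2 gate
    ``1 - dev(selected)/dev(batch-only) >= r2_min``.
    """
    design = design.loc[counts.columns]
    dap = design["dap"].to_numpy(dtype=float)
    n_tp = len(np.unique(dap))
    if degree >= n_tp:
        raise ValueError(f"polynomial degree {degree} needs more than {n_tp} time points")
    offset = _offsets(counts, tmm, library_sizes)
    y_all = counts.to_numpy(dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(y_all, dap, np.exp(offset))

    T = _poly_basis(dap, degree)
    B = _batch_dummies(design)
    ones = np.ones((len(dap), 1))
    X_null = np.hstack([ones, B])

    pvals = np.empty(len(counts))
    null_devs = np.empty(len(counts))
    for i in range(len(counts)):
        y, phi = y_all[i], float(dispersions[i])
        full = fit_nb_glm(y, np.hstack([ones, T, B]), offset, phi)
        null = fit_nb_glm(y, X_null, offset, phi)
        lrt = max(0.0, 2.0 * (full["loglik"] - null["loglik"]))
        pvals[i] = chi2.sf(lrt, degree)
        null_devs[i] = null["deviance"]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    significant = qvals <= fdr

    r2 = np.zeros(len(counts))
    terms_kept: list[str] = [""] * len(counts)
    for i in np.nonzero(significant)[0]:
        y, phi = y_all[i], float(dispersions[i])
        keep = list(range(degree))
        while keep:
            X_cur = np.hstack([ones, T[:, keep], B])
            cur = fit_nb_glm(y, X_cur, offset, phi)
            term_p = []
            for j in range(len(keep)):
                sub = keep[:j] + keep[j + 1:]
                X_sub = np.hstack([ones, T[:, sub], B]) if sub else X_null
                red = fit_nb_glm(y, X_sub, offset, phi)
                lrt_j = max(0.0, 2.0 * (cur["loglik"] - red["loglik"]))
                term_p.append(chi2.sf(lrt_j, 1))
            worst = int(np.argmax(term_p))
            if term_p[worst] > alpha_elim:
                keep.pop(worst)
            else:
                break
        if keep:
            X_sel = np.hstack([ones, T[:, keep], B])
            sel = fit_nb_glm(y, X_sel, offset, phi)
            if null_devs[i] > 0:
                r2[i] = 1.0 - sel["deviance"] / null_devs[i]
            terms_kept[i] = ",".join(f"t^{k + 1}" for k in keep)
        else:
            significant[i] = False

    return pd.DataFrame(
        {
            "p_poly": pvals,
            "q_poly": qvals,
            "r2": r2,
            "terms": terms_kept,
            "poly_deg": significant & (r2 >= r2_min),
        },
        index=counts.index,
    )


def intersect_degs(glm_result: pd.DataFrame, poly_result: pd.DataFrame) -> pd.DataFrame:
    """Combine the two stages; a DEG must be flagged by both."""
    out = glm_result.join(poly_result, how="outer")
    out["glm_deg"] = out["glm_deg"].fillna(False).astype(bool)
    out["poly_deg"] = out["poly_deg"].fillna(False).astype(bool)
    out["intersection_deg"] = out["glm_deg"] & out["poly_deg"]
    return out


def pca_samples(
    counts: pd.DataFrame, n_top: int = 500, n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on log2(CPM+1) of the most variable genes.

    Returns per-sample coordinates and the variance-explained fractions
    (non-increasing, summing to <= 1).
    """
    if counts.shape[1] < 3:
        raise ValueError("PCA needs at least three samples")
    x = np.log2(cpm(counts) + 1.0)
    var = x.var(axis=1)
    top = var.sort_values(ascending=False).index[: min(n_top, len(var))]
    mat = x.loc[top].to_numpy().T  # samples x genes
    mat = mat - mat.mean(axis=0)
    n_components = min(n_components, min(mat.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(mat)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=counts.columns, columns=cols), pca.explained_variance_ratio_
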