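"""Mixed-model association mapping of self-incompatibility loci.

Two phenotype constructions feed the same mixed linear model (MLM):

* model A — every ordered parent pair (female, male), selfs included, is an
  in-silico "progeny" whose marker score encodes the single-locus
  gametophytic SI expectation (+1 when the male carries an allele the
  female lacks, i.e. some pollen class escapes rejection; -1 when the
  female contains every male allele) and whose phenotype is 1 when progeny
  of that cross were observed, 0 otherwise;
* models B-D — each parent is a unit, the phenotype is its score on
  principal component 1-3 of the progeny-count matrix, and markers are the
  parents' additive {0,1,2} genotypes.

The MLM is y = Xb + g + s*tau + e with g ~ N(0, sigma_g^2 K); population
structure enters as the leading principal components of the marker matrix
(five by default) and K is a centered cross-product genomic relationship
matrix.  Variance components are estimated once by REML under the
marker-free null (the P3D shortcut) and each marker is then tested by
generalized least squares with a t-test on tau.  Multiple testing is
controlled by Storey-Tibshirani q-values with a Benjamini-Hochberg
fallback, genome-wide and optionally within designated chromosomes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline
from sklearn.decomposition import PCA

from .core import MISSING, CallMatrix

__all__ = [
    "impute_parent_genotypes",
    "encode_pair_locus",
    "build_diallel",
    "binary_phenotype",
    "progeny_matrix_pcs",
    "genomic_relationship",
    "structure_pcs",
    "mlm_scan",
    "qvalues",
    "fdr_control",
]


# ----------------------------------------------------------------------
# imputation and encoding
# ----------------------------------------------------------------------


def impute_parent_genotypes(parents: CallMatrix, seed: int = 0) -> CallMatrix:
    """Fill missing calls by sampling from each marker's observed genotype
    frequencies.  Non-missing calls are never altered; markers with no
    observed call at all are dropped with a warning."""
    rng = np.random.default_rng(seed)
    g = parents.genotypes.copy()
    called = g != MISSING
    n_called = called.sum(axis=0)
    empty = n_called == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} marker(s) with no observed calls",
            stacklevel=2,
        )
        keep = parents.markers.index[~empty]
        parents = parents.subset(markers=keep)
        g = parents.genotypes.copy()
        called = g != MISSING
    n, m = g.shape
    for j in range(m):
        miss = ~called[:, j]
        if not miss.any():
            continue
        observed = g[called[:, j], j]
        g[miss, j] = rng.choice(observed, size=int(miss.sum()))
    out = parents.copy()
    out.genotypes = g
    return out


def encode_pair_locus(male_call: int, female_call: int) -> int:
    """Table-coded gametophytic SI expectation for one ordered pair.

    +1 (compatible) when the male genotype carries at least one allele
    absent from the female genotype — some pollen class then evades the
    single-locus rejection rule; -1 (incompatible) when the female contains
    every male allele.
    """
    if male_call == MISSING or female_call == MISSING:
        raise ValueError("encode only complete (imputed) genotypes")
    male_alleles = {0: {0}, 1: {0, 1}, 2: {1}}[int(male_call)]
    female_alleles = {0: {0}, 1: {0, 1}, 2: {1}}[int(female_call)]
    return 1 if male_alleles - female_alleles else -1


def _encode_arrays(male: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Vectorized pair encoding over aligned genotype arrays in {0,1,2}."""
    compatible = (
        ((male == 1) & (female != 1))
        | ((male == 0) & (female == 2))
        | ((male == 2) & (female == 0))
    )
    return np.where(compatible, 1, -1).astype(np.int8)


def build_diallel(parent_genotypes: np.ndarray) -> np.ndarray:
    """(P^2, m) SI-encoded matrix over all ordered pairs, female-major.

    Row ``f * P + m`` holds the codes for female ``f`` crossed by male
    ``m``; self pairs are included (their codes are always -1).
    """
    g = np.asarray(parent_genotypes)
    if (g == MISSING).any():
        raise ValueError("parent genotypes must be imputed before encoding")
    n = g.shape[0]
    female = np.repeat(g, n, axis=0)
    male = np.tile(g, (n, 1))
    return _encode_arrays(male, female)


def diallel_pair_index(parents: list[str]) -> pd.MultiIndex:
    """Row labels of :func:`build_diallel` as a (female, male) MultiIndex."""
    return pd.MultiIndex.from_product([parents, parents],
                                      names=["female", "male"])


def binary_phenotype(progeny_matrix: pd.DataFrame) -> np.ndarray:
    """Model-A phenotype: 1 if the ordered cross produced progeny, else 0,
    flattened female-major to align with :func:`build_diallel` rows."""
    return (progeny_matrix.to_numpy() > 0).astype(float).ravel()


def progeny_matrix_pcs(progeny_matrix: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Scores of each parent on the first k principal components of the
    progeny-count matrix (parents as rows/units, columns mean-centered,
    unscaled).  PC signs are arbitrary."""
    x = progeny_matrix.to_numpy(dtype=float)
    if x.shape[0] < k:
        raise ValueError("need at least k parents")
    if np.allclose(x, x.mean(axis=0)):
        raise ValueError("progeny matrix has no variance")
    scores = PCA(n_components=k, random_state=0).fit_transform(x)
    return pd.DataFrame(
        scores,
        index=progeny_matrix.index.rename("parent"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )


# ----------------------------------------------------------------------
# relationship matrix and structure covariates
# ----------------------------------------------------------------------


def genomic_relationship(markers: np.ndarray,
                         coding: str = "additive") -> np.ndarray:
    """Centered cross-product relationship matrix K = Wc Wc' / c.

    ``coding="additive"`` expects {0,1,2} dosages and normalizes by
    ``sum 2 p_j (1 - p_j)`` (VanRaden); ``coding="pm1"`` expects the
    {-1,+1} SI pair codes and normalizes by the marker count.
    """
    w = np.asarray(markers, dtype=float)
    if w.shape[1] == 1:
        warnings.warn("single-marker relationship matrix is degenerate",
                      stacklevel=2)
    centered = w - w.mean(axis=0, keepdims=True)
    if coding == "additive":
        p = w.mean(axis=0) / 2.0
        c = float((2.0 * p * (1.0 - p)).sum())
    elif coding == "pm1":
        c = float(w.shape[1])
    else:
        raise ValueError(f"unknown coding: {coding}")
    if c <= 0:
        raise ValueError("normalization constant is not positive "
                         "(all markers fixed?)")
    return centered @ centered.T / c


def parent_pair_factors(n_parents: int) -> np.ndarray:
    """Female and male indicator covariates for the P^2 ordered-pair rows.

    In the pair-phenotype design every pseudo-individual is a cross of two
    parents, so its "population structure" is its parental composition:
    a female-parent factor and a male-parent factor (reference-coded, 2P-2
    columns, female-major row order).  Projecting these out removes all
    parent main effects — fecundity differences, per-mother sampling depth —
    leaving marker tests sensitive only to female x male interaction
    effects such as self-incompatibility."""
    n = n_parents
    female = np.repeat(np.arange(n), n)
    male = np.tile(np.arange(n), n)
    x = np.zeros((n * n, 2 * n - 2))
    for k in range(n - 1):
        x[female == k, k] = 1.0
        x[male == k, n - 1 + k] = 1.0
    return x


def structure_pcs(markers: np.ndarray, n_pcs: int = 5) -> np.ndarray:
    """Leading principal-component scores of the (centered) marker matrix,
    used as fixed structure covariates in the MLM."""
    w = np.asarray(markers, dtype=float)
    w = w - w.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(w.shape) - 1)
    return PCA(n_components=n_pcs, random_state=0).fit_transform(w)


# ----------------------------------------------------------------------
# mixed linear model scan
# ----------------------------------------------------------------------


def _reml_delta(yr: np.ndarray, xr: np.ndarray, d: np.ndarray):
    """REML estimate of delta = sigma_g^2 / sigma_e^2 on eigenrotated data.

    ``yr``/``xr`` are the phenotype/covariates rotated by the eigenvectors
    of K and ``d`` holds K's eigenvalues.  Returns (delta, sigma_e^2).
    """
    n, p = xr.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = delta * d + 1.0
        xw = xr / w[:, None]
        xtx = xr.T @ xw
        try:
            beta = np.linalg.solve(xtx, xw.T @ yr)
        except np.linalg.LinAlgError:  # pragma: no cover
            return np.inf
        resid = yr - xr @ beta
        rss = float(resid @ (resid / w))
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0 or rss <= 0:  # pragma: no cover
            return np.inf
        return 0.5 * (
            (n - p) * np.log(rss) + np.log(w).sum() + logdet_xtx
        )

    grid = np.linspace(-10.0, 10.0, 21)
    values = [neg_reml(g) for g in grid]
    best = int(np.argmin(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi),
                                   method="bounded")
    log_delta = float(res.x) if res.success else grid[best]
    delta = float(np.exp(log_delta))
    w = delta * d + 1.0
    xw = xr / w[:, None]
    beta = np.linalg.solve(xr.T @ xw, xw.T @ yr)
    resid = yr - xr @ beta
    sigma_e2 = float(resid @ (resid / w)) / (n - p)
    return delta, sigma_e2


def mlm_scan(
    y: np.ndarray,
    marker_scores: np.ndarray,
    marker_info: pd.DataFrame,
    K: np.ndarray,
    n_pcs: int = 5,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
) -> pd.DataFrame:
    """Single-marker mixed-model scan with P3D variance components.

    Parameters
    ----------
    y
        Phenotype vector of length n (model A: 0/1 per ordered pair;
        models B-D: a PC score per parent).
    marker_scores
        (n, m) marker score matrix tested one column at a time.
    marker_info
        DataFrame (m rows, index = marker id) with at least ``chrom`` and
        ``pos``; carried through to the result.
    K
        n x n genomic relationship matrix for the polygenic term.
    n_pcs
        Number of leading marker-matrix PCs used as structure covariates
        (ignored when ``covariates`` is given).
    covariates
        Optional explicit (n, f) fixed-effect matrix replacing the PCs
        (an intercept is always added).

    Returns a DataFrame with effect, se, t, p per marker.  Under P3D the
    residual scale of each marker test is refit from that marker's
    generalized residual sum of squares, so with K = I and zero polygenic
    variance the p-values coincide with ordinary least-squares F-tests.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(marker_scores, dtype=float)
    n = len(y)
    if s.shape[0] != n or K.shape != (n, n):
        raise ValueError("dimension mismatch between y, markers and K")
    if len(marker_info) != s.shape[1]:
        raise ValueError("marker_info must describe the score columns")
    if covariates is None:
        covariates = structure_pcs(s, n_pcs) if n_pcs > 0 else None
    x = np.ones((n, 1))
    if covariates is not None:
        x = np.hstack([x, np.asarray(covariates, dtype=float)])

    d, u = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yr = u.T @ y
    xr = u.T @ x
    if not p3d:
        raise NotImplementedError("only the P3D strategy is implemented")
    delta, sigma_e2 = _reml_delta(yr, xr, d)
    sigma_g2 = delta * sigma_e2

    w = delta * d + 1.0
    sw = np.sqrt(w)
    z = yr / sw
    c = xr / sw[:, None]
    g = (u.T @ s) / sw[:, None]
    # project covariates out of phenotype and markers in the V-metric
    q, _ = np.linalg.qr(c)
    z_res = z - q @ (q.T @ z)
    t_coeff = q.T @ g
    a = g.T @ z_res
    b = (g * g).sum(axis=0) - (t_coeff * t_coeff).sum(axis=0)
    rss0 = float(z_res @ z_res)
    df = n - x.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(b > 1e-10, a / b, np.nan)
        rss = rss0 - np.where(b > 1e-10, a * a / b, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / b)
        tstat = tau / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df)
    p = np.where(np.isnan(tstat), 1.0, p)
    out = marker_info.copy()
    out["effect"] = tau
    out["se"] = se
    out["t"] = tstat
    out["p"] = p
    out.attrs["sigma_g2"] = sigma_g2
    out.attrs["sigma_e2"] = sigma_e2
    out.attrs["delta"] = delta
    return out


# ----------------------------------------------------------------------
# false discovery rate control
# ----------------------------------------------------------------------


def _bh_qvalues(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def _estimate_pi0(p: np.ndarray) -> float:
    """Storey-Tibshirani smoother estimate of the null proportion pi0.

    Returns 1.0 (the Benjamini-Hochberg limit) when the estimate is
    unstable: too few p-values, a degenerate spline fit, or an estimate
    outside (0, 1].
    """
    if len(p) < 100:
        return 1.0
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    try:
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
    except Exception:  # pragma: no cover
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0.0 or pi0 > 1.0:
        return 1.0
    return pi0


def qvalues(p: np.ndarray) -> np.ndarray:
    """Storey-Tibshirani q-values (BH step-up scaled by the estimated
    proportion of true nulls)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return _bh_qvalues(p, _estimate_pi0(p))


def fdr_control(
    scan: pd.DataFrame,
    genome_wide_alpha: float = 0.05,
    chromosome_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Attach q-values and significance flags to a scan result.

    Genome-wide q-values are computed over all markers; when
    ``chromosome_subset`` names chromosomes suspected to harbor SI genes,
    q-values are additionally computed within each of those chromosomes
    and flagged at the same level.
    """
    out = scan.copy()
    out["q"] = qvalues(out["p"].to_numpy())
    out["sig_genome"] = out["q"] <= genome_wide_alpha
    out["q_chrom"] = np.nan
    out["sig_chrom"] = False
    if chromosome_subset:
        for chrom in chromosome_subset:
            mask = out["chrom"] == chrom
            if not mask.any():
                continue
            qc = qvalues(out.loc[mask, "p"].to_numpy())
            out.loc[mask, "q_chrom"] = qc
            out.loc[mask, "sig_chrom"] = qc <= genome_wide_alpha
    return out
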