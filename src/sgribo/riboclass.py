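"""Differential expression, translational efficiency, and gene classification.

Paired RNA-seq/Ribo-seq count matrices are analyzed with per-gene
negative-binomial log-linear models (log size-factor offsets, Wald tests),
a DESeq2-style dispersion workflow (gene-wise method-of-moments estimates,
a local lowess mean–dispersion trend, log-space shrinkage toward the
trend), normal-prior MAP shrinkage of fold changes, and a translational-
efficiency interaction model over both assays. Genes are then sorted into
the regulatory categories used in ribosome-profiling studies:

* **TE up/down** — significant translational-efficiency (assay × condition
  interaction) change;
* **Buffering up/down** — mRNA abundance changes without a significant
  ribosome-occupancy change (the occupancy is "buffered");
* **RNA abundance up/down** — concordant significant change in both mRNA
  and ribosome occupancy;
* **Ribo ocp up/down** — significant ribosome-occupancy change.

Flags are set independently; a canonical single label is resolved by a
documented precedence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "shrink_lfc",
    "te_interaction_test",
    "classify_genes",
    "ClassificationThresholds",
    "delta_te_rna_regression",
    "spearman_correlation",
    "bh_adjust",
]

LN2 = np.log(2.0)
MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    For each sample, the median over all-positive genes of the ratio of
    its count to the gene's geometric mean across samples.
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    all_pos = np.all(mat > 0, axis=1)
    if not np.any(all_pos):
        raise ValueError(
            "no gene has positive counts in every sample; supply a filtered "
            "matrix or compute factors on a pseudo-reference explicitly")
    log_geo = np.mean(np.log(mat[all_pos]), axis=1)
    ratios = np.log(mat[all_pos]) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns,
                     name="size_factor")


def _design_groups(metadata: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Integer group id per sample for the design cells used in pooling."""
    key = metadata[factors].astype(str).agg("|".join, axis=1)
    return pd.factorize(key)[0]


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         metadata: pd.DataFrame | None = None,
                         design_factors: list[str] | None = None,
                         span: float = 0.3,
                         shrink_weight: float = 0.35) -> pd.DataFrame:
    """Per-gene NB dispersion α (variance = μ + α μ²).

    Three stages, mirroring the standard RNA-seq workflow with a local
    ("lowess") mean–dispersion fit:

    1. gene-wise method-of-moments on normalized counts, pooled within
       design cells: α̂ = (s² − μ̄/h̄) / μ̄² with h̄ the harmonic-mean size
       factor correction;
    2. a lowess regression of log α̂ on log mean over genes with a
       positive gene-wise estimate (the local trend);
    3. shrinkage of log gene-wise values toward the trend with weight
       ``shrink_weight`` on the gene-wise component; genes without a
       positive gene-wise estimate take the trend value.

    Returns a DataFrame with columns genewise, trend, alpha; all-zero
    genes get NaN and are excluded downstream.
    """
    mat = counts.to_numpy(dtype=float)
    sfv = sf.to_numpy(dtype=float)
    if np.any(sfv <= 0):
        raise ValueError("size factors must be positive")
    norm = mat / sfv[None, :]

    if metadata is not None and design_factors:
        groups = _design_groups(metadata.loc[counts.columns], design_factors)
    else:
        groups = np.zeros(mat.shape[1], dtype=int)

    n_genes = mat.shape[0]
    mean_all = norm.mean(axis=1)
    ss = np.zeros(n_genes)
    mu_w = np.zeros(n_genes)   # Σ n_k μ_k / n  (for the Poisson part)
    df = 0
    n_total = 0
    poisson_part = np.zeros(n_genes)
    for g in np.unique(groups):
        idx = groups == g
        n_k = int(idx.sum())
        if n_k < 2:
            continue
        sub = norm[:, idx]
        mu_k = sub.mean(axis=1)
        ss += ((sub - mu_k[:, None]) ** 2).sum(axis=1)
        # normalized counts have Poisson-scale variance μ/s; average 1/s
        poisson_part += mu_k * np.mean(1.0 / sfv[idx]) * (n_k - 1)
        df += n_k - 1
        n_total += n_k
    if df < 1:
        raise ValueError("need >= 2 replicates in at least one design cell")
    s2 = ss / df
    pois = poisson_part / df
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = (s2 - pois) / mean_all**2
    genewise[~np.isfinite(genewise)] = np.nan

    all_zero = mean_all == 0
    usable = (~all_zero) & np.isfinite(genewise) & (genewise > 0)
    # lowess tracks the median of the gene-wise estimates, which for a
    # chi-square-driven variance at d residual df sits a factor
    # median(chi2_d)/d (~0.84 at d=4) below the mean; scale the fitted
    # trend back up so it targets the true dispersion
    median_bias = (1.0 - 2.0 / (9.0 * df)) ** 3
    trend = np.full(n_genes, np.nan)
    if usable.sum() >= 10:
        x = np.log(mean_all[usable])
        y = np.log(genewise[usable])
        fitted = lowess(y, x, frac=span, return_sorted=False)
        order = np.argsort(x)
        # interpolate/extrapolate trend to every expressed gene
        trend[~all_zero] = np.interp(np.log(mean_all[~all_zero]),
                                     x[order], fitted[order])
        trend = np.where(np.isnan(trend), np.nan,
                         np.exp(trend) / median_bias)
    else:
        # too few genes for a trend: fall back to the median gene-wise value
        fallback = np.nanmedian(genewise[usable]) if usable.any() else MIN_DISPERSION
        trend[~all_zero] = max(fallback, MIN_DISPERSION)

    alpha = np.full(n_genes, np.nan)
    gw = np.clip(genewise, MIN_DISPERSION, None)
    has_gw = usable
    w = shrink_weight
    alpha[has_gw] = np.exp(w * np.log(gw[has_gw])
                           + (1 - w) * np.log(np.clip(trend[has_gw],
                                                      MIN_DISPERSION, None)))
    rest = (~all_zero) & ~has_gw
    alpha[rest] = np.clip(trend[rest], MIN_DISPERSION, None)
    # guard against anticonservative tests: at few replicates the gene-wise
    # estimate is noisy downward, so never let the final value drop below
    # the fitted trend
    floor = np.where(np.isfinite(trend), trend, MIN_DISPERSION)
    alpha = np.fmax(alpha, floor)
    alpha = np.clip(alpha, MIN_DISPERSION, None)
    alpha[all_zero] = np.nan

    out = pd.DataFrame({
        "genewise": np.where(np.isfinite(genewise), np.clip(genewise, 0, None), np.nan),
        "trend": trend,
        "alpha": alpha,
    }, index=counts.index)
    return out


# ---------------------------------------------------------------------------
# per-gene NB GLM Wald tests
# ---------------------------------------------------------------------------

def _fit_gene(y, X, offset, alpha):
    """NB GLM fit; returns (params, bse, converged)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, MIN_DISPERSION))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
        except Exception:
            return None, None, False
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        return None, None, False
    return res.params, res.bse, True


@dataclass
class DEResult:
    """Per-gene differential-expression table plus fit metadata."""

    table: pd.DataFrame           # baseMean, log2FC, lfcSE, stat, p, padj
    size_factors: pd.Series
    dispersions: pd.DataFrame

    def __getitem__(self, col):
        return self.table[col]


def nb_wald_test(counts: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: tuple[str, str, str],
                 sf: pd.Series | None = None,
                 dispersions: pd.DataFrame | None = None) -> DEResult:
    """Per-gene NB Wald test for ``contrast = (factor, test, reference)``.

    Fits log μ = β₀ + β·1[factor = test] with offset log(size factor) per
    gene; Wald statistic β̂/SE against the standard normal, two-sided;
    Benjamini–Hochberg adjusted p over testable genes. ``log2FC`` is β̂ in
    log2 units; ``baseMean`` is the mean of normalized counts over all
    samples. Genes with all-zero counts or non-converged fits get NaN
    statistics and are excluded from the BH adjustment.
    """
    factor, test_level, ref_level = contrast
    metadata = metadata.loc[counts.columns]
    levels = set(metadata[factor])
    if test_level not in levels or ref_level not in levels:
        raise ValueError(f"contrast levels not found in metadata[{factor!r}]")
    keep = metadata[factor].isin([test_level, ref_level])
    counts = counts.loc[:, keep.to_numpy()]
    metadata = metadata.loc[keep]

    if sf is None:
        sf = size_factors(counts)
    sf = sf.loc[counts.columns]
    if dispersions is None:
        dispersions = estimate_dispersions(counts, sf, metadata, [factor])
    alpha = dispersions["alpha"].to_numpy()

    mat = counts.to_numpy(dtype=float)
    offset = np.log(sf.to_numpy(dtype=float))
    x = (metadata[factor] == test_level).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    base_mean = (mat / sf.to_numpy()[None, :]).mean(axis=1)

    n = mat.shape[0]
    lfc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    for g in range(n):
        if not np.isfinite(alpha[g]) or base_mean[g] == 0:
            continue
        params, bse, ok = _fit_gene(mat[g], X, offset, alpha[g])
        if not ok:
            logger.debug("gene %s: NB fit did not converge", counts.index[g])
            continue
        lfc[g] = params[1] / LN2
        se[g] = bse[1] / LN2
    stat = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    padj = np.full(n, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        padj[ok] = bh_adjust(p[ok])
    table = pd.DataFrame({
        "baseMean": base_mean, "log2FC": lfc, "lfcSE": se,
        "stat": stat, "p": p, "padj": padj,
    }, index=counts.index)
    return DEResult(table, sf, dispersions)


def shrink_lfc(result: DEResult | pd.DataFrame,
               prior_sd: float | None = None) -> pd.Series:
    """MAP fold-change shrinkage under a zero-centered normal prior.

    With a normal approximation to the per-gene likelihood
    (β̂ ± SE), the posterior mode is β̂ · σ²/(σ² + SE²) — noisy
    (high-SE, low-count) estimates are pulled toward zero while precise
    ones are nearly untouched. When ``prior_sd`` is None, σ is fit from
    the observed LFC distribution by moment matching:
    σ² = max(mean(β̂²) − mean(SE²), 10⁻⁶). p-values are unaffected.
    """
    table = result.table if isinstance(result, DEResult) else result
    lfc = table["log2FC"].to_numpy(dtype=float)
    se = table["lfcSE"].to_numpy(dtype=float)
    ok = np.isfinite(lfc) & np.isfinite(se)
    if prior_sd is None:
        if not ok.any():
            raise ValueError("no finite LFC estimates to fit a prior")
        var = np.mean(lfc[ok] ** 2) - np.mean(se[ok] ** 2)
        prior_sd = float(np.sqrt(max(var, 1e-6)))
    w = prior_sd**2 / (prior_sd**2 + se**2)
    return pd.Series(lfc * w, index=table.index, name="log2FC_shrunk")


# ---------------------------------------------------------------------------
# translational efficiency
# ---------------------------------------------------------------------------

@dataclass
class TEResult:
    """Per-gene translational-efficiency interaction table."""

    table: pd.DataFrame           # te_log2FC, te_lfcSE, stat, p, padj
    size_factors: pd.Series

    def __getitem__(self, col):
        return self.table[col]


def te_interaction_test(rna_counts: pd.DataFrame, ribo_counts: pd.DataFrame,
                        rna_meta: pd.DataFrame, ribo_meta: pd.DataFrame,
                        contrast: tuple[str, str, str]) -> TEResult:
    """Assay × condition interaction test of translational efficiency.

    Per gene, one NB model over both assays:
    log μ = β₀ + β₁·condition + β₂·assay + β₃·condition·assay, with
    offsets from assay-specific median-of-ratios size factors and a single
    shared dispersion per gene (the simplification used by interaction-
    based TE tools, which stabilizes small-n fits). ``te_log2FC`` is β₃ in
    log2 units — the change in ribosome occupancy not explained by the
    mRNA change; Wald p, BH padj.
    """
    factor, test_level, ref_level = contrast
    if not rna_counts.index.equals(ribo_counts.index):
        raise ValueError("RNA and Ribo matrices must share the gene index")
    rna_meta = rna_meta.loc[rna_counts.columns]
    ribo_meta = ribo_meta.loc[ribo_counts.columns]
    for name, m in (("RNA", rna_meta), ("RIBO", ribo_meta)):
        lv = set(m[factor])
        if not {test_level, ref_level} <= lv:
            raise ValueError(f"{name} samples missing a contrast level of {factor!r}")

    sf_rna = size_factors(rna_counts)
    sf_ribo = size_factors(ribo_counts)

    mat = np.hstack([rna_counts.to_numpy(dtype=float),
                     ribo_counts.to_numpy(dtype=float)])
    sf = np.concatenate([sf_rna.to_numpy(), sf_ribo.to_numpy()])
    cond = np.concatenate([
        (rna_meta[factor] == test_level).to_numpy(dtype=float),
        (ribo_meta[factor] == test_level).to_numpy(dtype=float)])
    assay = np.concatenate([np.zeros(len(rna_meta)), np.ones(len(ribo_meta))])
    X = np.column_stack([np.ones_like(cond), cond, assay, cond * assay])
    offset = np.log(sf)

    # shared per-gene dispersion across the four design cells
    combined = pd.DataFrame(mat, index=rna_counts.index)
    meta_comb = pd.DataFrame({
        "cell": [f"{int(a)}|{int(c)}" for a, c in zip(assay, cond)]},
        index=combined.columns)
    disp = estimate_dispersions(combined, pd.Series(sf, index=combined.columns),
                                meta_comb, ["cell"])
    alpha = disp["alpha"].to_numpy()

    n = mat.shape[0]
    te = np.full(n, np.nan)
    se = np.full(n, np.nan)
    for g in range(n):
        if not np.isfinite(alpha[g]):
            continue
        params, bse, ok = _fit_gene(mat[g], X, offset, alpha[g])
        if not ok:
            continue
        te[g] = params[3] / LN2
        se[g] = bse[3] / LN2
    stat = te / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    padj = np.full(n, np.nan)
    okm = np.isfinite(p)
    if okm.any():
        padj[okm] = bh_adjust(p[okm])
    table = pd.DataFrame({
        "te_log2FC": te, "te_lfcSE": se, "stat": stat, "p": p, "padj": padj,
    }, index=rna_counts.index)
    return TEResult(table, pd.Series(sf))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs for the regulatory-category calls."""

    basemean_min: float = 20.0
    padj_rna: float = 0.01       # buffering (RNA-only change)
    padj_ribo: float = 0.05      # ribo occupancy
    padj_both: float = 0.05      # RNA abundance (both assays)
    padj_te: float = 0.05        # TE interaction


FLAG_COLUMNS = ["te_up", "te_down", "rna_abundance_up", "rna_abundance_down",
                "buffering_up", "buffering_down", "ribo_ocp_up", "ribo_ocp_down"]

# canonical-label precedence; within a category, direction from the LFC sign.
# Buffering outranks TE because an RNA-only change necessarily carries an
# opposite-sign TE interaction — that interaction IS the buffering
# signature, not an independent TE event.
_PRECEDENCE = ["rna_abundance", "buffering", "te", "ribo_ocp"]
_LABELS = {
    "rna_abundance_up": "RNA abundance up", "rna_abundance_down": "RNA abundance down",
    "buffering_up": "Buffering up", "buffering_down": "Buffering down",
    "te_up": "TE up", "te_down": "TE down",
    "ribo_ocp_up": "Ribo ocp up", "ribo_ocp_down": "Ribo ocp down",
}


def classify_genes(rna: DEResult | pd.DataFrame, ribo: DEResult | pd.DataFrame,
                   te: TEResult | pd.DataFrame,
                   thresholds: ClassificationThresholds | None = None
                   ) -> pd.DataFrame:
    """Sort genes into regulatory categories from the three result tables.

    Only genes with RNA baseMean > 20 and Ribo baseMean > 20 are
    considered. Flags (independent):

    * ``buffering_up/down`` — RNA padj < 0.01, RNA LFC ≷ 0, and Ribo padj
      ≥ 0.05 (mRNA changes while occupancy does not);
    * ``ribo_ocp_up/down`` — Ribo padj < 0.05, Ribo LFC ≷ 0;
    * ``rna_abundance_up/down`` — RNA and Ribo padj both < 0.05 with
      concordant LFC signs (discordant significant pairs keep both
      directional flags unset but are marked in ``discordant``);
    * ``te_up/down`` — TE padj < 0.05, TE LFC ≷ 0.

    The canonical ``label`` resolves multi-flag genes by the precedence
    RNA abundance > Buffering > TE > Ribo ocp, or "NS" if no flag is set.
    """
    th = thresholds or ClassificationThresholds()
    rna_t = rna.table if isinstance(rna, DEResult) else rna
    ribo_t = ribo.table if isinstance(ribo, DEResult) else ribo
    te_t = te.table if isinstance(te, TEResult) else te
    if not (rna_t.index.equals(ribo_t.index) and rna_t.index.equals(te_t.index)):
        raise ValueError("RNA, Ribo and TE tables must share the gene index")

    idx = rna_t.index
    passed = ((rna_t["baseMean"] > th.basemean_min)
              & (ribo_t["baseMean"] > th.basemean_min)).to_numpy()

    rna_sig = (rna_t["padj"] < th.padj_rna).fillna(False).to_numpy()
    rna_sig05 = (rna_t["padj"] < th.padj_both).fillna(False).to_numpy()
    ribo_sig = (ribo_t["padj"] < th.padj_ribo).fillna(False).to_numpy()
    ribo_ns = (~(ribo_t["padj"] < th.padj_ribo).fillna(False)).to_numpy()
    te_sig = (te_t["padj"] < th.padj_te).fillna(False).to_numpy()

    rna_lfc = rna_t["log2FC"].to_numpy()
    ribo_lfc = ribo_t["log2FC"].to_numpy()
    te_lfc = te_t["te_log2FC"].to_numpy()

    out = pd.DataFrame(index=idx)
    out["passed_basemean_filter"] = passed
    out["buffering_up"] = passed & rna_sig & (rna_lfc > 0) & ribo_ns
    out["buffering_down"] = passed & rna_sig & (rna_lfc < 0) & ribo_ns
    out["ribo_ocp_up"] = passed & ribo_sig & (ribo_lfc > 0)
    out["ribo_ocp_down"] = passed & ribo_sig & (ribo_lfc < 0)
    both = passed & rna_sig05 & ribo_sig
    concord = np.sign(rna_lfc) == np.sign(ribo_lfc)
    out["rna_abundance_up"] = both & concord & (rna_lfc > 0)
    out["rna_abundance_down"] = both & concord & (rna_lfc < 0)
    out["discordant"] = both & ~concord
    out["te_up"] = passed & te_sig & (te_lfc > 0)
    out["te_down"] = passed & te_sig & (te_lfc < 0)

    labels = np.array(["NS"] * len(idx), dtype=object)
    for cat in reversed(_PRECEDENCE):
        for direction in ("down", "up"):
            flag = f"{cat}_{direction}"
            labels[out[flag].to_numpy()] = _LABELS[flag]
    out["label"] = labels
    return out[["passed_basemean_filter"] + FLAG_COLUMNS + ["discordant", "label"]]


# ---------------------------------------------------------------------------
# correlations and regression
# ---------------------------------------------------------------------------

def delta_te_rna_regression(te_lfc: pd.Series, rna_lfc: pd.Series):
    """OLS of per-gene ΔTE on ΔRNA; returns (slope, intercept, adjusted R²)."""
    joined = pd.concat({"te": te_lfc, "rna": rna_lfc}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 genes with both ΔTE and ΔRNA")
    x = joined["rna"].to_numpy()
    y = joined["te"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("ΔRNA has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared_adj)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
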