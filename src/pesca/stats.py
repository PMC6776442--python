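"""Enrichment statistics for the single-nucleus screen readout.

Given the cell x feature UMI matrix (features are barcodes or GREs) and
per-cell type labels with one designated target type, this module computes:

* log-normalized expression, ``ln(1 + count / cell_total * scale)`` with
  ``scale`` = 10,000 by default;
* the pseudocounted target-enrichment fold per feature,
  ``(mean_target + 0.01) / (mean_rest + 0.01)``;
* pairwise Pearson consistency of the enrichment values computed separately
  from each barcode slot of a GRE triplet, together with a permutation
  (shuffle) null for the mean pairwise correlation;
* a per-feature negative-binomial likelihood-ratio test (NB2 GLM with log
  link and log size-factor offset; full model intercept + target indicator
  vs intercept only; per-feature dispersion by maximum likelihood with a
  method-of-moments fallback; LRT statistic against chi-square(1)), with
  Benjamini-Hochberg correction across features;
* a binomial-thinning power analysis that replaces each count c by a
  Binomial(c, p) draw and reruns the test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

from .barcodes import GreBarcodeMap
from .errors import ValidationError
from .quant import CellByFeatureMatrix


@dataclass
class EnrichmentConfig:
    expr_pseudocount: float = 0.01
    normalize_scale: float = 10_000.0
    use_normalized: bool = True
    fdr_threshold: float = 0.01
    n_shuffles: int = 1000
    size_factors: str = "total"  # "total" | "median_ratio" | "none"
    seed: int = 0

    def __post_init__(self):
        if self.expr_pseudocount <= 0 or self.normalize_scale <= 0:
            raise ValidationError("pseudocount and scale must be positive")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.size_factors not in ("total", "median_ratio", "none"):
            raise ValidationError("size_factors must be total|median_ratio|none")


# ---------------------------------------------------------------------------
# normalization and fold enrichment


def normalize_expression(
    counts,
    scale: float = 10_000.0,
    cell_totals=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-normalize counts: ``ln(1 + count / cell_total * scale)``.

    ``cell_totals`` may supply external totals (e.g. whole-transcriptome
    totals when available); by default totals are row sums of ``counts``
    (viral totals only — documented limitation). Returns ``(values,
    kept_mask)``; rows for zero-total cells are zeroed and flagged False in
    the mask.
    """
    X = counts.to_dense() if isinstance(counts, CellByFeatureMatrix) else np.asarray(
        sp.csr_matrix(counts).todense() if sp.issparse(counts) else counts, dtype=float
    )
    if (X < 0).any():
        raise ValidationError("negative counts")
    totals = X.sum(axis=1) if cell_totals is None else np.asarray(cell_totals, float)
    if totals.shape[0] != X.shape[0]:
        raise ValidationError("cell_totals length mismatch")
    kept = totals > 0
    out = np.zeros_like(X, dtype=float)
    out[kept] = np.log1p(X[kept] / totals[kept, None] * scale)
    return out, kept


def _target_mask(labels, cells, target: str) -> np.ndarray:
    if isinstance(labels, pd.DataFrame):
        lab = labels.set_index("cell_barcode")["cell_type"]
    else:
        lab = pd.Series(labels)
        if cells is not None and len(lab) == len(cells) and not lab.index.isin(cells).all():
            lab.index = cells
    if cells is not None:
        missing = [c for c in cells if c not in lab.index]
        if missing:
            raise ValidationError(f"{len(missing)} cells missing labels")
        lab = lab.loc[cells]
    mask = lab.to_numpy() == target
    if target not in set(lab):
        raise ValidationError(f"target cell type {target!r} absent from labels")
    if mask.all():
        raise ValidationError("no non-target cells")
    return mask


def expression_enrichment(
    values,
    labels,
    target: str,
    pseudocount: float = 0.01,
    cells=None,
    feature_names=None,
) -> pd.Series:
    """Pseudocounted fold enrichment per feature:
    ``(mean over target cells + c) / (mean over non-target cells + c)``."""
    if isinstance(values, CellByFeatureMatrix):
        cells = values.cells
        feature_names = values.features
        values = values.to_dense().astype(float)
    values = np.asarray(values, dtype=float)
    mask = _target_mask(labels, cells, target)
    mean_t = values[mask].mean(axis=0)
    mean_r = values[~mask].mean(axis=0)
    fold = (mean_t + pseudocount) / (mean_r + pseudocount)
    idx = feature_names if feature_names is not None else np.arange(values.shape[1])
    return pd.Series(fold, index=idx, name="fold")


def screen_folds(
    matrix: CellByFeatureMatrix,
    labels,
    gmap: GreBarcodeMap,
    target: str,
    config: EnrichmentConfig | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-barcode and per-GRE pseudocounted fold enrichment.

    With ``config.use_normalized`` (default) counts are log-normalized
    against per-cell viral totals and zero-total cells excluded; GRE-level
    expression is the per-cell sum of its barcode slots (computed on the
    same scale the fold is taken on). Returns (barcode_folds, gre_folds).
    """
    config = config or EnrichmentConfig()
    X = matrix.to_dense().astype(float)
    mask_all = _target_mask(labels, matrix.cells, target)
    if config.use_normalized:
        values, kept = normalize_expression(X, config.normalize_scale)
    else:
        values, kept = X, np.ones(len(X), dtype=bool)
    lab = np.where(mask_all, target, "rest")[kept]
    vals = values[kept]
    barcode_folds = expression_enrichment(
        vals, pd.Series(lab), target, config.expr_pseudocount,
        feature_names=matrix.features,
    )
    feat_index = {f: j for j, f in enumerate(matrix.features)}
    gre_cols = {
        gre: [feat_index[bc] for bc in seqs if bc in feat_index]
        for gre, seqs in gmap.entries.items()
    }
    gre_vals = np.column_stack(
        [vals[:, cols].sum(axis=1) for cols in gre_cols.values()]
    )
    gre_folds = expression_enrichment(
        gre_vals, pd.Series(lab), target, config.expr_pseudocount,
        feature_names=list(gre_cols),
    )
    return barcode_folds, gre_folds


# ---------------------------------------------------------------------------
# barcode-triplet consistency and shuffle null


def _slot_vectors(values: pd.Series, gmap: GreBarcodeMap) -> np.ndarray:
    """Arrange per-barcode values into a (n_gres, slots) matrix in map
    order."""
    slots = gmap.slot_matrix()
    width = gmap.barcodes_per_gre
    if any(len(s) != width for s in slots):
        raise ValidationError("all GREs must have the same number of barcodes")
    try:
        return np.array([[values[bc] for bc in row] for row in slots], dtype=float)
    except KeyError as exc:
        raise ValidationError(f"missing enrichment value for barcode {exc}") from exc


def barcode_consistency(
    per_barcode_values: pd.Series,
    gmap: GreBarcodeMap,
) -> pd.DataFrame:
    """All pairwise Pearson correlations between the barcode-slot vectors.

    For triplets this returns three rows (slot pairs) with two-sided p;
    zero-variance vectors yield ``r = NaN`` (undefined), reported as such.
    """
    mat = _slot_vectors(per_barcode_values, gmap)
    rows = []
    for i, j in itertools.combinations(range(mat.shape[1]), 2):
        x, y = mat[:, i], mat[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"slot_i": i, "slot_j": j, "r": np.nan, "p": np.nan})
        else:
            r, p = sps.pearsonr(x, y)
            rows.append({"slot_i": i, "slot_j": j, "r": r, "p": p})
    return pd.DataFrame(rows)


def mean_pairwise_r(mat: np.ndarray) -> float:
    """Mean Pearson r over all column pairs of a (n, k) matrix."""
    k = mat.shape[1]
    cors = np.corrcoef(mat, rowvar=False)
    iu = np.triu_indices(k, 1)
    return float(cors[iu].mean())


@dataclass
class ShuffleNullResult:
    null_means: np.ndarray
    observed: float

    @property
    def mean(self) -> float:
        return float(self.null_means.mean())

    @property
    def sd(self) -> float:
        return float(self.null_means.std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "observed_mean_r": self.observed,
            "null_mean": self.mean,
            "null_sd": self.sd,
            "n_shuffles": int(len(self.null_means)),
        }


def shuffle_null(
    per_barcode_values: pd.Series,
    gmap: GreBarcodeMap,
    n_shuffles: int = 1000,
    seed: int | None = 0,
) -> ShuffleNullResult:
    """Permutation null for the mean pairwise slot correlation.

    Each shuffle permutes the assignment of enrichment values to
    (GRE, slot) positions uniformly at random, breaking the triplet
    structure; the mean pairwise Pearson r is recorded per shuffle.
    """
    mat = _slot_vectors(per_barcode_values, gmap)
    observed = mean_pairwise_r(mat)
    flat = mat.ravel()
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(flat).reshape(mat.shape)
        nulls[s] = mean_pairwise_r(perm)
    return ShuffleNullResult(null_means=nulls, observed=observed)


# ---------------------------------------------------------------------------
# negative-binomial likelihood-ratio test


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (mean mu, variance mu + alpha*mu^2)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_nb(y: np.ndarray, x: np.ndarray | None, log_sf: np.ndarray):
    """Maximize the NB2 likelihood over (intercept[, group coef], log alpha).

    ``x`` is the 0/1 target indicator or None for the intercept-only model.
    Returns (loglik, params, converged).
    """
    y = np.asarray(y, dtype=float)
    mean_all = max(y.mean(), 1e-8)
    if x is not None:
        m1 = max(y[x == 1].mean(), 1e-8)
        m0 = max(y[x == 0].mean(), 1e-8)
        beta0 = [np.log(m0), np.log(m1) - np.log(m0)]
    else:
        beta0 = [np.log(mean_all)]
    var = y.var()
    alpha_mom = max((var - mean_all) / mean_all**2, 1e-4)
    la0 = float(np.clip(np.log(alpha_mom), -10.0, 4.0))

    design = (
        np.column_stack([np.ones_like(y), x.astype(float)])
        if x is not None
        else np.ones((len(y), 1))
    )

    def negloglik_and_grad(params):
        beta, la = params[:-1], params[-1]
        la = np.clip(la, -12.0, 6.0)
        alpha = np.exp(la)
        r = 1.0 / alpha
        eta = design @ beta + log_sf
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        ll = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(np.maximum(mu, 1e-300) / (r + mu))
        ).sum()
        # d ll / d eta_i = (y - mu) * r / (r + mu)
        deta = (y - mu) * r / (r + mu)
        gbeta = design.T @ deta
        # d ll / d r, chained through r = exp(-la) => d/d la = -r * d/d r
        dr = (
            special.digamma(y + r)
            - special.digamma(r)
            + np.log(r / (r + mu))
            + 1.0
            - (y + r) / (r + mu)
        ).sum()
        gla = -r * dr
        return -ll, -np.concatenate([gbeta, [gla]])

    x0 = np.array(beta0 + [la0])
    res = optimize.minimize(
        negloglik_and_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(None, None)] * len(beta0) + [(-12.0, 6.0)],
        options={"maxiter": 200},
    )
    ok = bool(res.success) or res.fun < negloglik_and_grad(x0)[0] + 1e-9
    if not res.success:
        res2 = optimize.minimize(
            lambda p: negloglik_and_grad(p)[0], res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
        ok = True
    return -float(res.fun), res.x, ok


def compute_size_factors(counts: np.ndarray, method: str = "total") -> np.ndarray:
    """Per-cell size factors: total-count (default, scaled to median total)
    or DESeq-style median-of-ratios; zero-total cells get size factor NaN
    and are excluded from tests."""
    totals = counts.sum(axis=1).astype(float)
    if method == "none":
        return np.ones(len(totals))
    if method == "total":
        pos = totals > 0
        sf = np.full(len(totals), np.nan)
        sf[pos] = totals[pos] / np.median(totals[pos])
        return sf
    if method == "median_ratio":
        logs = np.log(counts + 0.5)
        ref = logs.mean(axis=0)
        ratios = logs - ref[None, :]
        sf = np.exp(np.median(ratios, axis=1))
        sf[totals <= 0] = np.nan
        return sf / np.nanmedian(sf)
    raise ValidationError(f"unknown size factor method {method!r}")


def nb_lrt_test(
    counts,
    labels,
    target: str,
    config: EnrichmentConfig | None = None,
    cells=None,
    feature_names=None,
    size_factors_values=None,
) -> pd.DataFrame:
    """Per-feature NB2 likelihood-ratio test for target-cell enrichment.

    ``size_factors_values`` supplies per-cell size factors computed
    externally (e.g. from the full library matrix when testing a feature
    subset — totals of a few enriched features would otherwise absorb the
    group effect into the offset); by default they are computed from
    ``counts`` with ``config.size_factors``.

    Returns the enrichment table (one row per feature): raw group means,
    pseudocounted fold (on normalized expression when
    ``config.use_normalized``), log2 fold, LRT statistic, p, BH q,
    detection count, and the ``enriched`` call (q < threshold and
    fold > 1). Features whose fits fail are flagged ``converged=False``
    with ``p = NaN`` and excluded from the BH denominator.
    """
    config = config or EnrichmentConfig()
    if isinstance(counts, CellByFeatureMatrix):
        cells = counts.cells
        feature_names = counts.features
        X = counts.to_dense()
    else:
        X = np.asarray(
            sp.csr_matrix(counts).todense() if sp.issparse(counts) else counts
        )
    if not np.issubdtype(X.dtype, np.integer):
        if not np.allclose(X, np.round(X)):
            raise ValidationError("NB test requires integer counts")
        X = np.round(X).astype(np.int64)
    mask = _target_mask(labels, cells, target)
    if feature_names is None:
        feature_names = [str(j) for j in range(X.shape[1])]

    if size_factors_values is not None:
        sf = np.asarray(size_factors_values, dtype=float)
        if sf.shape[0] != X.shape[0]:
            raise ValidationError("size_factors_values length mismatch")
    else:
        sf = compute_size_factors(X, config.size_factors)
    keep_cells = ~np.isnan(sf)
    Xk, sfk, maskk = X[keep_cells], sf[keep_cells], mask[keep_cells]
    if maskk.sum() == 0 or (~maskk).sum() == 0:
        raise ValidationError("need >= 1 target and >= 1 non-target cell with counts")
    log_sf = np.log(sfk)
    indicator = maskk.astype(float)

    if config.use_normalized:
        norm, _ = normalize_expression(X, config.normalize_scale)
        fold = expression_enrichment(
            norm, pd.Series(np.where(mask, target, "rest")), target,
            config.expr_pseudocount, feature_names=feature_names,
        ).to_numpy()
    else:
        fold = expression_enrichment(
            X.astype(float), pd.Series(np.where(mask, target, "rest")), target,
            config.expr_pseudocount, feature_names=feature_names,
        ).to_numpy()

    n_feat = X.shape[1]
    stat = np.zeros(n_feat)
    pvals = np.full(n_feat, np.nan)
    converged = np.ones(n_feat, dtype=bool)
    for j in range(n_feat):
        y = Xk[:, j]
        if y.sum() == 0:
            pvals[j] = 1.0  # no information
            continue
        try:
            ll_full, _, ok_f = _fit_nb(y, indicator, log_sf)
            ll_red, _, ok_r = _fit_nb(y, None, log_sf)
        except (ValueError, FloatingPointError):
            converged[j] = False
            continue
        if not (ok_f and ok_r):
            converged[j] = False
            continue
        stat[j] = max(2.0 * (ll_full - ll_red), 0.0)
        pvals[j] = sps.chi2.sf(stat[j], df=1)

    qvals = np.full(n_feat, np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    mean_t = X[mask].mean(axis=0)
    mean_r = X[~mask].mean(axis=0)
    table = pd.DataFrame(
        {
            "mean_target": mean_t,
            "mean_rest": mean_r,
            "fold": fold,
            "log2_fold": np.log2(fold),
            "lrt_stat": stat,
            "p": pvals,
            "q": qvals,
            "n_cells_detected": (X > 0).sum(axis=0),
            "converged": converged,
        },
        index=pd.Index(feature_names, name="feature"),
    )
    table["enriched"] = (table["q"] < config.fdr_threshold) & (table["fold"] > 1)
    return table


# ---------------------------------------------------------------------------
# binomial-thinning power analysis


def subsample_power(
    counts,
    labels,
    target: str,
    probabilities=(0.5, 0.25, 0.125, 0.0625),
    replicates: int = 10,
    seed: int | None = 0,
    config: EnrichmentConfig | None = None,
    cells=None,
    feature_names=None,
    size_factors_values=None,
) -> pd.DataFrame:
    """Binomial thinning power analysis.

    Each count c is replaced by a Binomial(c, p) draw for every probability
    in ``probabilities`` (replicated ``replicates`` times with independent
    derived seeds), and the NB-LRT rerun. Returns a long table with one row
    per (feature, probability, replicate): fold, q, detected.
    """
    config = config or EnrichmentConfig()
    if isinstance(counts, CellByFeatureMatrix):
        cells = counts.cells
        feature_names = counts.features
        X = counts.to_dense()
    else:
        X = np.asarray(
            sp.csr_matrix(counts).todense() if sp.issparse(counts) else counts
        ).astype(np.int64)
    probabilities = list(probabilities)
    if any(not (0.0 < p <= 1.0) for p in probabilities):
        raise ValidationError("subsampling probabilities must be in (0, 1]")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(probabilities) * replicates)
    rows = []
    for pi, p in enumerate(probabilities):
        for rep in range(replicates):
            rng = np.random.default_rng(streams[pi * replicates + rep])
            thinned = X if p == 1.0 else rng.binomial(X, p)
            table = nb_lrt_test(
                thinned, labels, target, config,
                cells=cells, feature_names=feature_names,
                size_factors_values=size_factors_values,
            )
            for feat, row in table.iterrows():
                rows.append(
                    {
                        "feature": feat,
                        "probability": p,
                        "replicate": rep,
                        "fold": row["fold"],
                        "q": row["q"],
                        "detected": bool(row["enriched"]),
                    }
                )
    return pd.DataFrame(rows)


def detection_rates(report: pd.DataFrame) -> pd.DataFrame:
    """Per (feature, probability) mean detection rate from a power table."""
    return (
        report.groupby(["feature", "probability"])["detected"]
        .mean()
        .rename("detection_rate")
        .reset_index()
    )
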