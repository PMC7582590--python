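"""Count normalization and negative-binomial differential expression.

This module implements the count-level statistics used throughout the
pipeline: counts-per-million (CPM) scaling, low-expression filtering,
trimmed-mean-of-M-values (TMM) normalization factors, method-of-moments
dispersion estimation with shrinkage toward a common value, a double-tail
NB exact test for two-group contrasts, and a translational-efficiency (TE)
interaction test that models matched mRNA and ribosome-protected-fragment
(RPF) counts with an NB log-linear model.

Conventions
-----------
* Counts are ``pandas.DataFrame`` objects with genes as rows and samples as
  columns; :class:`CountMatrix` attaches per-sample metadata (assay,
  condition, replicate).
* TMM factors returned here are *total* normalization factors: they absorb
  both sequencing depth and composition bias, and are rescaled so that
  their geometric mean is 1.  Normalized counts are obtained by dividing a
  sample's counts by its factor.
* The NB distribution is parameterized by mean ``mu`` and dispersion
  ``phi`` with ``var = mu + phi * mu**2``; ``phi = 0`` is the Poisson
  limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
"""BH false-discovery-rate threshold for calling significance."""

DEFAULT_LFC_THRESHOLD = 0.5
"""Minimum absolute log2 fold change for calling significance."""

PSEUDO_COUNT = 0.125
"""Pseudo-count (on the normalized-count scale) used when reporting log2
fold changes.  P-values never involve the pseudo-count."""

_TIE_REL_TOL = 1e-9
"""Relative cushion used when summing outcome probabilities that are less
than or equal to the observed outcome's probability.  Symmetric splits are
exact mathematical ties and must not be dropped by floating-point jitter."""

ASSAYS = ("mRNA", "RPF", "smallRNA")


# ---------------------------------------------------------------------------
# Count matrix container


@dataclass
class CountMatrix:
    """Integer genes x samples matrix with per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes as index, samples as columns.
    samples
        Metadata indexed by sample name with columns ``assay``,
        ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample names are not unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_for(self, condition: str | None = None,
                    assay: str | None = None) -> list[str]:
        """Sample names matching the given condition and/or assay."""
        sel = pd.Series(True, index=self.samples.index)
        if condition is not None:
            sel &= self.samples["condition"] == condition
        if assay is not None:
            sel &= self.samples["assay"] == assay
        return list(self.samples.index[sel])

    def subset(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[samples].copy(),
                           self.samples.loc[samples].copy())

    @staticmethod
    def from_frame(counts: pd.DataFrame) -> "CountMatrix":
        """Build a CountMatrix from columns named ``assay_condition_rep``."""
        meta = []
        for name in counts.columns:
            parts = str(name).split("_")
            if len(parts) < 3:
                raise ValueError(
                    f"sample name {name!r} is not of the form assay_condition_rep")
            meta.append({"assay": parts[0],
                         "condition": "_".join(parts[1:-1]),
                         "replicate": parts[-1]})
        samples = pd.DataFrame(meta, index=counts.columns)
        return CountMatrix(counts.astype(np.int64), samples)


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


# ---------------------------------------------------------------------------
# CPM and filtering


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count / library_total * 1e6`` per column."""
    frame = _as_frame(counts)
    totals = frame.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total library: {list(zero.index)}")
    return frame / totals * 1e6


def filter_low(counts: CountMatrix, cpm_threshold: float = 0.5,
               min_samples: int = 4) -> CountMatrix:
    """Remove genes without ``CPM >= cpm_threshold`` in >= min_samples samples."""
    if cpm_threshold < 0:
        raise ValueError("cpm_threshold must be >= 0")
    keep = (cpm(counts) >= cpm_threshold).sum(axis=1) >= min_samples
    if cpm_threshold == 0:
        keep[:] = True
    return CountMatrix(counts.counts.loc[keep].copy(), counts.samples.copy())


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(counts: CountMatrix | pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of all samples' 75th percentiles.  For each sample, M- and
    A-values against the reference are computed over genes positive in
    both; genes in the upper/lower ``trim_m`` tail of M and ``trim_a`` tail
    of A are discarded, and the factor is ``2**(weighted mean of M)`` with
    inverse asymptotic-variance (delta-method) precision weights.  Factors
    are rescaled to geometric mean 1 and absorb both depth and composition.
    """
    frame = _as_frame(counts).astype(float)
    if frame.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = frame.sum(axis=0)
    q75 = cpm(frame).quantile(0.75, axis=0)
    ref = (q75 - q75.mean()).abs().idxmin()

    log2 = np.log2
    factors = {}
    cr = frame[ref].to_numpy()
    nr = lib[ref]
    for s in frame.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        cs = frame[s].to_numpy()
        ns = lib[s]
        pos = (cs > 0) & (cr > 0)
        m = log2(cs[pos]) - log2(cr[pos])
        a = 0.5 * (log2(cs[pos]) + log2(cr[pos]))
        w = 1.0 / ((ns - cs[pos]) / (ns * cs[pos])
                   + (nr - cr[pos]) / (nr * cr[pos]))
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.sum() < 10:
            warnings.warn(
                f"fewer than 10 genes survive TMM trimming for sample {s}; "
                "using untrimmed mean", RuntimeWarning)
            keep = np.ones_like(keep, dtype=bool)
        factors[s] = float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))
    fac = pd.Series(factors).loc[frame.columns]
    fac /= np.exp(np.mean(np.log(fac)))
    return fac


def normalized_counts(counts: CountMatrix | pd.DataFrame,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by their per-sample TMM factor."""
    frame = _as_frame(counts)
    if factors is None:
        factors = tmm_factors(frame)
    return frame / factors


# ---------------------------------------------------------------------------
# Dispersion estimation


def estimate_dispersion(counts: CountMatrix, conditions: list[str] | None = None,
                        factors: pd.Series | None = None,
                        moderation_weight: float | None = None
                        ) -> tuple[pd.Series, float]:
    """Method-of-moments NB dispersion with shrinkage to a common value.

    Counts are normalized by TMM factors; within-condition means are
    removed and the pooled residual variance ``s2`` gives the gene-wise
    moment estimate ``phi_hat = (s2 - m) / m**2`` (floored at 0, with ``m``
    the gene's overall normalized mean).  The common dispersion is the
    median of the positive gene-wise estimates, and the returned per-gene
    values are ``w * phi_hat + (1 - w) * common`` with default
    ``w = n_reps / (n_reps + 4)``.

    Returns ``(per_gene_phi, common_phi)``.
    """
    if conditions is None:
        conditions = list(dict.fromkeys(counts.samples["condition"]))
    groups = {c: counts.samples_for(condition=c) for c in conditions}
    groups = {c: s for c, s in groups.items() if s}
    n_samples = sum(len(s) for s in groups.values())
    n_groups = len(groups)
    if n_samples - n_groups < 1:
        raise ValueError(
            "dispersion estimation needs replication in at least one condition; "
            "supply a dispersion value instead")
    y = normalized_counts(counts.subset([s for g in groups.values() for s in g]),
                          factors)
    resid_ss = np.zeros(len(y))
    for c, ss in groups.items():
        block = y[ss]
        resid_ss += ((block.sub(block.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    s2 = resid_ss / (n_samples - n_groups)
    m = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = (s2 - m) / (m ** 2)
    phi_hat = phi_hat.replace([np.inf, -np.inf], 0.0).fillna(0.0).clip(lower=0.0)
    positive = phi_hat[phi_hat > 0]
    common = float(positive.median()) if len(positive) else 0.0
    if moderation_weight is None:
        n_reps = n_samples / n_groups
        moderation_weight = n_reps / (n_reps + 4.0)
    phi = moderation_weight * phi_hat + (1 - moderation_weight) * common
    return phi, common


# ---------------------------------------------------------------------------
# Double-tail NB exact test


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if mean <= 0:
        out = np.full(np.shape(k), -np.inf)
        out[np.asarray(k) == 0] = 0.0
        return out
    if phi <= 0:
        return stats.poisson.logpmf(k, mean)
    size = 1.0 / phi
    return stats.nbinom.logpmf(k, size, size / (size + mean))


def exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int,
                    phi: float) -> float:
    """Double-tail exact p-value for two NB group sums.

    Conditional on the total ``S = sum_a + sum_b``, every split ``(k, S-k)``
    is assigned probability proportional to ``f_A(k) * f_B(S-k)`` where the
    group sums are NB with means ``n * mu`` (``mu = S / (n_a + n_b)``) and
    dispersions ``phi / n``.  The p-value is the total probability of
    splits no more likely than the observed one (ties included with a
    relative tolerance), capped at 1.
    """
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    log_joint = (_nb_logpmf(k, n_a * mu, phi / n_a)
                 + _nb_logpmf(k[::-1], n_b * mu, phi / n_b))
    log_joint = log_joint - logsumexp(log_joint)
    obs = log_joint[int(sum_a)]
    tail = log_joint[log_joint <= obs + _TIE_REL_TOL]
    return float(min(1.0, np.exp(logsumexp(tail))))


def exact_test(counts: CountMatrix, group_a: list[str], group_b: list[str],
               phi: pd.Series | float, factors: pd.Series | None = None,
               alpha: float = DEFAULT_ALPHA,
               lfc_threshold: float = DEFAULT_LFC_THRESHOLD) -> pd.DataFrame:
    """NB exact test of ``group_a`` (treated) versus ``group_b`` (control).

    Counts are scaled to a common effective library size (the geometric
    mean of the samples' effective sizes), rounded, and summed within each
    group; p-values come from :func:`exact_nb_pvalue` and are adjusted
    across genes with Benjamini-Hochberg.  The reported log2 fold change
    uses a fixed pseudo-count of :data:`PSEUDO_COUNT` on the per-sample
    normalized scale; significance requires ``fdr < alpha`` and
    ``|log2fc| > lfc_threshold``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    sub = counts.subset(list(group_a) + list(group_b))
    if factors is None:
        factors = tmm_factors(sub)
    factors = factors.loc[sub.counts.columns]
    # factors have geometric mean 1 and absorb depth, so dividing by them
    # already places every sample on the common effective library scale
    scaled = (sub.counts / factors).round().astype(np.int64)
    sum_a = scaled[list(group_a)].sum(axis=1)
    sum_b = scaled[list(group_b)].sum(axis=1)
    n_a, n_b = len(group_a), len(group_b)

    phi_s = (pd.Series(float(phi), index=sub.counts.index)
             if np.isscalar(phi) else pd.Series(phi).loc[sub.counts.index])
    pvals = np.array([
        exact_nb_pvalue(int(sa), int(sb), n_a, n_b, float(ph))
        for sa, sb, ph in zip(sum_a, sum_b, phi_s)
    ])
    log2fc = np.log2((sum_a / n_a + PSEUDO_COUNT)
                     / (sum_b / n_b + PSEUDO_COUNT))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    result = pd.DataFrame({
        "log2fc": log2fc,
        "pvalue": pvals,
        "fdr": fdr,
        "mean_cpm": cpm(sub).mean(axis=1),
    }, index=sub.counts.index)
    result["significant"] = (result["fdr"] < alpha) & \
        (result["log2fc"].abs() > lfc_threshold)
    return result


# ---------------------------------------------------------------------------
# Translational-efficiency interaction test


def te_test(mrna: CountMatrix, rpf: CountMatrix, treated: str, control: str,
            phi: pd.Series | float, factors: pd.Series | None = None,
            alpha: float = DEFAULT_ALPHA,
            lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
            maxiter: int = 100) -> pd.DataFrame:
    """Test the assay x condition interaction in an NB log-linear model.

    Per gene, counts from both assays and both conditions are fit to
    ``mean = exp(offset + b0 + b_assay*I(RPF) + b_cond*I(treated) +
    b_int*I(RPF)*I(treated))`` by iteratively reweighted least squares with
    the supplied fixed dispersion, where the offset is the log TMM factor.
    ``dlog2_te = b_int / ln 2`` and the p-value is a 1-df likelihood-ratio
    test of ``b_int = 0``.  Genes that fail to converge are flagged and
    excluded from the BH adjustment.
    """
    import statsmodels.api as sm

    genes = mrna.counts.index.intersection(rpf.counts.index)
    cols = {}
    design_rows = []
    for cm_, is_rpf in ((mrna, 0), (rpf, 1)):
        for cond, is_treat in ((control, 0), (treated, 1)):
            for s in cm_.samples_for(condition=cond):
                cols[(is_rpf, is_treat, s)] = cm_.counts.loc[genes, s].to_numpy()
                design_rows.append((is_rpf, is_treat))
    if not design_rows:
        raise ValueError("no samples found for the requested conditions")
    y_all = np.column_stack(list(cols.values()))
    design_rows = np.asarray(design_rows, dtype=float)
    x_full = np.column_stack([
        np.ones(len(design_rows)),
        design_rows[:, 0],
        design_rows[:, 1],
        design_rows[:, 0] * design_rows[:, 1],
    ])
    x_reduced = x_full[:, :3]

    if factors is None:
        joint = pd.DataFrame(
            y_all, index=genes,
            columns=[f"{'RPF' if r else 'mRNA'}.{s}" for (r, t, s) in cols])
        factors_vec = tmm_factors(joint).to_numpy()
    else:
        factors_vec = np.array([factors[s] for (_, _, s) in cols])
    offset = np.log(factors_vec)

    phi_s = (pd.Series(float(phi), index=genes)
             if np.isscalar(phi) else pd.Series(phi).loc[genes])

    dlog2te = np.full(len(genes), np.nan)
    pvals = np.full(len(genes), np.nan)
    converged = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        y = y_all[i]
        fam = sm.families.NegativeBinomial(alpha=max(float(phi_s.iloc[i]), 1e-6))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(y, x_full, family=fam, offset=offset).fit(
                    maxiter=maxiter)
                red = sm.GLM(y, x_reduced, family=fam, offset=offset).fit(
                    maxiter=maxiter)
            if not (full.converged and red.converged):
                continue
        except Exception:
            continue
        converged[i] = True
        dlog2te[i] = full.params[3] / np.log(2)
        lrt = max(0.0, 2.0 * (full.llf - red.llf))
        pvals[i] = stats.chi2.sf(lrt, df=1)

    fdr = np.full(len(genes), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    result = pd.DataFrame({
        "dlog2_te": dlog2te,
        "pvalue": pvals,
        "fdr": fdr,
        "converged": converged,
    }, index=genes)
    result["significant"] = (result["fdr"] < alpha) & \
        (result["dlog2_te"].abs() > lfc_threshold)
    result["significant"] = result["significant"].fillna(False).astype(bool)
    return result
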