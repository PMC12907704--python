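"""Tumor-specific DMP discovery with empirical-Bayes moderated statistics.

Per-probe group-means linear models are fitted to M-values under cell-means
coding (one indicator column per group, no intercept). Contrast t-statistics
are moderated by shrinking per-probe residual variances toward a pooled prior
estimated by the method of moments on log variances — the standard moderated-t
framework for microarray-scale differential analysis. Two contrasts drive
tumor-specific selection: tumor tissue vs adjacent normal tissue (the signal
of interest) and normal tissue vs healthy plasma (tissue-specific background
to be excluded, since cfDNA aggregates DNA from many tissues).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from cfdeconv.errors import ValidationError

logger = logging.getLogger(__name__)

TUMOR_ADJ_P = 0.01
TUMOR_MIN_ABS_LFC = 0.2
TISSUE_ADJ_P = 0.05
TISSUE_MAX_ABS_LFC = 0.01
TOP_N = 500


@dataclass(frozen=True)
class GroupDesign:
    """Cell-means design: each sample belongs to exactly one group.

    ``groups`` is the ordered list of distinct group names; ``labels`` maps
    each sample (in matrix column order) to its group.
    """

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    groups: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels must have equal length")
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        object.__setattr__(self, "groups", tuple(seen))
        if any(self.group_sizes[g] < 1 for g in self.groups):
            raise ValidationError("every group needs at least one sample")

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def indicator(self) -> np.ndarray:
        """Sample x group 0/1 indicator matrix."""
        index = {g: j for j, g in enumerate(self.groups)}
        design = np.zeros((len(self.labels), len(self.groups)))
        for i, lab in enumerate(self.labels):
            design[i, index[lab]] = 1.0
        return design


@dataclass(frozen=True)
class ProbeFit:
    """Per-probe least-squares fit under a cell-means design."""

    coef: pd.DataFrame  # probe x group mean M-values
    sigma2: pd.Series  # residual variance per probe
    df_resid: int
    group_sizes: dict[str, int]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.coef.columns)


@dataclass(frozen=True)
class ModeratedPrior:
    """Scaled inverse-chi-square prior on residual variances."""

    d0: float  # prior degrees of freedom; may be inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValidationError("prior df must be positive")
        if not self.s0_sq > 0:
            raise ValidationError("prior variance must be positive")


def fit_group_means(m_matrix: pd.DataFrame, design: GroupDesign) -> ProbeFit:
    """Fit per-probe group means and pooled residual variance.

    Under cell-means coding the least-squares coefficient for each group is
    the within-group mean; the residual variance is the pooled within-group
    sum of squares over ``n - k`` degrees of freedom.
    """
    if list(m_matrix.columns) != list(design.sample_ids):
        raise ValidationError("matrix columns do not match design sample_ids")
    n, k = len(design.sample_ids), len(design.groups)
    df_resid = n - k
    if df_resid < 1:
        raise ValidationError(
            f"residual degrees of freedom must be >= 1 (n={n}, groups={k})"
        )
    values = m_matrix.to_numpy(dtype=float)
    ind = design.indicator()  # n x k
    sizes = ind.sum(axis=0)  # k
    coef = (values @ ind) / sizes  # probes x k: within-group means
    fitted = coef @ ind.T
    rss = ((values - fitted) ** 2).sum(axis=1)
    sigma2 = rss / df_resid
    return ProbeFit(
        coef=pd.DataFrame(coef, index=m_matrix.index, columns=list(design.groups)),
        sigma2=pd.Series(sigma2, index=m_matrix.index, name="sigma2"),
        df_resid=df_resid,
        group_sizes=design.group_sizes,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(fit: ProbeFit) -> ModeratedPrior:
    """Estimate the variance prior (d0, s0_sq) by moments on log variances.

    Residual variances are modeled as ``s0_sq * F(df_resid, d0)``. Matching
    the sample mean and variance of ``log(sigma2)`` to digamma/trigamma
    expressions yields the prior; when the observed spread of log variances
    does not exceed what sampling alone explains, the prior df is infinite
    (complete shrinkage to a common variance).
    """
    s2 = np.maximum(fit.sigma2.to_numpy(dtype=float), 0.0)
    if np.count_nonzero(s2) < 2:
        raise ValidationError(
            "need >= 2 probes with positive residual variance; input is degenerate"
        )
    med = float(np.median(s2))
    if med == 0:
        raise ValidationError(
            "more than half of the residual variances are zero; input is degenerate"
        )
    if (s2 == 0).any():
        logger.warning("zero residual variances offset away from zero")
        s2 = np.maximum(s2, 1e-5 * med)
    df = float(fit.df_resid)
    z = np.log(s2)
    # center by the known chi-square contribution of the residual df
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
        )
    else:
        # spread of log variances is fully explained by sampling: complete
        # shrinkage to the pooled (arithmetic mean) variance
        d0 = np.inf
        s0_sq = float(s2.mean())
    return ModeratedPrior(d0=d0, s0_sq=s0_sq)


def moderated_contrast(
    fit: ProbeFit,
    prior: ModeratedPrior,
    contrast: np.ndarray | list[float],
) -> pd.DataFrame:
    """Moderated t-test of a group contrast for every probe.

    Posterior variances shrink each probe's residual variance toward the
    prior: ``s2_post = (d0*s0_sq + df*sigma2) / (d0 + df)``. The moderated t
    is the contrast estimate over its posterior standard error, with
    ``d0 + df`` degrees of freedom (normal reference when d0 is infinite).

    Returns a DataFrame indexed by probe with columns ``logFC``, ``t``,
    ``P.Value`` and ``adj.P.Val`` (Benjamini-Hochberg across all probes).
    """
    c = np.asarray(contrast, dtype=float)
    groups = fit.groups
    if c.shape != (len(groups),):
        raise ValidationError(
            f"contrast length {c.size} does not match number of groups {len(groups)}"
        )
    logfc = fit.coef.to_numpy() @ c
    sizes = np.array([fit.group_sizes[g] for g in groups], dtype=float)
    stdev_unscaled = float(np.sqrt(np.sum(c**2 / sizes)))
    df = float(fit.df_resid)
    sigma2 = fit.sigma2.to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(sigma2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * sigma2) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = stdev_unscaled * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(logfc == 0.0, 0.0, np.divide(logfc, se))
    t = np.where(np.isnan(t), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(logfc == 0.0, 1.0, p)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "P.Value": p,
            "adj.P.Val": bh_adjust(p),
        },
        index=fit.coef.index,
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, tie-safe)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def select_tumor_specific(
    tumor: pd.DataFrame,
    tissue: pd.DataFrame,
    p_tumor: float = TUMOR_ADJ_P,
    lfc_tumor: float = TUMOR_MIN_ABS_LFC,
    p_tissue: float = TISSUE_ADJ_P,
    lfc_tissue: float = TISSUE_MAX_ABS_LFC,
    top_n: int = TOP_N,
) -> list[str]:
    """Select up to ``top_n`` tumor-specific DMPs ranked by |logFC|.

    A probe qualifies when it is strongly differential between tumor and
    adjacent normal tissue (adjusted p < ``p_tumor`` and |logFC| >
    ``lfc_tumor``) while NOT tissue-specific: its normal-tissue vs plasma
    contrast is non-significant (adjusted p >= ``p_tissue``) or negligible
    (|logFC| < ``lfc_tissue``). Survivors are ranked by the tumor-contrast
    |logFC| descending (probe ID breaks ties) and capped at ``top_n``.
    """
    if not tumor.index.equals(tissue.index):
        tissue = tissue.reindex(tumor.index)
        if tissue["logFC"].isna().any():
            raise ValidationError("tumor and tissue tables cover different probes")
    tumor_pass = (tumor["adj.P.Val"] < p_tumor) & (tumor["logFC"].abs() > lfc_tumor)
    tissue_nonspecific = (tissue["adj.P.Val"] >= p_tissue) | (
        tissue["logFC"].abs() < lfc_tissue
    )
    candidates = tumor.loc[tumor_pass & tissue_nonspecific].copy()
    if candidates.empty:
        warnings.warn("no probe passed the tumor-specific selection", stacklevel=2)
        return []
    candidates["abs_lfc"] = candidates["logFC"].abs()
    candidates.index.name = "probe_id"
    ranked = candidates.reset_index().sort_values(
        ["abs_lfc", "probe_id"], ascending=[False, True], kind="stable"
    )
    return ranked["probe_id"].head(top_n).tolist()


def two_contrast_analysis(
    m_matrix: pd.DataFrame,
    design: GroupDesign,
    tumor_group: str = "tumor_tissue",
    normal_group: str = "normal_tissue",
    plasma_group: str = "normal_plasma",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the model and return (tumor vs normal tissue, normal tissue vs plasma)
    moderated result tables sharing one variance prior."""
    fit = fit_group_means(m_matrix, design)
    prior = estimate_prior(fit)
    groups = list(fit.groups)
    for g in (tumor_group, normal_group, plasma_group):
        if g not in groups:
            raise ValidationError(f"group '{g}' not present in design ({groups})")

    def contrast_vec(pos: str, neg: str) -> np.ndarray:
        c = np.zeros(len(groups))
        c[groups.index(pos)] = 1.0
        c[groups.index(neg)] = -1.0
        return c

    tumor_results = moderated_contrast(fit, prior, contrast_vec(tumor_group, normal_group))
    tissue_results = moderated_contrast(fit, prior, contrast_vec(normal_group, plasma_group))
    return tumor_results, tissue_results
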