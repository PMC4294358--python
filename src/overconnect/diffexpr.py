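"""Case-control differential expression with an empirical-Bayes moderated t-test.

The pipeline consumes a normalized, log2-scale expression matrix (genes x
samples) with a two-group (case/control) sample sheet and produces per-gene
fold changes, moderated t statistics, Benjamini-Hochberg adjusted p-values and
significance calls under joint FDR and fold-change gates.

Variance moderation follows the standard empirical-Bayes scheme for microarray
linear models: per-gene residual variances are shrunk toward a common prior
variance ``s0_sq`` with prior degrees of freedom ``d0``, both estimated by
method of moments on the log variances; the moderated t statistic is referred
to a Student t distribution with ``df + d0`` degrees of freedom (standard
normal when ``d0`` is infinite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")

DE_COLUMNS = [
    "gene_id", "fc", "log2fc", "t_mod", "df_total",
    "p_raw", "p_adj", "significant", "direction",
]


class ExpressionLoadError(ValueError):
    """Raised when an expression matrix or sample sheet fails validation."""


@dataclass
class ExpressionStudy:
    """A validated two-group expression study.

    ``values`` is a genes x samples array of log2-scale normalized
    intensities; ``group_of`` assigns every sample to ``case`` or ``control``.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionLoadError("duplicate gene identifiers in study")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionLoadError("duplicate sample identifiers in study")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ExpressionLoadError(
                f"samples missing from the sample sheet: {', '.join(missing)}"
            )
        bad = {g for g in self.group_of.values()} - set(GROUPS)
        if bad:
            raise ExpressionLoadError(f"unknown group labels: {sorted(bad)}")
        for grp in GROUPS:
            n = sum(1 for s in self.sample_ids if self.group_of[s] == grp)
            if n < 2:
                raise ExpressionLoadError(
                    f"group '{grp}' has {n} samples; at least 2 are required"
                )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionLoadError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ExpressionLoadError("matrix contains missing values")

    def sample_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group],
            dtype=int,
        )

    @property
    def n_case(self) -> int:
        return len(self.sample_indices("case"))

    @property
    def n_control(self) -> int:
        return len(self.sample_indices("control"))


@dataclass
class TwoGroupFit:
    """Per-gene summaries of the case-vs-control linear fit."""

    gene_ids: list[str]
    log2fc: np.ndarray   # mean(case) - mean(control), log2 scale
    s2: np.ndarray       # pooled within-group variance
    df: int              # residual degrees of freedom, n_case + n_control - 2
    se_unit: float       # sqrt(1/n_case + 1/n_control)


@dataclass
class VariancePrior:
    """Empirical-Bayes variance prior and the shrunken posterior variances."""

    d0: float            # prior degrees of freedom (may be math.inf)
    s0_sq: float         # prior variance
    s2_post: np.ndarray  # (d0*s0_sq + df*s2) / (d0 + df)


@dataclass
class DESummary:
    """Tally of significant genes, split by direction."""

    n_total_de: int
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.n_total_de != self.n_up + self.n_down:
            raise ValueError("n_total_de must equal n_up + n_down")


def load_expression(matrix_path: str | Path, samplesheet_path: str | Path,
                    *, drop_missing: bool = True) -> ExpressionStudy:
    """Load a genes x samples TSV and its case/control sample sheet.

    The matrix has a ``gene_id`` first column and one column per sample; the
    sheet has columns ``sample`` and ``group`` with values case/control.
    Genes with missing values are dropped with a warning rather than imputed.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if matrix.shape[1] < 2:
        raise ExpressionLoadError(f"{matrix_path}: no sample columns found")
    gene_col = matrix.columns[0]
    genes = matrix[gene_col].tolist()
    dup = matrix[gene_col][matrix[gene_col].duplicated()].unique()
    if len(dup):
        raise ExpressionLoadError(
            f"{matrix_path}: duplicated gene id(s): {', '.join(map(str, dup))}"
        )
    value_block = matrix.drop(columns=[gene_col])
    try:
        values = value_block.astype(float).to_numpy()
    except (TypeError, ValueError):
        for col in value_block.columns:
            coerced = pd.to_numeric(value_block[col], errors="coerce")
            bad = coerced.isna() & value_block[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ExpressionLoadError(
                    f"{matrix_path}: non-numeric value "
                    f"{value_block[col].iloc[row]!r} at gene {genes[row]!r}, "
                    f"sample {col!r}"
                ) from None
        raise
    if drop_missing:
        keep = ~np.isnan(values).any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropping %d gene(s) with missing values", n_dropped)
            values = values[keep]
            genes = [g for g, k in zip(genes, keep) if k]

    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ExpressionLoadError(
                f"{samplesheet_path}: missing required column '{col}'"
            )
    group_of = dict(zip(sheet["sample"], sheet["group"]))
    sample_ids = list(value_block.columns)
    orphans = [s for s in sample_ids if s not in group_of]
    if orphans:
        raise ExpressionLoadError(
            f"samples in matrix but not in sample sheet: {', '.join(orphans)}"
        )
    group_of = {s: group_of[s] for s in sample_ids}
    return ExpressionStudy(genes, values, sample_ids, group_of)


def fit_two_group(study: ExpressionStudy) -> TwoGroupFit:
    """Per-gene log2 fold change and pooled within-group variance.

    log2fc = mean(case) - mean(control); s2 is the pooled variance with
    ``n_case + n_control - 2`` degrees of freedom.
    """
    ci = study.sample_indices("case")
    ki = study.sample_indices("control")
    case = study.values[:, ci]
    ctrl = study.values[:, ki]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    df = len(ci) + len(ki) - 2
    rss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss += ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = rss / df
    se_unit = math.sqrt(1.0 / len(ci) + 1.0 / len(ki))
    return TwoGroupFit(list(study.gene_ids), log2fc, s2, df, se_unit)


def _trigamma_inverse(y: float, *, tol: float = 1e-10, max_iter: int = 80) -> float:
    # Newton iteration for trigamma(x) = y; trigamma is monotone decreasing.
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        step = (tri - y) / float(special.polygamma(2, x))
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * x:
            break
    return x


def moderate_variances(s2: np.ndarray, df: int) -> VariancePrior:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits the prior (``d0``, ``s0_sq``) by method of moments on the log
    variances: under the model, ``log(s2)`` has mean
    ``log(s0_sq) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)`` and
    excess variance ``trigamma(d0/2)`` beyond the sampling term
    ``trigamma(df/2)``. When the observed spread does not exceed the sampling
    term the prior is degenerate (``d0 = inf``); with literally identical
    inputs the prior sits at that common value, so they are returned
    unchanged.
    """
    s2 = np.asarray(s2, dtype=float)
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    positive = s2 > 0
    if positive.sum() < 2:
        raise ValueError(
            "need at least 2 genes with positive variance to fit the prior"
        )
    z = np.log(s2[positive])
    half_df = df / 2.0
    e = z - special.digamma(half_df) + math.log(half_df)
    emean = float(e.mean())
    spread = float(e.var(ddof=1))
    evar = spread - float(special.polygamma(1, half_df))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    elif spread < 1e-12:
        # All variances identical: a point prior at that common value.
        d0 = math.inf
        s0_sq = math.exp(float(z.mean()))
    else:
        # Spread within chi^2 sampling expectation: degenerate prior at the
        # bias-corrected location of the log-variance distribution.
        d0 = math.inf
        s0_sq = math.exp(emean)
    s2_post = _posterior_variances(s2, df, d0, s0_sq)
    return VariancePrior(d0, s0_sq, s2_post)


def _posterior_variances(s2: np.ndarray, df: int, d0: float, s0_sq: float) -> np.ndarray:
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


def moderated_t(log2fc: np.ndarray, s2_post: np.ndarray, se_unit: float,
                df_total: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistic and two-sided p-value.

    ``t = log2fc / (sqrt(s2_post) * se_unit)`` referred to Student t with
    ``df_total`` degrees of freedom, or the standard normal when ``df_total``
    is infinite.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    if np.any(s2_post <= 0):
        raise ValueError("posterior variances must be strictly positive")
    t = log2fc / (np.sqrt(s2_post) * se_unit)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, np.minimum(p, 1.0)


def adjust_fdr_bh(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw.copy()
    if np.any((p_raw < 0) | (p_raw > 1)) or np.isnan(p_raw).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p_raw, method="fdr_bh")[1]


def call_significant(de: pd.DataFrame, alpha: float = 0.05,
                     fc_threshold: float = 2.0) -> tuple[pd.DataFrame, DESummary]:
    """Apply the joint FDR and fold-change gates and tally directions.

    A gene is significant iff ``p_adj <= alpha`` and ``max(fc, 1/fc) >=
    fc_threshold`` (equivalently ``|log2fc| >= log2(fc_threshold)``); the
    direction is up for fc > 1, down otherwise.
    """
    de = de.copy()
    fc = de["fc"].to_numpy(dtype=float)
    fold = np.maximum(fc, 1.0 / fc)
    sig = (de["p_adj"].to_numpy(dtype=float) <= alpha) & (fold >= fc_threshold)
    direction = np.where(~sig, "none", np.where(fc > 1.0, "up", "down"))
    de["significant"] = sig
    de["direction"] = direction
    n_up = int((direction == "up").sum())
    n_down = int((direction == "down").sum())
    return de, DESummary(n_up + n_down, n_up, n_down)


def run_de(study: ExpressionStudy, alpha: float = 0.05, fc_threshold: float = 2.0,
           *, moderate: bool = True) -> tuple[pd.DataFrame, DESummary]:
    """Full differential-expression pass over a two-group study.

    With ``moderate=False`` the prior df is forced to zero and the result is
    the classical pooled two-sample t-test.
    """
    fit = fit_two_group(study)
    if moderate:
        prior = moderate_variances(fit.s2, fit.df)
        d0 = prior.d0
        s2_post = prior.s2_post
    else:
        d0 = 0.0
        s2_post = fit.s2
    df_total = fit.df + d0
    t, p_raw = moderated_t(fit.log2fc, s2_post, fit.se_unit, df_total)
    de = pd.DataFrame({
        "gene_id": fit.gene_ids,
        "fc": np.exp2(fit.log2fc),
        "log2fc": fit.log2fc,
        "t_mod": t,
        "df_total": df_total,
        "p_raw": p_raw,
        "p_adj": adjust_fdr_bh(p_raw),
    })
    return call_significant(de, alpha=alpha, fc_threshold=fc_threshold)


def write_de_table(de: pd.DataFrame, out_path: str | Path) -> None:
    de.loc[:, DE_COLUMNS].to_csv(out_path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    if de["significant"].dtype == object:
        de["significant"] = de["significant"].map(
            {"True": True, "False": False}).astype(bool)
    return de


def write_summary(summary: DESummary, out_path: str | Path) -> None:
    pd.DataFrame(
        [[summary.n_total_de, summary.n_up, summary.n_down]],
        columns=["n_total_de", "n_up", "n_down"],
    ).to_csv(out_path, sep="\t", index=False)
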