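"""Two-group differential expression with fold-change gating.

Expression values are on a linear scale (RPKM/FPKM-like).  For a contrast
(e.g. treatment: stress vs control) each gene gets a Welch unequal-variance
t-test (pooled-variance behind a flag), a log2 fold change of linear-scale
group means (pseudo-count guarded), BH adjustment across genes, and a
volcano class:

    up   : significant and log2fc >= +log2(fold_threshold)
    down : significant and log2fc <= -log2(fold_threshold)
    ns   : otherwise

The defaults mirror the study design this emulates: alpha 0.01 and a
2-fold change gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

#: pseudo-count guarding zero linear-scale means in the fold change
EPSILON = 1e-9


class DesignError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes × samples linear-scale expression with per-sample metadata."""

    values: pd.DataFrame          # index gene_id, columns sample_id
    sample_meta: pd.DataFrame     # index sample_id; columns tissue/treatment/genotype

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise DesignError(f"samples without metadata: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DesignError("expression matrix contains non-finite values")

    @classmethod
    def read(cls, expr_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        return cls(values=values, sample_meta=meta)

    def select(self, attribute: str, level: str) -> pd.DataFrame:
        samples = self.sample_meta.index[self.sample_meta[attribute] == level]
        return self.values[list(samples)]


def welch_t(group_a, group_b, pooled: bool = False):
    """(t, df, p) for the two-sided two-sample t-test.

    Welch by default: t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)
    with Welch–Satterthwaite degrees of freedom.  Degenerate inputs (both
    groups constant) return (0, df, 1) when equal and (inf-sign, df, 0)
    when unequal rather than raising.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError("each group needs >=2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DesignError("non-finite expression values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df_fallback = len(a) + len(b) - 2
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(df_fallback), 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * np.inf, float(df_fallback), 0.0
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def log2_fold_change(mean_stress: float, mean_control: float) -> float:
    return float(np.log2((mean_stress + EPSILON) / (mean_control + EPSILON)))


def _classify(p_or_q: float, log2fc: float, alpha: float, log2_thresh: float) -> str:
    if p_or_q < alpha and log2fc >= log2_thresh:
        return "up"
    if p_or_q < alpha and log2fc <= -log2_thresh:
        return "down"
    return "ns"


def run_de(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str, str],
    alpha: float = 0.01,
    fold_threshold: float = 2.0,
    use_fdr: bool = True,
    pooled: bool = False,
    log_scale_test: bool = True,
) -> pd.DataFrame:
    """Per-gene DE results for contrast ``(attribute, level_stress, level_control)``.

    The t-test runs on log2-transformed values by default (expression noise
    is approximately Gaussian on the log scale, so this is where the
    parametric test is calibrated); the fold change is always the ratio of
    linear-scale group means.  Returns a frame ordered by ascending p (ties
    by gene_id) with columns gene_id, log2fc, t, df, p, q, class.
    """
    attribute, level_a, level_b = contrast
    grp_a = matrix.select(attribute, level_a)
    grp_b = matrix.select(attribute, level_b)
    for level, grp in ((level_a, grp_a), (level_b, grp_b)):
        if grp.shape[1] < 2:
            raise DesignError(
                f"contrast level {attribute}={level!r} selects "
                f"{grp.shape[1]} sample(s); need >=2"
            )
    a = grp_a.to_numpy(dtype=float)
    b = grp_b.to_numpy(dtype=float)
    if log_scale_test:
        ta, tb = np.log2(a + EPSILON), np.log2(b + EPSILON)
    else:
        ta, tb = a, b
    # vectorised Welch across genes; degenerate rows patched afterwards
    res = stats.ttest_ind(ta, tb, axis=1, equal_var=pooled)
    t = np.array(res.statistic, dtype=float)
    df = np.array(res.df, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    va, vb = ta.var(axis=1, ddof=1), tb.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    same = degenerate & (ta.mean(axis=1) == tb.mean(axis=1))
    diff = degenerate & ~same
    t[same], p[same] = 0.0, 1.0
    t[diff] = np.sign(ta.mean(axis=1)[diff] - tb.mean(axis=1)[diff]) * np.inf
    p[diff] = np.nextafter(0.0, 1.0)  # BH domain is (0, 1]
    df[degenerate] = a.shape[1] + b.shape[1] - 2
    log2fc = np.log2((a.mean(axis=1) + EPSILON) / (b.mean(axis=1) + EPSILON))
    q = bh_fdr(p)
    crit = q if use_fdr else p
    log2_thresh = float(np.log2(fold_threshold))
    classes = [
        _classify(c, fc, alpha, log2_thresh) for c, fc in zip(crit, log2fc)
    ]
    out = pd.DataFrame({
        "gene_id": matrix.values.index,
        "log2fc": log2fc, "t": t, "df": df, "p": p, "q": q, "class": classes,
    })
    return out.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)


def volcano_classify(
    results: pd.DataFrame,
    alpha: float,
    fold_threshold: float,
    use_fdr: bool = True,
) -> dict[str, int]:
    """Recount up/down/ns under (possibly different) thresholds; total conserved."""
    crit = results["q"] if use_fdr else results["p"]
    log2_thresh = float(np.log2(fold_threshold))
    counts = {"up": 0, "down": 0, "ns": 0}
    for c, fc in zip(crit, results["log2fc"]):
        counts[_classify(c, fc, alpha, log2_thresh)] += 1
    return counts
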