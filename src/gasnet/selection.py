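"""Gene selection: expression filters, differential expression, the
two-comparison intersection rule for invasion-specific genes, and the
driver-score filter.

The differential-expression test is deliberately pluggable: the default is
a two-sample t-test on log2(x + 1) with Benjamini-Hochberg correction, and
its TSV output format matches what an external edgeR run would produce, so
either can feed the downstream stages.
"""

from __future__ import annotations

import logging


import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DE_COLUMNS, DriverTable, ExpressionMatrix, PhenotypeLabels, ValidationError

logger = logging.getLogger(__name__)


def filter_unexpressed_by_count(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose median raw read count is zero across all samples."""
    if expr.raw_counts is None:
        raise ValidationError(
            "raw counts unavailable; use filter_unexpressed_by_fpkm on the "
            "abundance matrix instead"
        )
    med = expr.raw_counts.median(axis=1)
    keep = med.index[med > 0]
    if len(keep) == 0:
        logger.warning("all genes have median raw count 0")
    return ExpressionMatrix(expr.values.loc[keep], expr.raw_counts.loc[keep])


def filter_unexpressed_by_fpkm(expr: ExpressionMatrix,
                               threshold: float = 1.0) -> set[str]:
    """Genes with median abundance >= threshold (complement of the
    "median FPKM < 1" removal rule)."""
    med = expr.median_per_gene()
    return set(med.index[med >= threshold])


def differential_expression(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    method: str = "log_t_test",
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential expression for the labels' comparison.

    Returns one row per gene with columns (gene, log2_fc, p_value, fdr):
    log2 fold change of case over control means with an ``epsilon``
    pseudocount, a two-sided p-value from a two-sample t-test on
    log2(x + 1)-transformed abundances, and Benjamini-Hochberg FDR over
    all tested genes.
    """
    if method != "log_t_test":
        raise ValidationError(f"unknown DE method {method!r}")
    labels.validate_against(expr)
    control_s, case_s = labels.comparison_samples()
    if len(control_s) < 2 or len(case_s) < 2:
        raise ValidationError("each comparison class needs >= 2 samples")
    control = expr.values[control_s].to_numpy(dtype=float)
    case = expr.values[case_s].to_numpy(dtype=float)

    log2fc = np.log2(case.mean(axis=1) + epsilon) - np.log2(
        control.mean(axis=1) + epsilon
    )
    t, p = stats.ttest_ind(
        np.log2(case + 1.0), np.log2(control + 1.0), axis=1
    )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-both-groups ties
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log2_fc": log2fc,
            "p_value": p,
            "fdr": fdr,
        },
        columns=list(DE_COLUMNS),
    )


def select_invasive_specific(
    de_case_vs_intermediate: pd.DataFrame,
    de_case_vs_control: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes significant in BOTH comparisons, annotated up/down.

    A gene qualifies when |log2FC| > log2(fc_threshold) and
    fdr < fdr_threshold in both DE tables. Genes whose fold-change signs
    disagree between the comparisons are dropped with a warning.
    Returns a DataFrame (gene, direction) sorted by gene id.
    """
    a = de_case_vs_intermediate.set_index("gene")
    b = de_case_vs_control.set_index("gene")
    if set(a.index) != set(b.index):
        raise ValidationError("the two DE tables cover different gene universes")
    b = b.loc[a.index]
    log2_cut = np.log2(fc_threshold)
    hits_a = (a["log2_fc"].abs() > log2_cut) & (a["fdr"] < fdr_threshold)
    hits_b = (b["log2_fc"].abs() > log2_cut) & (b["fdr"] < fdr_threshold)
    both = hits_a & hits_b
    sign_a = np.sign(a.loc[both, "log2_fc"])
    sign_b = np.sign(b.loc[both, "log2_fc"])
    discordant = sign_a != sign_b
    if discordant.any():
        logger.warning(
            "dropping %d genes with discordant fold-change signs: %s",
            int(discordant.sum()), sorted(sign_a.index[discordant])[:5],
        )
    kept = sign_b.index[~discordant]
    out = pd.DataFrame(
        {
            "gene": kept,
            "direction": np.where(b.loc[kept, "log2_fc"] > 0, "up", "down"),
        }
    )
    return out.sort_values("gene").reset_index(drop=True)


def filter_drivers(
    drivers: DriverTable,
    score_threshold: float = 0.8,
    p_threshold: float = 0.05,
    strict: bool = True,
) -> set[str]:
    """Putative driver genes: score above ``score_threshold`` and p-value
    below ``p_threshold`` (strict inequalities by default)."""
    t = drivers.table
    if strict:
        mask = (t["score"] > score_threshold) & (t["p_value"] < p_threshold)
    else:
        mask = (t["score"] >= score_threshold) & (t["p_value"] < p_threshold)
    return set(t.index[mask])
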