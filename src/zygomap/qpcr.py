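"""Relative copy-number quantification from qPCR Ct tables (delta-delta-Ct).

Per biological sample, the gene-of-interest Ct (arithmetic mean over
technical replicates) is normalised against a nuclear single-copy reference
gene (delta Ct).  Group means of delta Ct are contrasted between mutant and
wild-type plants (delta-delta Ct) and transformed to a linear copy-number
ratio 2**(-ddCt).  An unpaired t-test decides significance per gene.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

CT_COLUMNS = ["sample", "group", "gene"]
GROUPS = ("mutant", "wildtype")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table: sample, group, gene, then one column per technical
    replicate (ct1..ctN)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: Ct table lacks columns {missing}")
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    if not ct_cols:
        raise ValidationError(f"{path}: no technical-replicate columns (ct1..ctN)")
    bad = df[ct_cols].stack(future_stack=True).dropna()
    if not np.isfinite(bad).all() or (bad <= 0).any():
        raise ValidationError(f"{path}: Ct values must be finite and positive")
    return df


def _tech_means(table: pd.DataFrame) -> pd.DataFrame:
    ct_cols = [c for c in table.columns if c.startswith("ct")]
    out = table[CT_COLUMNS].copy()
    out["ct_mean"] = table[ct_cols].mean(axis=1, skipna=True)
    return out


def delta_ct(table: pd.DataFrame, gene: str, reference_gene: str) -> pd.DataFrame:
    """Per-sample delta Ct = mean Ct(gene) - mean Ct(reference gene).

    Samples lacking the reference gene are excluded with a warning.
    """
    means = _tech_means(table)
    goi = means[means["gene"] == gene].set_index("sample")
    ref = means[means["gene"] == reference_gene].set_index("sample")
    if goi.empty:
        raise ValidationError(f"gene {gene!r} absent from Ct table")
    if ref.empty:
        raise ValidationError(f"reference gene {reference_gene!r} absent from Ct table")
    dropped = sorted(set(goi.index) - set(ref.index))
    if dropped:
        warnings.warn(
            f"samples without reference gene {reference_gene!r} excluded: {dropped}",
            stacklevel=2,
        )
    common = goi.index.intersection(ref.index)
    out = pd.DataFrame(
        {
            "sample": common,
            "group": goi.loc[common, "group"].to_numpy(),
            "gene": gene,
            "delta_ct": (goi.loc[common, "ct_mean"] - ref.loc[common, "ct_mean"]).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def relative_copy_number(
    delta_ct_mutant: Sequence[float],
    delta_ct_wildtype: Sequence[float],
) -> tuple[float, float]:
    """(delta-delta Ct, 2**(-ddCt) ratio) between the two groups."""
    m = np.asarray(delta_ct_mutant, dtype=float)
    w = np.asarray(delta_ct_wildtype, dtype=float)
    if m.size == 0 or w.size == 0:
        raise ValidationError("both groups must be non-empty")
    ddct = float(m.mean() - w.mean())
    return ddct, float(2.0 ** (-ddct))


def significance_stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def group_difference_test(
    delta_ct_mutant: Sequence[float],
    delta_ct_wildtype: Sequence[float],
    welch: bool = False,
) -> tuple[float, str]:
    """Two-sided unpaired t-test of the group delta-Ct means.

    Pooled-variance (classic) by default; Welch via ``welch=True``.  Two
    degenerate zero-variance groups with equal means give p = 1.
    """
    m = np.asarray(delta_ct_mutant, dtype=float)
    w = np.asarray(delta_ct_wildtype, dtype=float)
    if m.size < 2 or w.size < 2:
        raise ValidationError("each group needs at least two biological replicates")
    if m.std(ddof=1) == 0.0 and w.std(ddof=1) == 0.0:
        p = 1.0 if m.mean() == w.mean() else 0.0
        return p, significance_stars(p)
    p = float(stats.ttest_ind(m, w, equal_var=not welch).pvalue)
    return p, significance_stars(p)


def copy_number_report(
    table: pd.DataFrame,
    genes: Sequence[str],
    reference_gene: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene ddCt, copy-number ratio, p-value and stars."""
    rows = []
    for gene in genes:
        d = delta_ct(table, gene, reference_gene)
        m = d.loc[d["group"] == "mutant", "delta_ct"].to_numpy()
        w = d.loc[d["group"] == "wildtype", "delta_ct"].to_numpy()
        ddct, ratio = relative_copy_number(m, w)
        p, star = group_difference_test(m, w, welch=welch)
        rows.append((gene, ddct, ratio, p, star))
    return pd.DataFrame(rows, columns=["gene", "ddct", "ratio", "p_value", "stars"])
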