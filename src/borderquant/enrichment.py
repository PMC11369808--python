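"""2x2 contingency enrichment: Fisher's exact test, odds ratios with Woolf
confidence intervals, cluster and differential-expression overlap summaries,
and forest-plot data.

The gene-centric table for a cluster c over a gene universe U is

                 has peak    no peak
    in c            a           b
    not in c        c           d

with OR = (a*d)/(b*c) > 1 indicating enrichment of peak-associated genes in
the cluster. Peak-wise percentages (share of all peaks assigned to genes of
a cluster) are reported descriptively alongside, as in the source figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peak_annotation import GenomeAnnotation


@dataclass
class ContingencyTable:
    """2x2 counts; rows: in-set vs not, cols: with-peak/in-cluster vs not."""

    a: int
    b: int
    c: int
    d: int
    unit: str = "genes"

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (the standard definition). A table with a zero margin carries no
    information and returns p = 1 with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def odds_ratio(
    table: ContingencyTable, zero_correction: bool = True
) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with Woolf 95% CI.

    With ``zero_correction`` the Haldane–Anscombe rule adds 0.5 to every cell
    when any cell is zero; with it disabled a zero b*c yields an explicit
    infinite OR (CI undefined -> (nan, inf)).
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if zero_correction and 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0.0:
        if a * d == 0.0:
            return np.nan, np.nan, np.nan
        return np.inf, np.nan, np.inf
    oratio = (a * d) / (b * c)
    if a * d == 0.0:
        return 0.0, 0.0, np.nan
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        oratio,
        float(oratio * np.exp(-1.96 * se)),
        float(oratio * np.exp(1.96 * se)),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _enrich_row(n_in_with: int, n_in: int, n_with: int, n_universe: int) -> dict:
    t = ContingencyTable(
        a=n_in_with,
        b=n_in - n_in_with,
        c=n_with - n_in_with,
        d=n_universe - n_in - (n_with - n_in_with),
    )
    oratio, lo, hi = odds_ratio(t)
    return dict(odds_ratio=oratio, ci_low=lo, ci_high=hi, p=fisher_exact(t))


def cluster_enrichment(
    assoc: pd.DataFrame,
    clusters: dict[str, list[str]],
    universe: list[str] | GenomeAnnotation | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-cluster peak/gene enrichment summary.

    ``assoc`` is the nearest-TSS association table (``peak_id, gene_id``,
    null gene_id for unassignable peaks — those peaks still count in the
    peak denominator). For each cluster the summary reports

    * ``percent_of_peaks`` — share of all peaks assigned to genes of the
      cluster (exact and integer-rounded);
    * ``percent_of_genes`` — share of cluster genes with at least one peak;
    * a gene-centric 2x2 over the universe -> Fisher p, OR, Woolf CI.

    The universe defaults to the union of all cluster gene lists and all
    assigned genes. Empty clusters are skipped with a warning.
    """
    if len(assoc) == 0:
        raise ValueError("empty association table")
    if isinstance(universe, GenomeAnnotation):
        universe = list(universe.genes["gene_id"])
    n_peaks_total = len(assoc)
    assigned = assoc.dropna(subset=["gene_id"])
    peaked_genes = set(assigned["gene_id"])
    if universe is None:
        universe_set = peaked_genes.union(*[set(g) for g in clusters.values()])
    else:
        universe_set = set(universe)
        for name, genes in clusters.items():
            extra = set(genes) - universe_set
            if extra:
                raise ValueError(f"cluster {name!r} has genes outside the universe: {sorted(extra)[:5]}")

    rows = []
    for name, genes in clusters.items():
        genes = set(genes)
        if not genes:
            warnings.warn(f"cluster {name!r} is empty; skipped", stacklevel=2)
            continue
        n_peaks_in = int(assigned["gene_id"].isin(genes).sum())
        genes_with_peak = len(genes & peaked_genes)
        pct_peaks = 100.0 * n_peaks_in / n_peaks_total
        pct_genes = 100.0 * genes_with_peak / len(genes)
        stats_row = _enrich_row(
            genes_with_peak, len(genes), len(peaked_genes & universe_set), len(universe_set)
        )
        rows.append(
            dict(
                cluster=name,
                n_peaks=n_peaks_in,
                n_genes=len(genes),
                n_genes_with_peak=genes_with_peak,
                percent_of_peaks=pct_peaks,
                percent_of_peaks_int=int(round(pct_peaks)),
                percent_of_genes=pct_genes,
                percent_of_genes_int=int(round(pct_genes)),
                **stats_row,
            )
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_adj"] = bh_adjust(out["p"])
    return out


def filter_de_genes(
    de: pd.DataFrame,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.5,
    absolute: bool = False,
) -> pd.DataFrame:
    """Differentially expressed genes: ``padj < padj_cut`` (strict) and
    ``log2fc > lfc_cut`` (strict; ``|log2fc|`` with ``absolute=True``)."""
    lfc = de["log2fc"].abs() if absolute else de["log2fc"]
    return de[(de["padj"] < padj_cut) & (lfc > lfc_cut)]


def de_overlap_enrichment(
    de: pd.DataFrame,
    assoc: pd.DataFrame,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.5,
    absolute: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Enrichment of peak-associated genes among differentially expressed genes.

    The 2x2 is gene-centric over all genes of the DE table (rows: DE vs not,
    cols: has associated peak vs not). Returns ``(result, de_gene_table)``.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    de_set = filter_de_genes(de, padj_cut, lfc_cut, absolute)
    peaked = set(assoc.dropna(subset=["gene_id"])["gene_id"])
    all_genes = set(de["gene_id"])
    de_genes = set(de_set["gene_id"])
    if not de_genes:
        warnings.warn("no genes pass the DE filter", stacklevel=2)
        return dict(n_de=0, n_de_with_peak=0, odds_ratio=np.nan,
                    ci_low=np.nan, ci_high=np.nan, p=1.0), de_set
    stats_row = _enrich_row(
        len(de_genes & peaked), len(de_genes), len(all_genes & peaked), len(all_genes)
    )
    result = dict(n_de=len(de_genes), n_de_with_peak=len(de_genes & peaked), **stats_row)
    return result, de_set


def forest_data(results: pd.DataFrame, label_col: str = "cluster") -> pd.DataFrame:
    """Plotting-ready forest table: (label, OR, ci_low, ci_high, p)."""
    cols = [label_col, "odds_ratio", "ci_low", "ci_high", "p"]
    return results[cols].rename(columns={label_col: "label"}).reset_index(drop=True)


def plot_forest(forest: pd.DataFrame, ax=None):
    """Draw a forest plot of odds ratios with 95% CIs (log-scaled x axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * len(forest) + 1))
    y = np.arange(len(forest))[::-1]
    ax.hlines(y, forest["ci_low"], forest["ci_high"], color="0.3")
    ax.plot(forest["odds_ratio"], y, "s", color="0.1")
    ax.axvline(1.0, color="0.6", ls="--", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(forest["label"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    return ax
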