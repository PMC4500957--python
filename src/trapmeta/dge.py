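"""Host trap-vs-leaf differential gene expression.

Per-gene read counts become RPKM (reads per kilobase of exon per million
mapped reads), are quantile-normalized across samples, and genes passing
the expressed-gene rule (more than one unique mapped read and more than
five total mapped reads) are tested: per-pair log2 ratios of trap over
corresponding leaf (with a pseudo-offset against zeros), a paired t-test
across pairs, and DEG selection at p < 0.05 — optionally with an
additional |mean log2 ratio| cutoff for the strongly-changed subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import paired_t_test, round_half_up


@dataclass
class ExpressionMatrix:
    """gene x sample expression: raw totals, unique counts, lengths and
    the derived RPKM / quantile-normalized layers."""

    total: pd.DataFrame         # total mapped reads
    unique: pd.DataFrame        # uniquely mapped reads
    lengths: pd.Series          # exon length, bp
    library_totals: pd.Series | None = None
    rpkm_values: pd.DataFrame | None = None
    qnorm_values: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.unique.values > self.total.values).any():
            raise ValueError("unique counts cannot exceed total counts")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.total.columns)

    @property
    def genes(self) -> pd.Index:
        return self.total.index


def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_totals: pd.Series | None = None) -> pd.DataFrame:
    """RPKM = 1e9 * count / (gene length * library mapped total)."""
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    if (library_totals <= 0).any():
        raise ValueError("library totals must be positive")
    lengths = lengths.reindex(counts.index)
    return 1e9 * counts.div(lengths, axis=0).div(library_totals, axis=1)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization.

    Each column is ranked, and every value is replaced by the mean over
    columns of the values at its rank; ties receive the mean of their tied
    ranks' reference values. Afterwards all columns share one multiset of
    values and within-column order is preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = matrix.values.astype(float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    ranks = matrix.rank(method="average")  # 1-based, ties averaged
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        r = ranks.iloc[:, j].values
        lo = np.floor(r).astype(int) - 1
        hi = np.ceil(r).astype(int) - 1
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def expressed_filter(matrix: ExpressionMatrix, min_unique: int = 1,
                     min_total: int = 5, mode: str = "union") -> pd.Index:
    """Genes eligible for testing: more than ``min_unique`` unique reads
    and more than ``min_total`` total reads — in at least one sample
    (``union``, default) or in every sample (``all``)."""
    ok = (matrix.unique > min_unique) & (matrix.total > min_total)
    if mode == "union":
        keep = ok.any(axis=1)
    elif mode == "all":
        keep = ok.all(axis=1)
    else:
        raise ValueError("mode must be 'union' or 'all'")
    return matrix.genes[keep]


def call_degs(
    matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    p_cut: float = 0.05,
    log2_cut: float = 0.0,
    offset: float = 1.0,
    expressed_mode: str = "union",
) -> tuple[pd.DataFrame, dict]:
    """Call differentially expressed genes over trap/leaf pairs.

    Computes RPKM and quantile-normalized layers if absent, evaluates
    per-pair log2((trap + offset)/(leaf + offset)) on the normalized
    values, runs the paired t-test across pairs for every expressed gene,
    and flags DEGs at p < ``p_cut`` with |mean log2 ratio| > ``log2_cut``
    (the default 0 reproduces a p-only selection; a cutoff of 1 marks the
    at-least-two-fold subset). Returns the per-gene record table plus a
    summary with DEG counts as percentages of the whole catalog and of
    the expressed genes (1 decimal).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 trap/leaf pairs")
    if matrix.rpkm_values is None:
        matrix.rpkm_values = rpkm(matrix.total, matrix.lengths,
                                  matrix.library_totals)
    if matrix.qnorm_values is None:
        matrix.qnorm_values = quantile_normalize(matrix.rpkm_values)
    qn = matrix.qnorm_values
    expressed = expressed_filter(matrix, mode=expressed_mode)

    rows = []
    for gene in matrix.genes:
        is_expressed = gene in expressed
        ratios = {}
        for trap_s, leaf_s in pairs:
            ratios[f"log2_{trap_s}_vs_{leaf_s}"] = float(np.log2(
                (qn.at[gene, trap_s] + offset) / (qn.at[gene, leaf_s] + offset)))
        vals = np.array(list(ratios.values()))
        mean_l2 = float(vals.mean())
        row = {"gene": gene, "expressed": is_expressed, **ratios,
               "mean_log2_ratio": mean_l2}
        if is_expressed:
            trap_vals = [np.log2(qn.at[gene, t] + offset) for t, _ in pairs]
            leaf_vals = [np.log2(qn.at[gene, l] + offset) for _, l in pairs]
            res = paired_t_test(trap_vals, leaf_vals)
            row["p"] = res.p
            row["degenerate_test"] = res.degenerate
            row["deg"] = bool(res.p < p_cut and abs(mean_l2) > log2_cut)
        else:
            row["p"] = np.nan
            row["degenerate_test"] = False
            row["deg"] = False
        fold = 2.0 ** abs(mean_l2)
        row["fold_change"] = fold if mean_l2 >= 0 else -fold
        rows.append(row)
    records = pd.DataFrame(rows).set_index("gene")

    n_genes = len(matrix.genes)
    n_expressed = len(expressed)
    n_deg = int(records["deg"].sum())
    summary = {
        "n_genes": n_genes,
        "n_expressed": n_expressed,
        "n_deg": n_deg,
        "deg_pct_of_catalog": round_half_up(100.0 * n_deg / n_genes, 1)
        if n_genes else float("nan"),
        "deg_pct_of_expressed": round_half_up(100.0 * n_deg / n_expressed, 1)
        if n_expressed else float("nan"),
        "p_cut": p_cut,
        "log2_cut": log2_cut,
        "offset": offset,
    }
    return records, summary


def read_count_matrix(path) -> ExpressionMatrix:
    """Load the tabular count matrix: gene, length, then per-sample
    ``<sample>_total`` / ``<sample>_unique`` column pairs."""
    df = pd.read_csv(path, sep="\t").set_index("gene")
    lengths = df.pop("length")
    total_cols = [c for c in df.columns if c.endswith("_total")]
    samples = [c[:-6] for c in total_cols]
    total = df[[f"{s}_total" for s in samples]].copy()
    total.columns = samples
    unique = df[[f"{s}_unique" for s in samples]].copy()
    unique.columns = samples
    return ExpressionMatrix(total=total, unique=unique, lengths=lengths)


def write_count_matrix(matrix: ExpressionMatrix, path) -> None:
    out = pd.DataFrame({"length": matrix.lengths})
    for s in matrix.samples:
        out[f"{s}_total"] = matrix.total[s]
        out[f"{s}_unique"] = matrix.unique[s]
    out.rename_axis("gene").to_csv(path, sep="\t")
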