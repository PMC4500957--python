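"""The active-microbiome classifier and community comparisons.

A genus belongs to the trap's active (preferentially entrapped) microbiome
when it simultaneously

(i)   reaches >= 0.1% relative abundance within its community category in
      at least one trap sample,
(ii)  is present (>= 1 qualifying read) in at least two trap samples
      regardless of species or season, and
(iii) is enriched >= 2-fold in some trap sample over its corresponding
      leaf sample — trap-exclusive presence (leaf abundance zero) counts
      as passing.

Also here: paired trap-vs-leaf significance tests per genus, Bray–Curtis
sample dissimilarity, UPGMA dendrograms with deterministic tie-breaking,
and abundance-weighted multi-label phenotype profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _bc

from .design import trap_leaf_pairs
from .phylotypes import AbundanceTable
from .stats import PairedTResult, benjamini_hochberg, paired_t_test

TRAP_EXCLUSIVE = math.inf


# ---------------------------------------------------------------------------
# fold change

def fold_change(trap_abundance: float, leaf_abundance: float) -> float | None:
    """Trap/leaf abundance ratio.

    Returns ``math.inf`` (the trap-exclusive marker, printed as the
    infinity symbol) when the genus is present in the trap but absent from
    the paired leaf; ``None`` when absent from both.
    """
    if trap_abundance < 0 or leaf_abundance < 0:
        raise ValueError("abundances must be nonnegative")
    if leaf_abundance == 0:
        return TRAP_EXCLUSIVE if trap_abundance > 0 else None
    return trap_abundance / leaf_abundance


# ---------------------------------------------------------------------------
# classifier

@dataclass
class EnrichmentRecord:
    genus: str
    category: str
    pct_by_sample: dict[str, float]
    occurrence: int
    fold_changes: dict[str, float | None]          # pair_id -> ratio / inf / None
    p_trap_vs_leaf: dict[str, float] = field(default_factory=dict)  # per species
    p_season: dict[str, float] = field(default_factory=dict)        # per organ
    passes: tuple[bool, bool, bool] = (False, False, False)
    trap_exclusive: bool = False

    @property
    def active(self) -> bool:
        return all(self.passes)


@dataclass
class ClassifierThresholds:
    """The three decision thresholds, at their published defaults."""

    min_abundance_pct: float = 0.1
    min_occurrence: int = 2
    min_fold: float = 2.0
    # permissive: criterion (i) holds in >= 1 trap sample (default);
    # strict: must hold in every trap sample where the genus occurs
    abundance_mode: str = "any"
    # presence for criterion (ii): ">=1 read" (default) or ">=min_abundance"
    presence_rule: str = "read"
    # criterion (iii): "any" pair >= min_fold (default) or "mean" over pairs
    fold_mode: str = "any"


def classify_active_microbiome(
    table: AbundanceTable,
    thresholds: ClassifierThresholds | None = None,
) -> pd.DataFrame:
    """Apply the three-criterion rule to every genus of an abundance table.

    Returns one row per genus with the per-criterion outcomes, fold
    changes per trap/leaf pair (``inf`` marking trap exclusivity), paired
    t-test p-values per species and per organ (seasonal contrast), and the
    final ``active`` call. Requires the paired 8-sample design in
    ``table.metadata``.
    """
    th = thresholds or ClassifierThresholds()
    meta = table.metadata
    for col in ("species", "season", "organ", "pair_id"):
        if col not in meta.columns:
            raise ValueError(f"metadata misses column {col!r}")
    pairs = trap_leaf_pairs(meta)
    trap_samples = sorted(meta.index[meta["organ"] == "trap"])
    pct = table.within_category_percent()
    counts = table.counts

    rows = []
    for genus in counts.index:
        cat = table.categories[genus]
        g_pct = pct.loc[genus].fillna(0.0)
        g_cnt = counts.loc[genus]

        # (i) within-category abundance in trap samples
        trap_pcts = g_pct[trap_samples]
        if th.abundance_mode == "any":
            crit_i = bool((trap_pcts >= th.min_abundance_pct).any())
        else:
            occupied = trap_pcts[g_cnt[trap_samples] > 0]
            crit_i = len(occupied) > 0 and bool(
                (occupied >= th.min_abundance_pct).all())

        # (ii) occurrence across trap samples
        if th.presence_rule == "read":
            present = g_cnt[trap_samples] > 0
        else:
            present = trap_pcts >= th.min_abundance_pct
        occurrence = int(present.sum())
        crit_ii = occurrence >= th.min_occurrence

        # (iii) trap enrichment per corresponding pair
        fcs: dict[str, float | None] = {}
        for trap_s, leaf_s in pairs:
            fcs[meta.at[trap_s, "pair_id"]] = fold_change(
                float(g_pct[trap_s]), float(g_pct[leaf_s]))
        defined = [v for v in fcs.values() if v is not None]
        exclusive = any(v == TRAP_EXCLUSIVE for v in defined)
        if th.fold_mode == "any":
            crit_iii = any(v >= th.min_fold for v in defined)
        else:
            finite = [v for v in defined if v != TRAP_EXCLUSIVE]
            crit_iii = exclusive or (
                len(finite) > 0 and float(np.mean(finite)) >= th.min_fold)

        # paired tests: trap vs leaf within species, and seasonal within organ
        p_species = {}
        for sp in sorted(meta["species"].unique()):
            sp_pairs = [(t, l) for t, l in pairs if meta.at[t, "species"] == sp]
            t_vals = [g_pct[t] for t, _ in sp_pairs]
            l_vals = [g_pct[l] for _, l in sp_pairs]
            if len(sp_pairs) >= 2:
                p_species[sp] = paired_t_test(t_vals, l_vals).p
        p_organ = {}
        for organ in ("trap", "leaf"):
            ss = sorted(meta.index[(meta["organ"] == organ) & (meta["season"] == "SS")])
            ws = sorted(meta.index[(meta["organ"] == organ) & (meta["season"] == "WS")])
            if len(ss) == len(ws) and len(ss) >= 2:
                p_organ[organ] = paired_t_test(
                    g_pct[ws].values, g_pct[ss].values).p

        rec = EnrichmentRecord(
            genus=genus, category=cat, pct_by_sample=g_pct.to_dict(),
            occurrence=occurrence, fold_changes=fcs,
            p_trap_vs_leaf=p_species, p_season=p_organ,
            passes=(crit_i, crit_ii, crit_iii), trap_exclusive=exclusive,
        )
        row = {
            "genus": genus, "category": cat,
            "max_trap_pct": float(trap_pcts.max()) if len(trap_pcts) else 0.0,
            "occurrence": occurrence,
            "pass_abundance": crit_i, "pass_occurrence": crit_ii,
            "pass_enrichment": crit_iii, "trap_exclusive": exclusive,
            "active": rec.active,
        }
        for pid, v in fcs.items():
            row[f"fold_{pid}"] = np.nan if v is None else v
        for sp, p in p_species.items():
            row[f"p_trap_vs_leaf_{sp}"] = p
        for organ, p in p_organ.items():
            row[f"p_season_{organ}"] = p
        rows.append(row)

    result = pd.DataFrame(rows).set_index("genus") if rows else pd.DataFrame(
        columns=["category", "active"])
    # unadjusted p-values drive nothing; BH columns are informational
    for col in list(result.columns):
        if col.startswith("p_trap_vs_leaf_") or col.startswith("p_season_"):
            vals = result[col].dropna()
            if len(vals):
                q = pd.Series(benjamini_hochberg(vals.values), index=vals.index)
                result[f"q_{col[2:]}"] = q
    return result


def active_census(records: pd.DataFrame, table: AbundanceTable | None = None
                  ) -> pd.Series:
    """Number of active genera per community category."""
    active = records[records["active"]]
    return active.groupby("category").size()


# ---------------------------------------------------------------------------
# community dissimilarity and clustering

def bray_curtis(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray–Curtis dissimilarity.

    BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i); two all-zero samples are
    defined as identical (0) rather than NaN.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    if (counts.values < 0).any():
        raise ValueError("Bray–Curtis requires nonnegative counts")
    samples = list(counts.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u = counts.iloc[:, i].values.astype(float)
            v = counts.iloc[:, j].values.astype(float)
            if u.sum() == 0 and v.sum() == 0:
                val = 0.0  # degenerate: both empty communities
            else:
                val = float(_bc(u, v))
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=samples, columns=samples)


def upgma(dissimilarity: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) dendrogram as a Newick string.

    Cluster heights are half the average inter-cluster dissimilarity;
    branch lengths are height differences, so the tree is ultrametric.
    Ties are broken by the lexicographically smallest member label, making
    the output deterministic.
    """
    labels = list(dissimilarity.index)
    if list(dissimilarity.columns) != labels:
        raise ValueError("dissimilarity matrix must be square with equal labels")
    mat = dissimilarity.values.astype(float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if len(labels) == 1:
        return f"{labels[0]};"

    # cluster state: key -> (newick, height, size, sorted member labels)
    clusters = {i: (labels[i], 0.0, 1, (labels[i],)) for i in range(len(labels))}
    dist = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = mat[i, j]
    next_id = len(labels)

    def pair_key(i, j):
        return (i, j) if i < j else (j, i)

    while len(clusters) > 1:
        # minimum distance; ties resolved by smallest member labels
        best = min(
            dist.items(),
            key=lambda kv: (kv[1],
                            min(clusters[kv[0][0]][3][0], clusters[kv[0][1]][3][0]),
                            max(clusters[kv[0][0]][3][0], clusters[kv[0][1]][3][0])),
        )
        (i, j), dij = best
        ni, hi, si, mi = clusters[i]
        nj, hj, sj, mj = clusters[j]
        height = dij / 2.0
        first, second = ((ni, hi, mi), (nj, hj, mj)) if mi[0] < mj[0] else \
            ((nj, hj, mj), (ni, hi, mi))
        newick = (f"({first[0]}:{height - first[1]:.10g},"
                  f"{second[0]}:{height - second[1]:.10g})")
        merged = (newick, height, si + sj, tuple(sorted(mi + mj)))
        # proportional (size-weighted) average linkage = UPGMA
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(pair_key(i, k))
            djk = dist.pop(pair_key(j, k))
            dist[pair_key(next_id, k)] = (si * dik + sj * djk) / (si + sj)
        del dist[pair_key(i, j)]
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1

    (newick, _, _, _), = clusters.values()
    return newick + ";"


# ---------------------------------------------------------------------------
# phenotype profiling

def phenotype_profile(
    genus_sets: dict[str, list[str]],
    abundances: pd.Series,
    phenotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Abundance-weighted multi-label trait proportions per phenotype
    category, contrasted across genus sets (e.g. whole trap community vs
    active microbiome).

    ``phenotypes`` has columns ``genus, category, trait`` with possibly
    several traits per (genus, category). A trait's proportion within a
    set is the abundance share of set members carrying it, so multi-label
    genera contribute to every trait they carry and proportions within a
    category may exceed 100% in sum. Abundance of genera without any
    annotation in a category is reported as the ``unknown`` trait.
    """
    need = {"genus", "category", "trait"}
    if not need.issubset(phenotypes.columns):
        raise ValueError(f"phenotype table needs columns {sorted(need)}")
    traits_by_genus: dict[tuple[str, str], set[str]] = {}
    for row in phenotypes.itertuples(index=False):
        traits_by_genus.setdefault((row.genus, row.category), set()).add(row.trait)
    categories = sorted(phenotypes["category"].unique())

    rows = []
    for set_name, genera in genus_sets.items():
        genera = [g for g in genera if g in abundances.index]
        total = float(abundances[genera].sum()) if genera else 0.0
        for cat in categories:
            if total == 0:
                continue
            trait_mass: dict[str, float] = {}
            unknown = 0.0
            for g in genera:
                w = float(abundances[g])
                labels = traits_by_genus.get((g, cat))
                if not labels:
                    unknown += w
                    continue
                for t in labels:
                    trait_mass[t] = trait_mass.get(t, 0.0) + w
            for t, mass in sorted(trait_mass.items()):
                rows.append({"set": set_name, "category": cat, "trait": t,
                             "proportion_pct": 100.0 * mass / total})
            if unknown > 0:
                rows.append({"set": set_name, "category": cat, "trait": "unknown",
                             "proportion_pct": 100.0 * unknown / total})
    return pd.DataFrame(rows, columns=["set", "category", "trait", "proportion_pct"])
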