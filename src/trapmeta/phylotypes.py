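"""Genus-level ribotag profiling.

Reads binned as rRNA are mapped to reference sequences; references backed
by at least one uniquely-mapping read contribute their *total* mapped reads
(unique + shared) to their genus, organellar references are excluded, and
the resulting genus x sample count table feeds two normalizations:
reads-per-million of the per-sample rRNA total, and percent within each of
the five community categories. Rarefaction of genus richness is estimated
by repeated subsampling without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taxonomy import CATEGORIES, TaxonomyTree

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Genus x sample read counts with category labels per genus.

    ``counts`` rows are genus ids, columns sample ids; ``categories`` maps
    each genus row to one community category; ``metadata`` is the
    sample-design table (species, season, organ, pair_id per sample).
    """

    counts: pd.DataFrame
    categories: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("abundance counts must be nonnegative")
        self.categories = self.categories.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def reads_per_million(self) -> pd.DataFrame:
        """1e6 * count / per-sample total."""
        totals = self.sample_totals()
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"samples with zero total reads: {bad}")
        return 1e6 * self.counts / totals

    def category_totals(self) -> pd.DataFrame:
        """category x sample totals."""
        return self.counts.groupby(self.categories).sum()

    def within_category_percent(self) -> pd.DataFrame:
        """100 * count / same-sample category total; NaN where a category
        has zero reads in a sample (percent undefined)."""
        cat_totals = self.counts.groupby(self.categories).sum()
        denom = cat_totals.reindex(self.categories.values)
        denom.index = self.counts.index
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / denom
        return pct.where(denom > 0)

    def to_long(self) -> pd.DataFrame:
        """Long-format table with both normalizations, for TSV export."""
        rpm = self.reads_per_million()
        pct = self.within_category_percent()
        rows = []
        for genus in self.counts.index:
            for sample in self.counts.columns:
                rows.append({
                    "genus": genus,
                    "category": self.categories[genus],
                    "sample_id": sample,
                    "count": int(self.counts.at[genus, sample]),
                    "reads_per_million": rpm.at[genus, sample],
                    "pct_within_category": pct.at[genus, sample],
                })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.counts.rename_axis("genus").to_csv(path, sep="\t")


def summarize_phylotypes(
    assignments: pd.DataFrame,
    taxonomy: TaxonomyTree,
    metadata: pd.DataFrame,
    fractional: bool = False,
) -> AbundanceTable:
    """Roll read-to-reference assignments up to genus counts.

    Parameters
    ----------
    assignments : DataFrame
        One row per (read, reference) mapping with columns
        ``read_id, sample_id, ref_id, unique`` — ``unique`` is True when
        the read qualified for exactly one reference.
    taxonomy : TaxonomyTree
        Supplies genus lineage, category and organellar flag per reference.
    metadata : DataFrame
        Sample design; defines the column order of the output.
    fractional : bool
        When True a read shared by k references contributes 1/k to each;
        default is full multi-counting, i.e. per-reference *total mapped
        reads*.

    A reference contributes only if at least one read maps uniquely to it;
    organellar references never contribute. References whose lineage stops
    above genus are aggregated under their deepest named ancestor and a
    warning is logged; references without any usable lineage fall into
    ``Unclassified``.
    """
    required = {"read_id", "sample_id", "ref_id", "unique"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignments need columns {sorted(required)}")

    samples = list(metadata.index)
    # references qualified by >= 1 unique read, per sample
    qualifying = (
        assignments.groupby(["sample_id", "ref_id"])["unique"].any()
        if len(assignments) else pd.Series(dtype=bool)
    )

    genus_rows: dict[tuple[str, str], dict[str, float]] = {}

    if len(assignments):
        if fractional:
            k = assignments.groupby(["sample_id", "read_id"])["ref_id"].transform("size")
            weights = 1.0 / k
        else:
            weights = pd.Series(1.0, index=assignments.index)
        totals = weights.groupby(
            [assignments["sample_id"], assignments["ref_id"]]).sum()

        for (sample, ref_id), total in totals.items():
            if sample not in samples:
                continue
            if not qualifying.get((sample, ref_id), False):
                continue  # no unique read backs this reference here
            if ref_id not in taxonomy.nodes:
                logger.warning("reference %s absent from taxonomy; Unclassified", ref_id)
                key = ("Unclassified", "Unclassified")
            elif taxonomy.is_organellar(ref_id):
                continue  # organellar rRNA excluded from community profiling
            else:
                genus = taxonomy.genus_of(ref_id)
                if genus is None:
                    lineage = taxonomy.lineage(ref_id)
                    deepest = lineage[1] if len(lineage) > 1 else lineage[0]
                    logger.warning(
                        "reference %s has no genus; aggregating at %s",
                        ref_id, deepest.name)
                    key = (deepest.name, taxonomy.category_of(ref_id))
                else:
                    key = (genus.name, genus.category)
            row = genus_rows.setdefault(key, {s: 0.0 for s in samples})
            row[sample] = row.get(sample, 0.0) + float(total)

    index = [g for g, _ in sorted(genus_rows)]
    cats = {g: c for g, c in sorted(genus_rows)}
    counts = pd.DataFrame(
        [[genus_rows[(g, cats[g])].get(s, 0.0) for s in samples] for g in index],
        index=pd.Index(index, name="genus"), columns=samples,
    )
    if not fractional:
        counts = counts.round().astype(int)
    categories = pd.Series({g: cats[g] for g in index}, name="category")
    return AbundanceTable(counts=counts, categories=categories, metadata=metadata)


def relative_abundance(table: AbundanceTable) -> dict[str, pd.DataFrame]:
    """Both normalized views of an abundance table."""
    return {
        "reads_per_million": table.reads_per_million(),
        "pct_within_category": table.within_category_percent(),
    }


def rarefaction_curve(counts, depths, reps: int = 100, seed: int = 0) -> pd.Series:
    """Expected number of distinct taxa at each subsampling depth.

    ``counts`` is a per-taxon read-count vector; each replicate draws reads
    uniformly without replacement. One permutation per replicate serves all
    depths, so each replicate's curve is monotone by construction.
    """
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("negative taxon counts")
    total = int(counts.sum())
    depths = [int(d) for d in depths]
    if any(d < 0 or d > total for d in depths):
        raise ValueError(f"depths must lie in [0, {total}]")
    labels = np.repeat(np.arange(counts.size), counts)
    rng = np.random.default_rng(seed)
    ntaxa = counts.size
    acc = np.zeros(len(depths))
    for _ in range(reps):
        perm = rng.permutation(labels)
        for j, d in enumerate(depths):
            acc[j] += np.unique(perm[:d]).size if d > 0 else 0
    return pd.Series(acc / reps, index=pd.Index(depths, name="depth"),
                     name="expected_taxa")


__all__ = [
    "AbundanceTable", "summarize_phylotypes", "relative_abundance",
    "rarefaction_curve", "CATEGORIES",
]
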