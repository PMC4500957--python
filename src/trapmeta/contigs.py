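"""Microbial contig characterization.

Trap-assembly contigs pass a sequential subtraction cascade — minimum
length, host-transcript removal, rRNA removal, 80%-identity redundancy
clustering, leaf-assembly subtraction, final >= 1 kb cut — after which the
survivors are taxonomically assigned from tabular protein hits (best hit,
minimum bit score 50, chordate hits bucketed into Metazoa), tallied by
enzyme-code class with hydrolase / phosphatase / peptidase sub-tallies,
and tested for GO-term enrichment by Fisher's exact test with
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import fisher_exact

from .alignment import infix_match, sequence_identity
from .stats import benjamini_hochberg, round_half_up
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore",
               "staxid"]

_EC_RE = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


@dataclass
class Contig:
    contig_id: str
    sequence: str
    source: str = "trap"          # originating library: trap or leaf
    tags: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    """Survivors of the cascade plus a per-contig removal ledger."""

    survivors: list[Contig]
    removed: pd.DataFrame  # contig_id, stage, length
    n_input: int

    def stage_counts(self) -> pd.Series:
        counts = self.removed.groupby("stage").size()
        counts["survivor"] = len(self.survivors)
        return counts


def read_contig_fasta(path: str | Path, source: str = "trap") -> list[Contig]:
    return [Contig(rec.id, str(rec.seq).upper(), source=source)
            for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# identity clustering

def cluster_identity(contigs: list[Contig], threshold: float = 0.80
                     ) -> tuple[list[Contig], dict[str, list[str]]]:
    """Greedy incremental clustering at a global-identity threshold.

    Inputs are visited by decreasing length (ties: lexicographic id); a
    contig joins the first existing representative it matches at
    >= ``threshold`` identity (terminal gaps free), otherwise it founds a
    new cluster. Deterministic by construction.
    """
    if not 0 < threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    reps: list[Contig] = []
    members: dict[str, list[str]] = {}
    for contig in ordered:
        placed = False
        for rep in reps:
            # identity can never reach the threshold if lengths are too
            # disparate (every missing base is a non-matching column)
            if contig.length < threshold * min(rep.length, contig.length):
                continue
            if sequence_identity(contig.sequence, rep.sequence) >= threshold:
                members[rep.contig_id].append(contig.contig_id)
                placed = True
                break
        if not placed:
            reps.append(contig)
            members[contig.contig_id] = [contig.contig_id]
    return reps, members


# ---------------------------------------------------------------------------
# the sequential filter cascade

def _matches_any(contig: Contig, refs: dict[str, str],
                 hits: pd.DataFrame | None, ref_ids: set[str],
                 evalue_cut: float, min_identity: float) -> bool:
    if hits is not None:
        sub = hits[(hits["qseqid"] == contig.contig_id)
                   & (hits["evalue"] <= evalue_cut)
                   & (hits["sseqid"].isin(ref_ids))]
        return len(sub) > 0
    return any(infix_match(contig.sequence, seq, min_identity=min_identity)
               for seq in refs.values())


def filter_cascade(
    contigs: list[Contig],
    host_transcripts: dict[str, str],
    rrna_refs: dict[str, str],
    leaf_contigs: dict[str, str],
    hits: pd.DataFrame | None = None,
    min_length: int = 500,
    cluster_threshold: float = 0.80,
    final_min_length: int = 1000,
    evalue_cut: float = 1e-9,
    match_identity: float = 0.80,
) -> ContigSet:
    """Run the six-stage subtraction cascade on trap contigs.

    Stages, in order: (1) drop contigs shorter than ``min_length``;
    (2) remove host-transcript matches; (3) remove rRNA matches;
    (4) cluster the remainder at ``cluster_threshold`` identity, keeping
    representatives; (5) remove contigs matching the leaf assembly;
    (6) keep contigs of at least ``final_min_length``. Similarity
    evidence comes from the tabular ``hits`` (removal at e-value <=
    ``evalue_cut``) when given, else from the module's own alignment
    search. Every removal is tagged with its stage.
    """
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in input")
    host_ids, rrna_ids, leaf_ids = (
        set(host_transcripts), set(rrna_refs), set(leaf_contigs))
    removed: list[dict] = []

    def drop(contig: Contig, stage: str) -> None:
        contig.tags.append(f"removed:{stage}")
        removed.append({"contig_id": contig.contig_id, "stage": stage,
                        "length": contig.length})

    stage1 = []
    for c in contigs:
        if c.length < min_length:
            drop(c, "min_length")
        else:
            c.tags.append("pass:min_length")
            stage1.append(c)

    stage2 = []
    for c in stage1:
        if _matches_any(c, host_transcripts, hits, host_ids,
                        evalue_cut, match_identity):
            drop(c, "host")
        else:
            c.tags.append("pass:host")
            stage2.append(c)

    stage3 = []
    for c in stage2:
        if _matches_any(c, rrna_refs, hits, rrna_ids,
                        evalue_cut, match_identity):
            drop(c, "rrna")
        else:
            c.tags.append("pass:rrna")
            stage3.append(c)

    reps, membership = cluster_identity(stage3, cluster_threshold)
    rep_ids = {r.contig_id for r in reps}
    stage4 = []
    for c in stage3:
        if c.contig_id in rep_ids:
            c.tags.append("pass:cluster")
            stage4.append(c)
        else:
            drop(c, "cluster")

    stage5 = []
    for c in stage4:
        if _matches_any(c, leaf_contigs, hits, leaf_ids,
                        evalue_cut, match_identity):
            drop(c, "leaf")
        else:
            c.tags.append("pass:leaf")
            stage5.append(c)

    survivors = []
    for c in stage5:
        if c.length < final_min_length:
            drop(c, "final_min_length")
        else:
            c.tags.append("survivor")
            survivors.append(c)

    removed_df = pd.DataFrame(removed, columns=["contig_id", "stage", "length"])
    return ContigSet(survivors=survivors, removed=removed_df,
                     n_input=len(contigs))


def select_annotation_window(contigs: list[Contig], lo: int = 1500,
                             hi: int = 8000) -> list[Contig]:
    """Closed-interval length filter selecting the annotation window."""
    if lo > hi:
        raise ValueError("window lower bound exceeds upper bound")
    return [c for c in contigs if lo <= c.length <= hi]


# ---------------------------------------------------------------------------
# taxonomic assignment from protein hits

def assign_taxon(
    hits: pd.DataFrame,
    taxonomy: TaxonomyTree,
    min_bitscore: float = 50.0,
    mode: str = "best",
    lca_score_window: float = 0.10,
) -> str | None:
    """Taxon for one contig from its sorted protein hits.

    Default: the best hit's taxon, unassigned below ``min_bitscore``.
    ``mode='lca'`` instead takes the lowest common ancestor of all hits
    within ``lca_score_window`` of the best bit score. Hits whose lineage
    passes through the phylum Chordata are bucketed into the Metazoa
    category by the taxonomy itself. Taxon ids absent from the tree are
    unassigned (logged).
    """
    if hits.empty:
        return None
    hits = hits.sort_values(["bitscore", "evalue", "sseqid"],
                            ascending=[False, True, True])
    best = hits.iloc[0]
    if float(best["bitscore"]) < min_bitscore:
        return None
    chosen = [str(best["staxid"])]
    if mode == "lca":
        cut = float(best["bitscore"]) * (1 - lca_score_window)
        chosen = [str(t) for t in
                  hits.loc[hits["bitscore"] >= cut, "staxid"].unique()]
    nodes = []
    for taxid in chosen:
        if taxid not in taxonomy.nodes:
            logger.warning("hit taxon %s absent from taxonomy", taxid)
            continue
        nodes.append(taxid)
    if not nodes:
        return None
    if len(nodes) == 1:
        return nodes[0]
    # LCA: deepest node common to all lineages
    lineages = [[n.node_id for n in reversed(taxonomy.lineage(t))] for t in nodes]
    lca = None
    for level in zip(*lineages):
        if len(set(level)) == 1:
            lca = level[0]
        else:
            break
    return lca


def category_of_assignment(taxonomy: TaxonomyTree, node_id: str | None) -> str:
    """Community category of an assigned taxon; chordate lineages report
    as Metazoa, unassigned as 'Unassigned'."""
    if node_id is None:
        return "Unassigned"
    phylum = taxonomy.phylum_of(node_id)
    if phylum is not None and phylum.name == "Chordata":
        return "Metazoa"
    return taxonomy.category_of(node_id)


# ---------------------------------------------------------------------------
# enzyme-code tallies

def parse_ec_codes(raw: str | list[str]) -> list[str]:
    """Validated EC codes from a ';'-joined string or list; malformed
    entries are skipped with a warning."""
    if isinstance(raw, str):
        parts = [p.strip() for p in raw.replace("EC:", "").split(";")]
    else:
        parts = [str(p).replace("EC:", "").strip() for p in raw]
    out = []
    for p in parts:
        if not p:
            continue
        if _EC_RE.match(p):
            out.append(p)
        else:
            logger.warning("malformed EC code %r skipped", p)
    return out


def tally_functions(annotations: pd.DataFrame) -> dict:
    """EC class distribution with hydrolase sub-tallies.

    ``annotations`` rows carry ``contig_id``, an ``ec`` field (possibly
    several ';'-joined codes) and a ``category`` (taxonomic) field. A
    transcript counts once per top-level EC class it carries; the
    hydrolase fraction is hydrolase transcripts / EC-assigned transcripts
    (percent, 1 decimal). Sub-tallies: phosphatases (EC 3.1.3),
    peptidases (EC 3.4), and the share of each taxonomy category among
    hydrolase transcripts.
    """
    class_hist: dict[str, int] = {}
    n_assigned = 0
    n_hydrolase = n_phosphatase = n_peptidase = 0
    hydrolase_by_cat: dict[str, int] = {}
    for row in annotations.itertuples(index=False):
        codes = parse_ec_codes(getattr(row, "ec", "") or "")
        if not codes:
            continue
        n_assigned += 1
        classes = {c.split(".")[0] for c in codes}
        for cl in classes:
            class_hist[cl] = class_hist.get(cl, 0) + 1
        if "3" in classes:
            n_hydrolase += 1
            cat = getattr(row, "category", "Unassigned")
            hydrolase_by_cat[cat] = hydrolase_by_cat.get(cat, 0) + 1
        if any(c.startswith("3.1.3") for c in codes):
            n_phosphatase += 1
        if any(c == "3.4" or c.startswith("3.4.") for c in codes):
            n_peptidase += 1
    hydrolase_pct = (round_half_up(100.0 * n_hydrolase / n_assigned, 1)
                     if n_assigned else float("nan"))
    shares = {cat: round_half_up(100.0 * n / n_hydrolase, 1)
              for cat, n in sorted(hydrolase_by_cat.items())} if n_hydrolase else {}
    return {
        "ec_class_histogram": dict(sorted(class_hist.items())),
        "n_ec_assigned": n_assigned,
        "n_hydrolase": n_hydrolase,
        "hydrolase_pct": hydrolase_pct,
        "n_phosphatase": n_phosphatase,
        "n_peptidase": n_peptidase,
        "hydrolase_category_shares_pct": shares,
    }


# ---------------------------------------------------------------------------
# GO enrichment

def _go_ancestors(ontology: pd.DataFrame) -> dict[str, set[str]]:
    parents: dict[str, set[str]] = {}
    for row in ontology.itertuples(index=False):
        if pd.isna(row.parent) or row.parent == "":
            parents.setdefault(row.term, set())
        else:
            parents.setdefault(row.term, set()).add(row.parent)
    anc: dict[str, set[str]] = {}

    def walk(term: str) -> set[str]:
        if term in anc:
            return anc[term]
        out: set[str] = set()
        for p in parents.get(term, ()):  # multi-parent DAG allowed
            out.add(p)
            out |= walk(p)
        anc[term] = out
        return out

    for t in parents:
        walk(t)
    return anc


def go_enrichment(
    subset: pd.DataFrame,
    background: pd.DataFrame,
    ontology: pd.DataFrame | None = None,
    propagate: bool = True,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher's exact test of a contig subset against its
    background, Benjamini–Hochberg corrected.

    ``subset`` and ``background`` carry ``contig_id`` and ``go`` (';'-joined
    term ids); subset ids must be a subset of background ids. With
    ``propagate`` (default) every annotation also counts for its ancestor
    terms in the ``term, parent`` ontology table; terms missing from the
    ontology are tested as-is with a warning.
    """
    sub_ids = set(subset["contig_id"])
    bg_ids = set(background["contig_id"])
    if not sub_ids <= bg_ids:
        raise ValueError("subset contigs must be contained in the background")
    ancestors = _go_ancestors(ontology) if (propagate and ontology is not None) \
        else {}

    def term_sets(frame: pd.DataFrame) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for row in frame.itertuples(index=False):
            raw = getattr(row, "go", "") or ""
            terms = {t.strip() for t in str(raw).split(";") if t.strip()}
            full = set(terms)
            for t in terms:
                if propagate and ontology is not None and t not in ancestors:
                    logger.warning("GO term %s absent from ontology", t)
                full |= ancestors.get(t, set())
            out[row.contig_id] = out.get(row.contig_id, set()) | full
        return out

    bg_terms = term_sets(background)
    all_terms = sorted(set().union(*bg_terms.values())) if bg_terms else []
    n_sub = len(sub_ids)
    n_bg = len(bg_ids)
    rows = []
    for term in all_terms:
        with_term = {cid for cid, ts in bg_terms.items() if term in ts}
        a = len(with_term & sub_ids)                  # subset, has term
        b = n_sub - a                                 # subset, lacks term
        c = len(with_term) - a                        # rest, has term
        d = (n_bg - n_sub) - c                        # rest, lacks term
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"term": term, "subset_with": a, "subset_without": b,
                     "background_with": c, "background_without": d,
                     "p": float(p)})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = benjamini_hochberg(result["p"].values)
        result["significant"] = result["q"] < q_cut
        result = result.sort_values("p", kind="mergesort").reset_index(drop=True)
    return result
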