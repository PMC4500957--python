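"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: eight
total-RNA libraries (two species x two seasons x trap/leaf), a five-
category community (Bacteria, SAR protists, green algae, metazoans, other
eukaryotes), 2x100 bp reads, trap-enriched / rare / trap-exclusive /
decoy genera planted with known margins around each classifier criterion,
contig classes covering every cascade stage, and host genes with planted
log2 fold-changes. Every operation is a pure function of the
configuration: the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contigs import Contig
from .design import default_metadata, sample_id
from .dge import ExpressionMatrix
from .partition import ReadRecord
from .phylotypes import AbundanceTable
from .taxonomy import CATEGORIES, Node, ROOT_ID, ROOT_NAME, TaxonomyTree

BASES = np.array(list("ACGT"))

# per-operation rng streams, so ops can run independently yet reproducibly
_STREAMS = {"taxonomy": 1, "references": 2, "community": 3, "reads": 4,
            "contigs": 5, "expression": 6}


def _rng(config: "SimulationConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    n_genera_per_category: dict = field(default_factory=lambda: {
        "Bacteria": 12, "SAR": 6, "Chlorophyta": 5, "Metazoa": 8,
        "OtherEukaryote": 5})
    n_enriched: int = 8                 # planted active genera (incl. 1 exclusive)
    enrichment_fold: float = 4.0        # planted trap/leaf ratio for actives
    decoy_fold: float = 1.5             # fold of the criterion-(iii) decoy
    rare_fraction: float = 0.4          # background genera at 0.1–1% abundance
    library_size: int = 100_000         # rRNA reads per sample (counts table)
    error_rate: float = 0.005           # per-base substitution probability
    reads_per_sample: int = 400         # simulated FASTQ depth per library
    read_length: int = 100
    ref_length: int = 800               # rRNA reference length
    genus_refs: int = 1                 # references per genus (2 = multi-ref mode)
    n_organellar: int = 2
    bin_proportions: dict = field(default_factory=lambda: {
        "rRNA": 0.3, "host": 0.5, "nonhost": 0.2})
    low_quality_tail_from: int | None = None  # plant a Q<=5 tail after this base
    # contig fixture
    n_keepers_per_band: tuple = (3, 5, 2)   # 1000–1500 / 1500–8000 / >8000 bp
    # host expression fixture
    n_host_genes: int = 200
    n_deg: int = 10
    deg_log2fc: float = 3.0
    expr_noise_sd: float = 0.25         # sd of log2 expression noise
    n_unexpressed: int = 6

    def validate(self) -> None:
        for cat in CATEGORIES:
            if self.n_genera_per_category.get(cat, 0) < 1:
                raise ValueError(
                    f"at least one genus required in every category; "
                    f"{cat} has {self.n_genera_per_category.get(cat, 0)}")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("per-base error rate must lie in [0, 0.5)")
        if self.n_deg > self.n_host_genes:
            raise ValueError("n_deg cannot exceed n_host_genes")
        min_lib = 1000 * len(CATEGORIES)
        if self.library_size < min_lib:
            raise ValueError(
                f"library_size {self.library_size} cannot resolve 0.1% "
                f"within-category abundance; minimum is {min_lib}")


@dataclass
class GroundTruth:
    """What was planted, for exact recovery checks downstream."""

    planted_active_genera: dict = field(default_factory=dict)  # category -> [genus]
    decoys: dict = field(default_factory=dict)                 # failed criterion -> genus
    planted_deg_genes: dict = field(default_factory=dict)      # gene -> true log2fc
    unexpressed_genes: list = field(default_factory=list)
    read_origin: dict = field(default_factory=dict)            # read -> (ref, bin)
    bin_totals: dict = field(default_factory=dict)             # sample -> {bin: n}
    contig_origin: dict = field(default_factory=dict)          # contig -> class
    planted_keepers: list = field(default_factory=list)

    @property
    def active_set(self) -> set:
        return {g for gs in self.planted_active_genera.values() for g in gs}

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# taxonomy

def make_taxonomy(config: SimulationConfig) -> TaxonomyTree:
    """Rooted taxonomy over the five community categories.

    Each category holds one or more phyla (each phylum maps to exactly one
    category); every genus hangs under a phylum and carries one rRNA
    reference by default (two in multi-reference mode). A configured
    number of extra references is flagged organellar. The Metazoa category
    always contains a Chordata phylum so chordate bucketing is
    exercisable.
    """
    config.validate()
    tree = TaxonomyTree()
    tree.add_node(Node(ROOT_ID, None, "no rank", ROOT_NAME, "Unclassified"))
    phyla_names = {
        "Bacteria": ["Proteobacteria", "Verrucomicrobia", "Planctomycetes",
                     "Acidobacteria", "Firmicutes"],
        "SAR": ["Ciliophora", "Cercozoa", "Bacillariophyta"],
        "Chlorophyta": ["Chlorophyta"],
        "Metazoa": ["Arthropoda", "Chordata", "Nematoda", "Annelida",
                    "Rotifera"],
        "OtherEukaryote": ["Amoebozoa", "Chytridiomycota"],
    }
    for ci, cat in enumerate(CATEGORIES):
        dom_id = f"sk{ci}"
        tree.add_node(Node(dom_id, ROOT_ID, "superkingdom", cat, cat))
        n_genera = config.n_genera_per_category[cat]
        pool = phyla_names[cat]
        n_phyla = min(len(pool), max(1, n_genera // 3 + 1))
        phylum_ids = []
        for pi in range(n_phyla):
            pid = f"p{ci}_{pi}"
            tree.add_node(Node(pid, dom_id, "phylum", pool[pi], cat))
            phylum_ids.append(pid)
        for gi in range(n_genera):
            gid = f"g_{cat}_{gi}"
            # round-robin: every phylum of the pool receives a genus
            phylum = phylum_ids[gi % len(phylum_ids)]
            tree.add_node(Node(gid, phylum, "genus", gid, cat))
            for ri in range(config.genus_refs):
                rid = f"ref_{cat}_{gi}" if config.genus_refs == 1 \
                    else f"ref_{cat}_{gi}_{ri}"
                tree.add_node(Node(rid, gid, "reference", rid, cat))
    # organellar references (host plastid/mitochondrial rRNA) under a Host genus
    tree.add_node(Node("sk_host", ROOT_ID, "superkingdom", "Host", "Host"))
    tree.add_node(Node("p_host", "sk_host", "phylum", "Streptophyta", "Host"))
    tree.add_node(Node("g_host", "p_host", "genus", "g_host", "Host"))
    for oi in range(config.n_organellar):
        tree.add_node(Node(f"ref_organellar_{oi}", "g_host", "reference",
                           f"ref_organellar_{oi}", "Host", organellar=True))
    return tree


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def make_references(config: SimulationConfig, taxonomy: TaxonomyTree
                    ) -> dict[str, dict[str, str]]:
    """Sequence sets keyed by bin: rRNA references (one per taxonomy
    reference node), host transcripts, and non-host (microbial mRNA)
    transcripts for read simulation."""
    rng = _rng(config, "references")
    rrna = {}
    for node in sorted(taxonomy.references(), key=lambda n: n.node_id):
        rrna[node.node_id] = _random_seq(rng, config.ref_length)
    host = {f"host_t{i}": _random_seq(rng, int(rng.integers(800, 2400)))
            for i in range(20)}
    nonhost = {f"microbe_t{i}": _random_seq(rng, int(rng.integers(600, 2000)))
               for i in range(12)}
    return {"rRNA": rrna, "host": host, "nonhost": nonhost}


# ---------------------------------------------------------------------------
# community counts

def simulate_community_counts(config: SimulationConfig,
                              taxonomy: TaxonomyTree
                              ) -> tuple[AbundanceTable, GroundTruth]:
    """Genus x sample counts with planted classifier outcomes.

    Planted active genera pass all three criteria with at least a twofold
    margin on each threshold (abundance 0.8% vs the 0.1% cutoff, presence
    in all four trap samples vs two required, count-ratio enrichment of
    ``enrichment_fold`` vs 2); one planted genus is trap-exclusive. Three
    decoys each violate exactly one criterion: sub-cutoff abundance
    (0.05%), single-trap occurrence, and ``decoy_fold`` enrichment.
    Background genera keep trap/leaf ratios below 1.5 so they can never
    pass criterion (iii); a configured fraction of them is rare (0.1–1%).
    """
    config.validate()
    rng = _rng(config, "community")
    metadata = default_metadata()
    samples = list(metadata.index)
    trap_samples = [s for s in samples if metadata.at[s, "organ"] == "trap"]
    cat_total = config.library_size // len(CATEGORIES)

    genera_by_cat = {
        cat: sorted(n.node_id for n in taxonomy.genera() if n.category == cat)
        for cat in CATEGORIES}

    # distribute planted roles round-robin over categories
    active: list[tuple[str, str]] = []   # (category, genus)
    ci = 0
    per_cat_used = {cat: 0 for cat in CATEGORIES}
    while len(active) < config.n_enriched:
        cat = CATEGORIES[ci % len(CATEGORIES)]
        ci += 1
        if per_cat_used[cat] < len(genera_by_cat[cat]):
            active.append((cat, genera_by_cat[cat][per_cat_used[cat]]))
            per_cat_used[cat] += 1
    decoys = {}
    for crit in ("abundance", "occurrence", "enrichment"):
        for cat in CATEGORIES:
            if per_cat_used[cat] < len(genera_by_cat[cat]) - 1:
                decoys[crit] = (cat, genera_by_cat[cat][per_cat_used[cat]])
                per_cat_used[cat] += 1
                break

    counts = pd.DataFrame(
        0, index=pd.Index([g for cat in CATEGORIES for g in genera_by_cat[cat]],
                          name="genus"),
        columns=samples, dtype=int)
    categories = pd.Series(
        {g: cat for cat in CATEGORIES for g in genera_by_cat[cat]},
        name="category")

    def set_pct(genus, sample, pct):
        counts.at[genus, sample] = int(round(pct / 100.0 * cat_total))

    exclusive_genus = active[0][1] if active else None
    for idx, (cat, genus) in enumerate(active):
        trap_pct = 0.8 + 0.05 * (idx % 5)
        for s in samples:
            if metadata.at[s, "organ"] == "trap":
                set_pct(genus, s, trap_pct)
            elif genus != exclusive_genus:
                set_pct(genus, s, trap_pct / config.enrichment_fold)
            # exclusive genus: leaf counts stay 0

    if "abundance" in decoys:
        _, g = decoys["abundance"]
        for s in samples:
            pct = 0.05 if metadata.at[s, "organ"] == "trap" \
                else 0.05 / config.enrichment_fold
            counts.at[g, s] = max(1, int(round(pct / 100.0 * cat_total)))
    if "occurrence" in decoys:
        _, g = decoys["occurrence"]
        set_pct(g, trap_samples[0], 0.8)
    if "enrichment" in decoys:
        _, g = decoys["enrichment"]
        for s in samples:
            pct = 0.8 if metadata.at[s, "organ"] == "trap" \
                else 0.8 / config.decoy_fold
            set_pct(g, s, pct)

    # background: fill each (category, sample) up to the category total
    planted = {g for _, g in active} | {g for _, g in decoys.values()}
    for cat in CATEGORIES:
        bg = [g for g in genera_by_cat[cat] if g not in planted]
        if not bg:
            continue
        n_rare = int(round(config.rare_fraction * len(bg)))
        rare = bg[:n_rare]
        common = bg[n_rare:]
        base = {}
        for g in rare:
            base[g] = float(rng.uniform(0.12, 0.9))
        if common:
            # one deterministic dominant genus (>10%), rest Dirichlet
            alloc = {s: cat_total - int(counts.loc[genera_by_cat[cat], s].sum())
                     for s in samples}
            weights = rng.dirichlet(np.full(len(common), 0.8))
            weights = 0.35 * (np.arange(len(common)) == 0) + 0.65 * weights
            for g, w in zip(common, weights):
                base[g] = None  # placeholder; mass assigned per sample below
            for s in samples:
                jitter = rng.uniform(0.9, 1.1, size=len(common))
                rare_counts = 0
                for g in rare:
                    j = float(rng.uniform(0.9, 1.1))
                    c = max(1, int(round(base[g] * j / 100.0 * cat_total)))
                    counts.at[g, s] = c
                    rare_counts += c
                remaining = max(alloc[s] - rare_counts, len(common))
                w = weights * jitter
                w = w / w.sum()
                bg_counts = np.maximum(1, np.round(w * remaining).astype(int))
                for g, c in zip(common, bg_counts):
                    counts.at[g, s] = int(c)
        else:
            for s in samples:
                for g in rare:
                    j = float(rng.uniform(0.9, 1.1))
                    counts.at[g, s] = max(1, int(round(
                        base[g] * j / 100.0 * cat_total)))

    truth = GroundTruth(
        planted_active_genera={
            cat: sorted(g for c, g in active if c == cat) for cat in CATEGORIES},
        decoys={crit: g for crit, (_, g) in decoys.items()},
    )
    table = AbundanceTable(counts=counts, categories=categories,
                           metadata=metadata)
    return table, truth


# ---------------------------------------------------------------------------
# reads

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(arr.size) < rate
    if hits.any():
        # substitute with one of the three other bases
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_reads(config: SimulationConfig,
                   references: dict[str, dict[str, str]]
                   ) -> tuple[dict[str, list[ReadRecord]], GroundTruth]:
    """Single-end 100 bp reads per library with known origins.

    Each read is drawn from a bin (rRNA / host / nonhost) by the
    configured proportions, from a uniformly chosen reference and start
    position, with i.i.d. per-base substitution errors at the configured
    rate. Quality strings encode the error profile (constant Phred from
    the error rate); an optional low-quality tail (p = 0.75 after a fixed
    position) exercises the trimming contract.
    """
    config.validate()
    if not any(references.values()):
        raise ValueError("references must be non-empty")
    rng = _rng(config, "reads")
    bins = [b for b in ("rRNA", "host", "nonhost") if references.get(b)]
    probs = np.array([config.bin_proportions[b] for b in bins], dtype=float)
    probs = probs / probs.sum()
    base_p = max(config.error_rate, 1e-4)

    truth = GroundTruth()
    out: dict[str, list[ReadRecord]] = {}
    metadata = default_metadata()
    L = config.read_length
    for s in metadata.index:
        reads = []
        bin_counts = {b: 0 for b in bins}
        draws = rng.choice(len(bins), size=config.reads_per_sample, p=probs)
        for i, bi in enumerate(draws):
            bin_name = bins[bi]
            refs = references[bin_name]
            usable = [rid for rid, seq in sorted(refs.items())
                      if len(seq) >= L]
            rid = usable[int(rng.integers(len(usable)))]
            seq = refs[rid]
            start = int(rng.integers(0, len(seq) - L + 1))
            frag = _mutate(rng, seq[start:start + L], config.error_rate)
            quals = np.full(L, base_p)
            if config.low_quality_tail_from is not None:
                k = config.low_quality_tail_from
                quals[k:] = 0.75
                tail = _random_seq(rng, max(L - k, 0))
                frag = frag[:k] + tail
            read_id = f"{s}_r{i}"
            reads.append(ReadRecord(read_id, frag, quals))
            truth.read_origin[read_id] = (rid, bin_name)
            bin_counts[bin_name] += 1
        truth.bin_totals[s] = bin_counts
        out[s] = reads
    return out, truth


# ---------------------------------------------------------------------------
# contigs, hits and toy annotations

@dataclass
class ContigBundle:
    trap_contigs: list
    leaf_contigs: dict[str, str]
    host_transcripts: dict[str, str]
    rrna_refs: dict[str, str]
    protein_hits: pd.DataFrame       # qseqid sseqid ... bitscore staxid
    annotations: pd.DataFrame        # contig_id, ec, go, category
    ontology: pd.DataFrame           # term, parent
    truth: GroundTruth


def make_contigs_and_hits(config: SimulationConfig,
                          taxonomy: TaxonomyTree) -> ContigBundle:
    """Contig fixture covering every cascade stage.

    Planted classes: sub-500 bp fragments; host-transcript copies; rRNA
    copies; contigs redundant with the leaf assembly; a near-duplicate
    pair at ~88% identity of which exactly one survives 80% clustering;
    a 900 bp clean microbe contig (dropped at the final >= 1 kb cut); and
    keepers in the 1000–1500 / 1500–8000 / > 8000 bp bands. Protein hits
    include bit scores on both sides of 50 and one chordate best hit; the
    toy GO/EC tables plant an enriched term in the hydrolase subset.
    """
    config.validate()
    rng = _rng(config, "contigs")
    # reference sets local to the contig fixture (distinct ids from the
    # read-simulation references)
    host = {f"chost_t{i}": _random_seq(rng, 2200) for i in range(4)}
    rrna = {f"crrna_r{i}": _random_seq(rng, 1500) for i in range(4)}
    leaf = {f"leaf_c{i}": _random_seq(rng, 1800) for i in range(3)}

    contigs: list[Contig] = []
    truth = GroundTruth()

    def add(cid, seq, klass):
        contigs.append(Contig(cid, seq, source="trap"))
        truth.contig_origin[cid] = klass

    add("c_short_1", _random_seq(rng, 300), "short")
    add("c_short_2", _random_seq(rng, 499), "short")
    add("c_host_1", host["chost_t0"][:2000], "host")
    add("c_rrna_1", rrna["crrna_r0"][:1200], "rrna")
    add("c_leaf_1", leaf["leaf_c0"][:1600], "leaf-redundant")
    add("c_mid_1", _random_seq(rng, 900), "mid")

    dup_a = _random_seq(rng, 1400)
    dup_b = _mutate(rng, dup_a, 0.12)[:1300]   # ~88% identity, shorter
    add("c_dup_keep", dup_a, "near-duplicate-rep")
    add("c_dup_drop", dup_b, "near-duplicate-member")
    truth.planted_keepers.append("c_dup_keep")

    bands = [(1000, 1500), (1500, 8000), (8001, 9000)]
    for (lo, hi), n in zip(bands, config.n_keepers_per_band):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            cid = f"c_keep_{lo}_{i}"
            add(cid, _random_seq(rng, length), f"keeper_{lo}")
            truth.planted_keepers.append(cid)
    truth.planted_keepers.sort()

    # protein hits for keepers: mostly Metazoa genera, scores straddling 50
    genera = sorted(n.node_id for n in taxonomy.genera())
    chordate_genus = next(
        (g.node_id for g in taxonomy.genera()
         if (ph := taxonomy.phylum_of(g.node_id)) and ph.name == "Chordata"),
        genera[0])
    hit_rows = []
    ann_rows = []
    ec_pool = ["3.1.3.2", "3.4.21.1", "3.1.3.5", "2.7.1.1", "1.11.1.7",
               "4.2.1.24", "6.3.2.19", "3.6.1.15"]
    go_terms = ["GO:0003824", "GO:0016787", "GO:0008152", "GO:0016301",
                "GO:0004672"]
    for i, cid in enumerate(sorted(truth.planted_keepers)):
        if i == 0:
            taxon, score = chordate_genus, 120.0
        elif i == 1:
            taxon, score = genera[int(rng.integers(len(genera)))], 49.9
        else:
            taxon = genera[int(rng.integers(len(genera)))]
            score = float(rng.uniform(60, 300))
        evalue = 10.0 ** -float(rng.uniform(10, 60))
        hit_rows.append({
            "qseqid": cid, "sseqid": f"prot_{i}", "pident": 90.0,
            "length": 200, "mismatch": 20, "gapopen": 0,
            "qstart": 1, "qend": 600, "sstart": 1, "send": 200,
            "evalue": evalue, "bitscore": score, "staxid": taxon})
        ec = ec_pool[i % len(ec_pool)]
        go = go_terms[i % len(go_terms)]
        # hydrolase contigs carry the planted enriched term GO:0016787
        if ec.startswith("3."):
            go = "GO:0016787"
        ann_rows.append({"contig_id": cid, "ec": ec, "go": go,
                         "category": taxonomy.category_of(taxon)})
    ontology = pd.DataFrame([
        {"term": "GO:0008152", "parent": ""},
        {"term": "GO:0003824", "parent": "GO:0008152"},
        {"term": "GO:0016787", "parent": "GO:0003824"},
        {"term": "GO:0016301", "parent": "GO:0003824"},
        {"term": "GO:0004672", "parent": "GO:0016301"},
    ])
    return ContigBundle(
        trap_contigs=contigs, leaf_contigs=leaf, host_transcripts=host,
        rrna_refs=rrna, protein_hits=pd.DataFrame(hit_rows),
        annotations=pd.DataFrame(ann_rows), ontology=ontology, truth=truth)


def make_phenotypes(config: SimulationConfig,
                    taxonomy: TaxonomyTree) -> pd.DataFrame:
    """Toy genus -> phenotype-trait table (multi-label).

    Emulates trait-database annotation of bacterial genera: each genus
    draws one or more labels per phenotype category (habitat, mobility,
    oxygen requirement, energy source); a fraction of genera stays
    unannotated so the 'unknown' mass is exercised.
    """
    rng = _rng(config, "contigs")  # shares a stream; order-stable
    traits = {
        "habitat": ["terrestrial", "soil", "aquatic", "host-associated"],
        "mobility": ["motile", "non-motile"],
        "oxygen": ["aerobic", "anaerobic", "facultative"],
        "energy": ["heterotroph", "phototroph", "lithotroph"],
    }
    rows = []
    for node in sorted(taxonomy.genera(), key=lambda n: n.node_id):
        if node.category != "Bacteria":
            continue
        if rng.random() < 0.2:
            continue  # unannotated genus
        for cat, pool in traits.items():
            n_labels = 1 + int(rng.random() < 0.3)  # multi-label sometimes
            chosen = rng.choice(len(pool), size=n_labels, replace=False)
            for c in chosen:
                rows.append({"genus": node.node_id, "category": cat,
                             "trait": pool[int(c)]})
    return pd.DataFrame(rows, columns=["genus", "category", "trait"])


# ---------------------------------------------------------------------------
# host expression

def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Host gene counts over the 8-sample design with planted DEGs.

    Gene expression lives on a log2 scale: a per-gene baseline U(6, 12),
    lognormal noise of sd ``expr_noise_sd`` per cell, and for the
    ``n_deg`` planted genes a ``deg_log2fc`` trap-vs-leaf difference
    (alternating sign) applied consistently in every pair. Planted genes
    start from a mid-range baseline and the elevated organ stays inside
    the null value envelope, so quantile normalization (which equalizes
    the per-sample value distributions, including their extremes)
    preserves the planted contrast instead of compressing it at the
    distribution tails. A configured number of genes is planted to fail
    the expressed-gene rule (unique read count 1, or total <= 5).
    """
    config.validate()
    rng = _rng(config, "expression")
    metadata = default_metadata()
    samples = list(metadata.index)
    genes = [f"gene_{i:04d}" for i in range(config.n_host_genes)]
    base = rng.uniform(6.0, 12.0, size=config.n_host_genes)
    lengths = pd.Series(rng.integers(500, 3000, size=config.n_host_genes),
                        index=genes, name="length")

    deg_genes = genes[: config.n_deg]
    signs = np.array([1 if i % 2 == 0 else -1 for i in range(config.n_deg)])
    # mid-range baseline so baseline + fold change stays within (6, 12)
    hi = 12.0 - config.deg_log2fc - 0.5
    base[: config.n_deg] = rng.uniform(6.5, max(hi, 6.6), size=config.n_deg)
    truth = GroundTruth(planted_deg_genes={
        g: float(s * config.deg_log2fc) for g, s in zip(deg_genes, signs)})

    log2_expr = np.empty((config.n_host_genes, len(samples)))
    for j, s in enumerate(samples):
        organ = metadata.at[s, "organ"]
        shift = np.zeros(config.n_host_genes)
        # up-regulated genes are elevated in traps, down-regulated genes
        # elevated in leaves; either way the difference is +-deg_log2fc
        if organ == "trap":
            shift[: config.n_deg] = np.where(signs > 0, config.deg_log2fc, 0.0)
        else:
            shift[: config.n_deg] = np.where(signs < 0, config.deg_log2fc, 0.0)
        noise = rng.normal(0.0, config.expr_noise_sd, size=config.n_host_genes)
        log2_expr[:, j] = base + shift + noise
    total = pd.DataFrame(np.round(2.0 ** log2_expr).astype(int),
                         index=genes, columns=samples)
    unique = (total * 0.8).astype(int)

    # plant expressed-rule failures on genes beyond the DEG block
    start = config.n_deg
    fails = genes[start: start + config.n_unexpressed]
    for k, g in enumerate(fails):
        if k % 2 == 0:
            unique.loc[g] = 1          # fails "more than one unique read"
        else:
            total.loc[g] = 5           # fails "more than five total reads"
            unique.loc[g] = 4
    truth.unexpressed_genes = list(fails)
    matrix = ExpressionMatrix(total=total, unique=unique, lengths=lengths)
    return matrix, truth
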