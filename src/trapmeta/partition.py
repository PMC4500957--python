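"""Quality trimming and rRNA / host / non-host read binning.

Reads are trimmed by the modified-Mott rule (retain the segment maximizing
the running sum of ``quality_limit - p_i`` over per-base error
probabilities, drop reads shorter than 80 bases afterwards), then each
read is assigned to reference sets by local alignment under the published
thresholds: an alignment covering at least 90% of the read at >= 80%
identity (or >= 97% in strict mode). Bins are decided in priority order
rRNA > host > non-host; the remainder after both references is the
non-host mRNA bin. Per-library composition is summarized with
half-up-rounded percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import LocalHit, ReferenceIndex
from .stats import percent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base error probabilities."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # per-base error probability, same length

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssignmentParams:
    """Published mapping thresholds: minimum aligned fraction of the read
    and minimum alignment identity."""

    min_length_fraction: float = 0.90
    min_identity: float = 0.80

    def __post_init__(self):
        for v in (self.min_length_fraction, self.min_identity):
            if not 0 < v <= 1:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class ReadAssignment:
    read_id: str
    ref_ids: list[str]
    hits: dict[str, LocalHit] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return bool(self.ref_ids)

    @property
    def unique(self) -> bool:
        return len(self.ref_ids) == 1


# ---------------------------------------------------------------------------
# trimming

def trim_read(read: ReadRecord, quality_limit: float = 0.05,
              min_len: int = 80) -> ReadRecord | None:
    """Modified-Mott trimming.

    Retains the contiguous segment maximizing sum(quality_limit - p_i);
    among equal-score segments the longest, then leftmost, is taken (a
    choice that makes trimming idempotent). Returns None when the read is
    dropped (empty, nonpositive best score, or fewer than ``min_len``
    retained bases).
    """
    if not 0 < quality_limit < 1:
        raise ValueError("quality_limit must lie in (0, 1)")
    n = len(read)
    if n == 0:
        return None
    scores = quality_limit - read.qualities
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    # sums[i, j] = score of segment [i, j); evaluate all O(n^2) segments
    sums = prefix[None, 1:] - prefix[:-1, None]  # rows: start, cols: end-1
    iu = np.triu_indices(n)
    seg_sums = sums[iu]
    best = seg_sums.max()
    if best <= 0:
        return None
    tied = np.flatnonzero(np.isclose(seg_sums, best, rtol=0, atol=1e-12))
    starts, ends = iu[0][tied], iu[1][tied] + 1
    lengths = ends - starts
    order = np.lexsort((starts, -lengths))  # longest, then leftmost
    s, e = int(starts[order[0]]), int(ends[order[0]])
    if e - s < min_len:
        return None
    return ReadRecord(read.read_id, read.sequence[s:e], read.qualities[s:e])


# ---------------------------------------------------------------------------
# classification

def classify_read(read: ReadRecord, refs: ReferenceIndex,
                  params: AssignmentParams) -> ReadAssignment:
    """Assign a read to every reference with a qualifying local alignment.

    Qualifying = some local alignment covers >= ``min_length_fraction`` of
    the read at >= ``min_identity``. A read shorter than the seed size has
    no candidates and is returned unassigned.
    """
    assignment = ReadAssignment(read.read_id, [])
    # edit-distance bound for the candidate prescreen: an alignment at the
    # identity threshold cannot exceed this many differences by much
    max_edit = int(np.ceil(len(read) * (1 - params.min_identity))) + 8
    for ref_id in sorted(refs.candidates(read.sequence, max_edit=max_edit)):
        hit = refs.align(read.sequence, ref_id)
        if hit is None:
            continue
        if (hit.read_fraction >= params.min_length_fraction
                and hit.identity >= params.min_identity):
            assignment.ref_ids.append(ref_id)
            assignment.hits[ref_id] = hit
    return assignment


# ---------------------------------------------------------------------------
# library partitioning

@dataclass
class PartitionResult:
    """Bins plus bookkeeping for one library."""

    sample_id: str
    bins: dict[str, list[ReadRecord]]
    rrna_assignments: pd.DataFrame  # read_id, sample_id, ref_id, unique
    counts: dict[str, int]
    n_dropped: int = 0


def partition_library(
    reads: list[ReadRecord],
    rrna_refs: ReferenceIndex,
    host_refs: ReferenceIndex,
    sample_id: str = "sample",
    strict_identity: float = 0.97,
    fallback_identity: float = 0.80,
    host_identity: float = 0.80,
    min_length_fraction: float = 0.90,
    rrna_bin: str = "strict",
    trim: bool = True,
    quality_limit: float = 0.05,
    min_len: int = 80,
) -> PartitionResult:
    """Trim reads and partition them into rRNA / host / non-host bins.

    rRNA assignment is evaluated at both the strict (97%) and fallback
    (80%) identity thresholds; ``rrna_bin`` selects which one defines the
    bin fed downstream (strict by default). A read matching both rRNA and
    host references counts as rRNA (priority order rRNA > host >
    non-host); reads matching neither form the non-host mRNA bin.
    """
    if rrna_bin not in ("strict", "loose"):
        raise ValueError("rrna_bin must be 'strict' or 'loose'")
    strict = AssignmentParams(min_length_fraction, strict_identity)
    loose = AssignmentParams(min_length_fraction, fallback_identity)
    host_params = AssignmentParams(min_length_fraction, host_identity)

    kept: list[ReadRecord] = []
    n_dropped = 0
    for read in reads:
        if trim:
            t = trim_read(read, quality_limit=quality_limit, min_len=min_len)
            if t is None:
                n_dropped += 1
                continue
            kept.append(t)
        else:
            kept.append(read)
    if not kept:
        logger.warning("sample %s has zero high-quality reads", sample_id)

    bins: dict[str, list[ReadRecord]] = {"rRNA": [], "host": [], "nonhost": []}
    n_rrna_strict = 0
    n_rrna_loose = 0
    assign_rows = []
    for read in kept:
        loose_asn = classify_read(read, rrna_refs, loose)
        strict_ids = [r for r in loose_asn.ref_ids
                      if loose_asn.hits[r].identity >= strict_identity]
        if loose_asn.assigned:
            n_rrna_loose += 1
        if strict_ids:
            n_rrna_strict += 1
        bin_ids = strict_ids if rrna_bin == "strict" else loose_asn.ref_ids
        if bin_ids:
            bins["rRNA"].append(read)
            for rid in bin_ids:
                assign_rows.append({
                    "read_id": read.read_id, "sample_id": sample_id,
                    "ref_id": rid, "unique": len(bin_ids) == 1,
                })
            continue
        host_asn = classify_read(read, host_refs, host_params)
        bins["host" if host_asn.assigned else "nonhost"].append(read)

    counts = {
        "total": len(kept),
        "rrna_strict": n_rrna_strict,
        "rrna_loose": n_rrna_loose,
        "host": len(bins["host"]),
        "nonhost": len(bins["nonhost"]),
    }
    assignments = pd.DataFrame(
        assign_rows, columns=["read_id", "sample_id", "ref_id", "unique"])
    return PartitionResult(sample_id=sample_id, bins=bins,
                           rrna_assignments=assignments, counts=counts,
                           n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# composition summary

class CompositionSummary:
    """Per-library read-composition summary (totals, bins, percentages).

    Percentages are 100 * count / total, rounded half-up to ``decimals``
    (2 by default, the convention of the published summary table).
    """

    COLUMNS = ["sample_id", "total_reads",
               "rrna_reads", "rrna_pct", "rrna_reads_loose", "rrna_pct_loose",
               "host_reads", "host_pct", "nonhost_reads", "nonhost_pct"]

    def __init__(self, frame: pd.DataFrame, decimals: int = 2):
        self.frame = frame
        self.decimals = decimals

    @classmethod
    def from_counts(cls, rows: list[dict], decimals: int = 2) -> "CompositionSummary":
        """Build a summary from per-sample raw counts.

        Each row needs ``sample_id, total, rrna_strict, host, nonhost`` and
        optionally ``rrna_loose``. Bin counts must not exceed the total.
        """
        out = []
        for row in rows:
            total = int(row["total"])
            rec = {"sample_id": row["sample_id"], "total_reads": total}
            for key, name in (("rrna_strict", "rrna"), ("rrna_loose", "rrna_loose"),
                              ("host", "host"), ("nonhost", "nonhost")):
                if key not in row or row[key] is None:
                    rec[f"{name}_reads"] = np.nan
                    rec[f"{name}_pct"] = np.nan
                    continue
                count = int(row[key])
                if count > total:
                    raise ValueError(
                        f"{row['sample_id']}: bin {key} ({count}) exceeds total {total}")
                rec[f"{name}_reads"] = count
                rec[f"{name}_pct"] = percent(count, total, decimals) if total else 0.0
            out.append(rec)
        frame = pd.DataFrame(out)
        frame = frame.rename(columns={"rrna_loose_reads": "rrna_reads_loose",
                                      "rrna_loose_pct": "rrna_pct_loose"})
        return cls(frame[cls.COLUMNS], decimals=decimals)

    @classmethod
    def from_partitions(cls, results: list[PartitionResult],
                        decimals: int = 2) -> "CompositionSummary":
        rows = [
            {"sample_id": r.sample_id, "total": r.counts["total"],
             "rrna_strict": r.counts["rrna_strict"],
             "rrna_loose": r.counts["rrna_loose"],
             "host": r.counts["host"], "nonhost": r.counts["nonhost"]}
            for r in results
        ]
        return cls.from_counts(rows, decimals=decimals)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33 via Biopython)

def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        phred = np.asarray(rec.letter_annotations["phred_quality"], dtype=float)
        reads.append(ReadRecord(rec.id, str(rec.seq),
                                np.power(10.0, -phred / 10.0)))
    return reads


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    records = []
    for r in reads:
        phred = np.clip(np.rint(-10.0 * np.log10(
            np.clip(r.qualities, 1e-9, 1.0))), 0, 60).astype(int)
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = phred.tolist()
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
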