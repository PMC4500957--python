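"""Similarity machinery behind read binning and contig subtraction.

Two regimes, two engines:

* short-read classification against reference sets — Biopython's
  ``PairwiseAligner`` in local mode with documented scores (match +1,
  mismatch -2, gap open -3, gap extend -1). Only the published thresholds
  are normative (alignment covering >= 90% of the read at >= 80% or 97%
  identity); the scoring scheme is configurable and recorded here for
  reproducibility. A k-mer seed index prunes the candidate references; the
  index is an implementation detail, the threshold contract is not.
* kilobase-scale contig-vs-reference identity — edlib bit-vector alignment
  with an extended CIGAR, since full DP on contig pairs is wasteful.
  Identity = matches / alignment columns, terminal gaps excluded
  (USEARCH-style "global" identity).

``N`` bases never count as matches; identity denominators are alignment
columns excluding end gaps throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_SCORES = {"match": 1.0, "mismatch": -2.0,
                  "gap_open": -3.0, "gap_extend": -1.0}

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _make_aligner(scores=None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORES, **(scores or {}))
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # explicit alphabet so N can be forced to never score as a match
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                mat[a, b] = s["match"]
            else:
                mat[a, b] = s["mismatch"]
    aligner.substitution_matrix = mat
    aligner.open_gap_score = s["gap_open"]
    aligner.extend_gap_score = s["gap_extend"]
    return aligner


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a read against one reference."""

    ref_id: str
    identity: float        # matches / alignment columns (no end gaps)
    read_fraction: float   # aligned read span / read length
    score: float


@dataclass
class ReferenceIndex:
    """Reference sequences plus a k-mer seed index.

    Candidate references for a read are those sharing at least one exact
    k-mer; reads shorter than the seed size have no candidates and are
    therefore unassignable, matching the contract that classification
    requires a seedable read.
    """

    references: dict[str, str]
    k: int = 15
    scores: dict | None = None
    _index: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _aligner: Align.PairwiseAligner | None = field(default=None, repr=False)

    def __post_init__(self):
        self.references = {rid: seq.upper() for rid, seq in self.references.items()}
        for rid, seq in self.references.items():
            for i in range(len(seq) - self.k + 1):
                self._index.setdefault(seq[i:i + self.k], set()).add(rid)
        self._aligner = _make_aligner(self.scores)

    def candidates(self, read_seq: str, max_edit: int | None = None) -> set[str]:
        """References worth aligning against.

        Exact k-mer sharing finds near-identical targets cheaply; when
        ``max_edit`` is given, the remaining references are screened by a
        banded edit-distance bound (edlib infix mode) so that divergent
        but still in-threshold targets are not lost to seeding. A read
        shorter than the seed size has no candidates.
        """
        seq = read_seq.upper()
        if len(seq) < self.k:
            return set()
        out: set[str] = set()
        for i in range(len(seq) - self.k + 1):
            out |= self._index.get(seq[i:i + self.k], set())
        if max_edit is not None:
            for rid, ref in self.references.items():
                if rid in out or len(ref) < len(seq):
                    continue
                res = edlib.align(seq, ref, mode="HW", k=max_edit)
                if res["editDistance"] != -1:
                    out.add(rid)
        return out

    def align(self, read_seq: str, ref_id: str) -> LocalHit | None:
        """Best-scoring local alignment of the read against one reference."""
        seq = read_seq.upper()
        ref = self.references[ref_id]
        alns = self._aligner.align(seq, ref)
        if len(alns) == 0 or alns.score <= 0:
            return None
        aln = alns[0]
        blocks_q, blocks_t = aln.aligned
        matched = 0
        block_cols = 0
        for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
            block_cols += qe - qs
            for a, b in zip(seq[qs:qe], ref[ts:te]):
                if a == b and a != "N":
                    matched += 1
        q_span = int(blocks_q[-1][1] - blocks_q[0][0])
        t_span = int(blocks_t[-1][1] - blocks_t[0][0])
        columns = block_cols + (q_span - block_cols) + (t_span - block_cols)
        if columns == 0:
            return None
        return LocalHit(
            ref_id=ref_id,
            identity=matched / columns,
            read_fraction=q_span / len(seq),
            score=float(alns.score),
        )


def cigar_identity(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an extended CIGAR (=/X/I/D)."""
    matches = 0
    columns = 0
    for length, op in _CIGAR_RE.findall(cigar):
        n = int(length)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def sequence_identity(a: str, b: str, end_free: bool = True) -> float:
    """Pairwise identity between two sequences.

    With ``end_free`` (default) the shorter sequence is aligned as an infix
    of the longer one, i.e. terminal gaps on the longer sequence are not
    charged — the convention of greedy 80%-identity clustering tools.
    Identity = matched columns / alignment columns.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    mode = "HW" if end_free else "NW"
    res = edlib.align(query, target, mode=mode, task="path")
    matches, columns = cigar_identity(res["cigar"])
    if columns == 0:
        return 0.0
    return matches / columns


def infix_match(query: str, target: str, min_identity: float = 0.8,
                min_columns: int = 100) -> bool:
    """Does ``query`` contain/represent a region of ``target`` (or vice
    versa) at the given identity over at least ``min_columns`` columns?

    Used for subtraction stages (host / rRNA / leaf matching) when no
    precomputed hit table is supplied.
    """
    a, b = query.upper(), target.upper()
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(q, t, mode="HW", task="path")
    matches, columns = cigar_identity(res["cigar"])
    if columns < min(min_columns, len(q)):
        return False
    return columns > 0 and matches / columns >= min_identity
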