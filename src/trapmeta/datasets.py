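"""Published reference numbers shipped with the package.

The per-library sequencing summary of the Genlisea trap/leaf
metatranscriptome study (raw data at ENA, project PRJEB1867): total
high-quality reads per library and the three bin counts — rRNA-mapped
reads at the strict (97% identity) and standard (80%) thresholds, reads
mapped to the annotated G. nigrocaulis genome ("host"), and reads mapped
to the non-redundant microbe contigs ("nonhost"). These printed counts
are inputs for composition arithmetic (the percentage columns of the
published table are recomputable from them), not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

from .stats import round_half_up

_ROWS = [
    # sample_id, species, season, organ, total, rrna_strict, rrna_loose, host, nonhost
    ("NIG_SS_t", "NIG", "SS", "trap", 55_570_966, 122_734, 218_975, 18_190_523, 6_790_717),
    ("NIG_SS_l", "NIG", "SS", "leaf", 68_905_010, 290_521, 492_631, 39_416_889, 148_530),
    ("NIG_WS_t", "NIG", "WS", "trap", 39_914_128, 195_871, 297_182, 17_107_634, 2_811_952),
    ("NIG_WS_l", "NIG", "WS", "leaf", 31_504_414, 127_178, 194_034, 21_144_415, 10_564),
    ("HIS_SS_t", "HIS", "SS", "trap", 83_721_886, 131_033, 203_470, 13_312_311, 40_547),
    ("HIS_SS_l", "HIS", "SS", "leaf", 73_706_164, 41_958, 72_126, 12_170_713, 17_254),
    ("HIS_WS_t", "HIS", "WS", "trap", 60_971_788, 91_577, 133_429, 8_733_316, 2_783),
    ("HIS_WS_l", "HIS", "WS", "leaf", 60_849_726, 80_315, 124_529, 7_471_549, 538_121),
]


def published_library_composition() -> pd.DataFrame:
    """The eight-library read-count summary (counts only, no percentages)."""
    return pd.DataFrame(
        _ROWS,
        columns=["sample_id", "species", "season", "organ", "total",
                 "rrna_strict", "rrna_loose", "host", "nonhost"],
    )


# Rhodospirillaceae share of bacterial reads in G. nigrocaulis traps, and
# the same family's share of Proteobacteria reads — published together,
# which pins down the Proteobacteria share of bacterial reads.
RHODOSPIRILLACEAE_PCT_OF_BACTERIA = 35.9
RHODOSPIRILLACEAE_PCT_OF_PROTEOBACTERIA = 55.9


def proteobacteria_share(
    family_pct_of_bacteria: float = RHODOSPIRILLACEAE_PCT_OF_BACTERIA,
    family_pct_of_phylum: float = RHODOSPIRILLACEAE_PCT_OF_PROTEOBACTERIA,
    decimals: int = 1,
) -> float:
    """Phylum share of bacterial reads implied by one family's two shares.

    If a family makes up a% of all bacterial reads and b% of its phylum's
    reads, the phylum holds 100*a/b percent of the bacterial reads.
    """
    if family_pct_of_phylum <= 0:
        raise ValueError("phylum-level share must be positive")
    return round_half_up(100.0 * family_pct_of_bacteria / family_pct_of_phylum,
                         decimals)
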