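"""The 8-library sampling design: 2 species x 2 seasons x (trap, leaf).

Species codes NIG and HIS, seasons SS (summer) and WS (winter); a trap
sample and its corresponding leaf sample from the same species and season
form a pair for fold-change and paired-test purposes.
"""

from __future__ import annotations

import pandas as pd

SPECIES = ("NIG", "HIS")
SEASONS = ("SS", "WS")
ORGANS = ("trap", "leaf")


def sample_id(species: str, season: str, organ: str) -> str:
    return f"{species}_{season}_{'t' if organ == 'trap' else 'l'}"


def default_metadata() -> pd.DataFrame:
    """Sample metadata table for the standard 8-library design."""
    rows = []
    for sp in SPECIES:
        for se in SEASONS:
            for organ in ORGANS:
                rows.append({
                    "sample_id": sample_id(sp, se, organ),
                    "species": sp,
                    "season": se,
                    "organ": organ,
                    "pair_id": f"{sp}_{se}",
                })
    return pd.DataFrame(rows).set_index("sample_id")


def trap_leaf_pairs(metadata: pd.DataFrame) -> list[tuple[str, str]]:
    """(trap_sample, leaf_sample) tuples, one per species/season pair."""
    pairs = []
    for pair_id, grp in metadata.groupby("pair_id", sort=True):
        traps = grp.index[grp["organ"] == "trap"].tolist()
        leaves = grp.index[grp["organ"] == "leaf"].tolist()
        if len(traps) != 1 or len(leaves) != 1:
            raise ValueError(f"pair {pair_id!r} is not one trap + one leaf")
        pairs.append((traps[0], leaves[0]))
    return pairs
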