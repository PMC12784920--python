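"""Small reference tables bundled for worked examples.

Both tables come from a published 2-vs-2 case-control in situ Hi-C study of
ovine mandibular bone (two animals with mandibular prognathism, "UNDER",
vs two controls): the per-library valid-pair counts, and five representative
1 Mb windows with higher boundary density in the affected group.  They serve
as tiny real-world inputs for the QC and hotspot stages.
"""

from __future__ import annotations

import pandas as pd

from .qc import PairStats


def sheep_pair_stats() -> list[PairStats]:
    """Valid-pair counts of the four ovine Hi-C libraries (cases: dibaotian*)."""
    rows = [
        ("dibaotian1", "UNDER", 444_574_329, 234_569_028, 210_005_301),
        ("dibaotian2", "UNDER", 481_591_477, 252_188_788, 229_402_689),
        ("duizhao1", "CTRL", 439_112_437, 238_565_417, 200_547_020),
        ("duizhao2", "CTRL", 532_221_884, 319_149_103, 213_072_781),
    ]
    return [PairStats(sample=s, group=g, valid_pairs=v, cis=c, trans=t)
            for s, g, v, c, t in rows]


def sheep_density_windows() -> pd.DataFrame:
    """Representative 1 Mb boundary-density windows of the ovine study.

    Per-group boundary counts for five UNDER-enriched windows; the ``Delta``
    column is left to be recomputed as Count_UNDER − Count_CTRL.
    """
    rows = [
        ("NC_056080.1", 49_000_000, 50_000_000, 0, 3, "UBQLN2/FOXR2/RRAGB/KLF8"),
        ("NC_056056.1", 151_000_000, 152_000_000, 1, 3, "IL22/IL26/IFNG/MDM1"),
        ("NC_056056.1", 65_000_000, 66_000_000, 0, 2, "VRK2/FANCL"),
        ("NC_056054.1", 145_000_000, 146_000_000, 0, 2, "ROBO2"),
        ("NC_056055.1", 9_000_000, 10_000_000, 1, 3,
         "COL27A1/AKNA/KIF12/AMBP/WHRN/ZNF618"),
    ]
    return pd.DataFrame(rows, columns=["Chr", "Start", "End", "Count_CTRL",
                                       "Count_UNDER", "Genes"])
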