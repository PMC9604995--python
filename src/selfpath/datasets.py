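"""Bundled genotypic-count data for six selfed cacao families.

Genotypic class counts (AA / AB / BB over ~3,380 Infinium SNPs) for four
cacao founder clones (TSH-1188, PS-13.19, CCN-51, SIAL-169), their genotyped
S1 plants and 49 S1/S2 offspring in six selfed families A-F.  The table is
the canonical counts-only input for :class:`selfpath.SelfingFamilyModel`
and the package's regression benchmark: observed and Mendelian-expected
homozygosities, per-offspring chi-square deviation tests, standardized
homozygosities and family summaries computed from these counts must
reproduce the published per-individual and per-family values.

The S1 parent of family C (TSH-1188_S1_1) was never genotyped; its row
carries no counts and analyses fall back to a surrogate built from its
genotyped siblings (see ``SelfingFamilyModel.fit``).
"""

from __future__ import annotations

import pandas as pd

# (family, generation, individual, parent, n_aa, n_ab, n_bb); None = ungenotyped
_CACAO_ROWS = [
    # founders (family label "-" : not members of an offspring family)
    ("-", "S0", "TSH-1188", None, 812, 1770, 798),
    ("-", "S0", "PS-13.19", None, 813, 1721, 846),
    ("-", "S0", "CCN-51", None, 767, 1846, 767),
    ("-", "S0", "SIAL-169", None, 1610, 106, 1664),
    # S1 plants selfed to make the S2 families
    ("A", "S1", "TSH-1188_S1_2", "TSH-1188", 924, 1542, 914),
    ("B", "S1", "TSH-1188_S1_3", "TSH-1188", 909, 1536, 934),
    ("C", "S1", "TSH-1188_S1_1", "TSH-1188", None, None, None),
    ("E", "S1", "CCN-51_S1_1", "CCN-51", 1239, 874, 1267),
    # family A: S2 of TSH-1188_S1_2
    ("A", "S2", "TSH-1188_S2_2_2", "TSH-1188_S1_2", 1193, 1044, 1141),
    ("A", "S2", "TSH-1188_S2_2_1", "TSH-1188_S1_2", 1285, 817, 1267),
    ("A", "S2", "TSH-1188_S2_2_3", "TSH-1188_S1_2", 1317, 746, 1317),
    ("A", "S2", "TSH-1188_S2_2_7", "TSH-1188_S1_2", 1295, 740, 1343),
    ("A", "S2", "TSH-1188_S2_2_6", "TSH-1188_S1_2", 1285, 729, 1363),
    ("A", "S2", "TSH-1188_S2_2_5", "TSH-1188_S1_2", 1350, 670, 1359),
    ("A", "S2", "TSH-1188_S2_2_8", "TSH-1188_S1_2", 1387, 580, 1409),
    ("A", "S2", "TSH-1188_S2_2_4", "TSH-1188_S1_2", 1474, 465, 1440),
    # family B: S2 of TSH-1188_S1_3
    ("B", "S2", "TSH-1188_S2_3_3", "TSH-1188_S1_3", 1186, 998, 1193),
    ("B", "S2", "TSH-1188_S2_3_4", "TSH-1188_S1_3", 1183, 958, 1238),
    ("B", "S2", "TSH-1188_S2_3_1", "TSH-1188_S1_3", 1219, 954, 1206),
    ("B", "S2", "TSH-1188_S2_3_5", "TSH-1188_S1_3", 1314, 752, 1311),
    ("B", "S2", "TSH-1188_S2_3_2", "TSH-1188_S1_3", 1321, 716, 1339),
    ("B", "S2", "TSH-1188_S2_3_6", "TSH-1188_S1_3", 1386, 627, 1366),
    # family C: S2 of the ungenotyped TSH-1188_S1_1
    ("C", "S2", "TSH-1188_S2_1_1", "TSH-1188_S1_1", 1250, 880, 1249),
    ("C", "S2", "TSH-1188_S2_1_7", "TSH-1188_S1_1", 1269, 827, 1282),
    ("C", "S2", "TSH-1188_S2_1_8", "TSH-1188_S1_1", 1335, 702, 1332),
    ("C", "S2", "TSH-1188_S2_1_6", "TSH-1188_S1_1", 1345, 691, 1344),
    ("C", "S2", "TSH-1188_S2_1_5", "TSH-1188_S1_1", 1335, 665, 1352),
    ("C", "S2", "TSH-1188_S2_1_4", "TSH-1188_S1_1", 1396, 615, 1368),
    ("C", "S2", "TSH-1188_S2_1_3", "TSH-1188_S1_1", 1316, 589, 1333),
    # family D: S1 of PS-13.19
    ("D", "S1", "PS-13.19_S1_1", "PS-13.19", 1051, 1266, 1063),
    ("D", "S1", "PS-13.19_S1_5", "PS-13.19", 1058, 1184, 1138),
    ("D", "S1", "PS-13.19_S1_4", "PS-13.19", 1123, 1093, 1158),
    ("D", "S1", "PS-13.19_S1_7", "PS-13.19", 1150, 966, 1226),
    ("D", "S1", "PS-13.19_S1_6", "PS-13.19", 1192, 934, 1252),
    ("D", "S1", "PS-13.19_S1_3", "PS-13.19", 1215, 888, 1275),
    ("D", "S1", "PS-13.19_S1_2", "PS-13.19", 1211, 829, 1340),
    ("D", "S1", "PS-13.19_S1_8", "PS-13.19", 1262, 791, 1324),
    ("D", "S1", "PS-13.19_S1_9", "PS-13.19", 751, 619, 1598),
    # family E: S2 of CCN-51_S1_1
    ("E", "S2", "CCN-51_S2_1_8", "CCN-51_S1_1", 1415, 510, 1455),
    ("E", "S2", "CCN-51_S2_1_5", "CCN-51_S1_1", 1438, 507, 1434),
    ("E", "S2", "CCN-51_S2_1_4", "CCN-51_S1_1", 1443, 445, 1492),
    ("E", "S2", "CCN-51_S2_1_3", "CCN-51_S1_1", 1470, 445, 1465),
    ("E", "S2", "CCN-51_S2_1_9", "CCN-51_S1_1", 1452, 444, 1484),
    ("E", "S2", "CCN-51_S2_1_6", "CCN-51_S1_1", 1464, 440, 1476),
    ("E", "S2", "CCN-51_S2_1_2", "CCN-51_S1_1", 1436, 439, 1505),
    ("E", "S2", "CCN-51_S2_1_1", "CCN-51_S1_1", 1473, 425, 1480),
    ("E", "S2", "CCN-51_S2_1_10", "CCN-51_S1_1", 1483, 411, 1486),
    ("E", "S2", "CCN-51_S2_1_7", "CCN-51_S1_1", 1489, 409, 1480),
    # family F: S1 of SIAL-169
    ("F", "S1", "SIAL-169_S1_1", "SIAL-169", 1625, 72, 1683),
    ("F", "S1", "SIAL-169_S1_7", "SIAL-169", 1638, 52, 1690),
    ("F", "S1", "SIAL-169_S1_6", "SIAL-169", 1642, 49, 1689),
    ("F", "S1", "SIAL-169_S1_2", "SIAL-169", 1644, 45, 1691),
    ("F", "S1", "SIAL-169_S1_5", "SIAL-169", 1641, 41, 1697),
    ("F", "S1", "SIAL-169_S1_3", "SIAL-169", 1643, 41, 1696),
]

#: parent rule reproducing the published family-C chi-squares: use sibling
#: TSH-1188_S1_3's counts in place of the ungenotyped TSH-1188_S1_1
CACAO_FAMILY_C_PARENT_RULE = {"C": "TSH-1188_S1_3"}


def load_cacao_counts() -> pd.DataFrame:
    """Counts table ready for ``SelfingFamilyModel.from_counts_table``."""
    return pd.DataFrame(
        _CACAO_ROWS,
        columns=["family", "generation", "individual", "parent", "n_aa", "n_ab", "n_bb"],
    )
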