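"""Bundled worked-example region tables.

Two small labeled-region tables from published plant comparisons, used in
the documentation, tests and the acceptance script:

* ``grape_chr13_regions`` — the six merged collinear regions that a
  willow (*Salix sinopurpurea*) genome leaves on grape (*Vitis vinifera*)
  chromosome 13; the willow lineage carries a recent whole-genome
  duplication, so these regions combine into two rounds.
* ``arabidopsis_chr3_regions`` — the seven regions that *Brassica rapa*
  leaves on *Arabidopsis thaliana* chromosome 3; the Brassica lineage
  carries a whole-genome triplication, giving three rounds.

Only the corner coordinates and gene counts are data; the delta columns
are recomputed from the corners on load.  The reference chromosome
lengths are the gene counts consistent with the coverage indices reported
for these comparisons (grape chr 13: 947/1281 = 73.93%, 909/1281 =
70.96%; Arabidopsis chr 3: 4793/5437 = 88.16%, 3799/5437 = 69.87%,
3533/5437 = 64.98%).
"""

from __future__ import annotations

import io as _io

from .io import read_box_table
from .model import ClusterBox

__all__ = [
    "grape_chr13_regions",
    "arabidopsis_chr3_regions",
    "GRAPE_CHR13_LEN",
    "ARABIDOPSIS_CHR3_LEN",
]

#: gene count of grape chromosome 13 (reference axis of the willow example)
GRAPE_CHR13_LEN = 1281
#: gene count of Arabidopsis chromosome 3 (reference axis of the Brassica example)
ARABIDOPSIS_CHR3_LEN = 5437

_GRAPE_CHR13_COMBINE = """\
chr1,chr2,id,l_x,l_y,num,r_x,r_y,∆y,∆x
8,13,1,592,1267,56,671,1155,112,79
8,13,2,78,1089,239,605,446,643,527
9,13,1,378,257,63,478,89,168,100
10,13,1,1327,1267,65,1426,1157,110,99
10,13,2,1419,1088,276,1934,457,631,515
16,13,1,1163,283,42,1235,91,192,72
"""

_ARABIDOPSIS_CHR3_COMBINE = """\
chr1,chr2,id,l_x,l_y,num,r_x,r_y,∆y,∆x
1,3,1,2581,5431,1036,3948,2863,2568,1367
3,3,1,2919,5436,857,4001,2763,2673,1082
4,3,1,3,1231,501,631,0,1231,628
5,3,1,1955,5432,1374,3668,3021,2411,1713
6,3,1,1571,2132,260,2021,1462,670,450
7,3,1,1555,1130,373,1998,8,1122,443
9,3,1,3322,1458,827,4386,8,1450,1064
"""


def grape_chr13_regions() -> list[ClusterBox]:
    """Six merged regions of willow against grape chromosome 13."""
    return read_box_table(_io.StringIO(_GRAPE_CHR13_COMBINE))


def arabidopsis_chr3_regions() -> list[ClusterBox]:
    """Seven merged regions of Brassica rapa against Arabidopsis chromosome 3."""
    return read_box_table(_io.StringIO(_ARABIDOPSIS_CHR3_COMBINE))
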