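"""Reference values from a whole-genome-sequenced collared flycatcher
three-generation pedigree (4 grandparents, 2 F1 parents, 5 F2 offspring;
10 scored meioses, 5 per sex).

These published per-chromosome recombination distances and the matching
sex-average linkage-map lengths are bundled for the worked examples and
for checking the package's map arithmetic against an independent,
externally derived dataset.  Distances are in cM, rates in cM/Mb.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

N_MEIOSES = 10
N_MEIOSES_PER_SEX = 5

# autosomal crossover counts by parental origin over the 5 + 5 meioses
N_AUTOSOMAL_CO = 305
N_MATERNAL_AUTOSOMAL_CO = 119
N_PATERNAL_AUTOSOMAL_CO = 186
N_CO_TOTAL = 325

# Z chromosome: 20 events, 2 maternal, both inside the ~0.6 Mb
# pseudoautosomal region
N_Z_CO = 20
N_Z_MATERNAL_PAR_CO = 2
PAR_LENGTH_MB = 0.6

# sex-specific autosomal rates (cM/Mb)
RATE_FEMALE_CM_PER_MB = 2.28
RATE_MALE_CM_PER_MB = 3.56

# non-crossover gene conversions: 229 of 267 events were weak:strong;
# the strong allele was transmitted in 59% -> 135 W>S vs 94 S>W
N_NCO_TOTAL = 267
N_NCO_WS_SITES = 229
N_WS_CONVERSIONS = 135
N_SW_CONVERSIONS = 94

_TABLE = """\
chrom	distance_cM	rate_cM_per_Mb	linkage_cM
1	260	2.2	246
1A	180	2.4	206
2	290	1.8	316
3	210	1.8	225
4	160	2.3	167
4A	40	1.9	80
5	200	3.1	170
6	90	2.4	121
7	100	2.5	122
8	100	3.1	96
9	60	2.2	96
10	80	3.7	94
11	70	3.2	81
12	60	2.7	84
13	110	5.9	87
14	80	4.6	87
15	110	7.4	59
17	60	4.8	73
18	100	7.6	79
19	30	2.5	58
20	60	3.8	53
21	60	7.4	48
22	60	10.5	53
23	60	7.6	49
24	60	7.5	50
25	60	21.4	47
26	70	9.1	46
27	90	16.1	73
28	60	9.7	48
LGE22	60	27.9	53
Z	180	3.0	161
"""


def flycatcher_map_table() -> pd.DataFrame:
    """Per-chromosome observed recombination distance, rate and
    sex-average linkage length (the Z row is a male map length)."""
    df = pd.read_csv(StringIO(_TABLE), sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df
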