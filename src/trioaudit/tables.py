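"""Published per-sample variant-count table, packaged as a fixture.

The 27-row table (8 parents + 19 embryos) of joint-call variant counts,
TrioDeNovo candidate counts, and final filtered SNV/indel counts from the
trio gene-editing audit.  Parents carry only the joint-call count.  These
numbers are the inputs to the published rank-sum comparisons and medians.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["sample", "group", "relationship", "passing_variants",
            "candidate_dnms", "final_snv", "final_indel"]

_ROWS = [
    ("MD5617a", "-", "parent", 225408, None, None, None),
    ("MD5618a", "-", "parent", 229105, None, None, None),
    ("MD5630a", "cas9 only", "embryo", 226692, 7106, 13, 0),
    ("MD5631a", "cas9 only", "embryo", 216975, 6533, 11, 0),
    ("MD5632a", "cas9 only", "embryo", 217421, 6626, 29, 1),
    ("MD5619a", "-", "parent", 226236, None, None, None),
    ("MD5620a", "-", "parent", 230156, None, None, None),
    ("MD5624a", "no injection", "embryo", 228022, 7377, 25, 4),
    ("MD5625a", "no injection", "embryo", 219537, 6599, 22, 2),
    ("MD5626a", "no injection", "embryo", 217827, 6510, 28, 0),
    ("MD5616a", "-", "parent", 224201, None, None, None),
    ("MD5623a", "-", "parent", 221461, None, None, None),
    ("MD5627a", "sham injection", "embryo", 226709, 7732, 15, 2),
    ("MD5628a", "sham injection", "embryo", 225793, 7693, 21, 2),
    ("MD5629a", "sham injection", "embryo", 224692, 7646, 19, 0),
    ("MD5621a", "-", "parent", 228855, None, None, None),
    ("MD5622a", "-", "parent", 228994, None, None, None),
    ("MD5633a", "Tyr2R treated", "embryo", 228026, 7083, 19, 0),
    ("MD5634a", "Tyr2R treated", "embryo", 225671, 6837, 14, 3),
    ("MD5635a", "Tyr2R treated", "embryo", 231888, 7308, 22, 5),
    ("MD5636a", "Tyr2R treated", "embryo", 226002, 6985, 21, 2),
    ("MD5637a", "Tyr2R treated", "embryo", 221699, 6618, 20, 1),
    ("MD5638a", "Tyr2F treated", "embryo", 222030, 6852, 15, 1),
    ("MD5639a", "Tyr2F treated", "embryo", 219136, 6440, 13, 2),
    ("MD5640a", "Tyr2F treated", "embryo", 220946, 6750, 11, 1),
    ("MD5641a", "Tyr2F treated", "embryo", 222174, 6803, 14, 1),
    ("MD5642a", "Tyr2F treated", "embryo", 226899, 7000, 23, 1),
]

CONTROL_GROUPS = ["cas9 only", "no injection", "sham injection"]
TREATED_GROUPS = ["Tyr2F treated", "Tyr2R treated"]

# guides used in the audited experiment (protospacer, PAM pattern)
GUIDE_SEQUENCES = {
    "Tyr2R": "GCTCCCATCTTCAGCAGATG",
    "Tyr2F": "TTTCCAGGATTACGTAATAG",
}


def fixture_table1() -> pd.DataFrame:
    """The published 27-sample count table, exactly as printed."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def fixture_embryo_counts() -> pd.DataFrame:
    """Embryo rows only (19), with group and final SNV/indel counts."""
    df = fixture_table1()
    return df[df["relationship"] == "embryo"].reset_index(drop=True)
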