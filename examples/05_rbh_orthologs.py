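"""Select one-to-one orthologs by reciprocal best hit.

Builds two tiny outfmt-6-like similarity tables and keeps the pairs that
are each other's best hit — the ortholog sets used for between-species
Ks distributions.
"""

import pandas as pd

from wgtkit import rbh_orthologs

cols = ["query", "subject", "bitscore", "evalue"]
ab = pd.DataFrame(
    [
        ("lba_1", "sly_1", 820, 1e-90),
        ("lba_1", "sly_2", 310, 1e-30),
        ("lba_2", "sly_2", 640, 1e-70),
        ("lba_3", "sly_2", 500, 1e-55),  # best hit, but not reciprocated
    ],
    columns=cols,
)
ba = pd.DataFrame(
    [
        ("sly_1", "lba_1", 815, 1e-89),
        ("sly_2", "lba_2", 650, 1e-71),
        ("sly_2", "lba_3", 480, 1e-52),
    ],
    columns=cols,
)

pairs = rbh_orthologs(ab, ba)
print("reciprocal best hits:")
for a, b in pairs:
    print(f"  {a} <-> {b}")
# lba_3 hits sly_2 best, but sly_2 prefers lba_2, so lba_3 is excluded:
# the output is strictly one-to-one.
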