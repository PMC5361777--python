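"""Greedy redundancy collapse at the 95% identity threshold.

Three near-identical variants and one fragment collapse into a single
non-redundant cluster represented by the longest member; an unrelated
sequence seeds its own cluster.
"""

import numpy as np

from tickpi import ProteinRecord, dedup, mutate_to_identity
from tickpi.records import CANONICAL_AA

rng = np.random.default_rng(4)
base = "".join(rng.choice(list(CANONICAL_AA), 150))

records = [
    ProteinRecord("variant1", "aam", base),
    ProteinRecord("variant2", "aam", mutate_to_identity(base, 98.0, 1)),
    ProteinRecord("variant3", "aam", mutate_to_identity(base, 97.0, 2)),
    ProteinRecord("fragment", "aam", base[:70]),
    ProteinRecord("unrelated", "aam", "".join(rng.choice(list(CANONICAL_AA), 150))),
]

for cluster in dedup(records, "I2"):
    idents = ", ".join(
        f"{m}={cluster.member_identities[m]:.1f}%" for m in cluster.member_ids
    )
    print(f"representative {cluster.representative_id}: {idents}")
# The non-redundant count for this family is the number of clusters (2);
# each member's identity to its representative is >= 95%.
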