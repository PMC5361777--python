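"""Cross-species conservation screening at the 50% identity threshold.

Homologs are planted at controlled identities in two other species; the
screen retains best hits at >= 50% column identity and bands the rest.
"""

import numpy as np

from tickpi import ProteinRecord, conservation_summary, mutate_to_identity, screen_conservation
from tickpi.records import CANONICAL_AA

rng = np.random.default_rng(9)
query_seq = "".join(rng.choice(list(CANONICAL_AA), 150))
query = ProteinRecord("aam_kunitz_1", "aam", query_seq)

subjects = [
    ProteinRecord("isca_hom", "isca", mutate_to_identity(query_seq, 85.0, 1)),
    ProteinRecord("iric_hom", "iric", mutate_to_identity(query_seq, 60.0, 2)),
    ProteinRecord("rmic_far", "rmic", mutate_to_identity(query_seq, 40.0, 3)),
]

hits = screen_conservation([query], subjects, "I2")
for h in hits:
    print(
        f"{h.query_id} ~ {h.subject_id} ({h.subject_species}): "
        f"{h.identity_percent}% over {h.aligned_columns} columns"
    )
print("\nper-query summary:")
print(conservation_summary(hits, [query]))
# The 85% and 60% homologs are retained; the 40% relative falls below the
# screen threshold and is absent from the hit list.
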