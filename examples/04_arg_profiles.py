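"""Antibiotic-resistance-gene filtering and drug-class aggregation.

Filters CARD-style alignment hits at 90% identity / 80% mutual coverage,
keeps ARGs present in at least three samples of one host, and sums the
survivors into drug-class abundance profiles.
"""

import pandas as pd

import strainniche as sn
from strainniche.argprofile import ArgHit

hits = [
    ArgHit("CARD_tetW", "UniRef90_tetW", 95.0, 90.0, 92.0),
    ArgHit("CARD_ermB", "UniRef90_ermB", 91.0, 85.0, 81.0),
    ArgHit("CARD_weak", "UniRef90_weak", 88.0, 95.0, 95.0),   # identity fails
    ArgHit("CARD_part", "UniRef90_part", 96.0, 85.0, 60.0),   # coverage fails
]
retained = sn.filter_hits(hits)
print("retained gene families:", retained)

ids = [f"dog{i}" for i in range(4)] + [f"cat{i}" for i in range(3)]
host_of = {s: s[:3] for s in ids}
abund = pd.DataFrame(
    {
        "UniRef90_tetW": [0.2, 0.1, 0.3, 0.0, 0.0, 0.0, 0.0],
        "UniRef90_ermB": [0.1, 0.0, 0.0, 0.0, 0.1, 0.0, 0.0],
    },
    index=ids,
)
present = sn.arg_presence_filter(abund, host_of)
print("ARGs present in >= 3 samples of one host:", present)

profile = sn.class_abundance(
    abund[present], {"UniRef90_tetW": "tetracycline"}
)
print("\nper-sample drug-class abundances:")
print(profile.to_string())
print()
print("tetW clears both filters and its abundance lands in the")
print("tetracycline class; ermB is seen in too few samples per host.")
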