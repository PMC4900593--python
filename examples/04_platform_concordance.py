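"""Phantom-nucleotide accounting across platform reconstructions.

Takes four reconstructions of the same specimen (three clean, one with
homopolymer-style single-base insertions), aligns them rotation-aware, and
calls phantoms in the focal platform.  Also reproduces the published
phantom rates from the study's printed counts.
"""

import numpy as np

from mitopool.concordance import (
    align_reconstructions,
    call_phantoms,
    gc_percent,
    phantom_rate,
)
from mitopool.published import load_phantom_counts

rng = np.random.default_rng(55)
specimen = "".join(rng.choice(list("ACGT"), 5406))

# inject 6 phantom single-base insertions into the focal reconstruction
focal = specimen
for p in sorted(rng.choice(np.arange(100, 5300, 7), size=6, replace=False),
                reverse=True):
    p = int(p)
    base = next(b for b in "ACGT" if b != focal[p - 1] and b != focal[p])
    focal = focal[:p] + base + focal[p:]

platforms = ["miseq", "hiseq", "iontorrent", "r454"]
rows = align_reconstructions(
    [specimen, specimen[1000:] + specimen[:1000], focal, specimen])
report = call_phantoms(rows, platforms, "iontorrent", specimen="synthetic")
print(f"focal iontorrent phantoms: {report.counts} "
      f"over {report.total_bp} bp -> rate {report.rate_percent}%")
print(f"GC% of the specimen: {gc_percent(specimen)}")

print("\npublished counts reproduce the printed rates:")
df = load_phantom_counts()
for row in df.itertuples():
    rate = phantom_rate({b: getattr(row, b) for b in "ACGTN"}, row.total_bp)
    print(f"  {row.specimen} {row.platform}: {rate}%")
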