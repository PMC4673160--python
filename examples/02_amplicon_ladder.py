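"""Predict the isoform band ladder of a single-tube RT-PCR.

With primers flanking the alternatively spliced exons 5 and 6, each isoform
yields a product whose length drops by exactly the length of every exon it
skips -- the band ladder that separates OPNa, OPNb and OPNc on a gel.
"""

from opnsplice import predict_amplicons
from opnsplice.spp1 import SPP1_EXONS, SPP1_PRIMERS, spp1_incidence

M = spp1_incidence()
products = predict_amplicons(M, SPP1_EXONS, SPP1_PRIMERS)
for isoform, length in products.items():
    print(f"{isoform}: {length if isinstance(length, str) else f'{length} bp'}")
# OPNa 253 bp (retains exons 5 and 6), OPNb 211 bp (-42 bp, skips exon 6),
# OPNc 172 bp (-81 bp, skips exon 5); OPN4 skips both, OPN5 adds exon 4.
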