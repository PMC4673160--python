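"""Which isoform combinations can an exon array see?

Builds the packaged SPP1 incidence matrix and asks what is estimable when
exon 6 has no probe set (the situation on the ST 2.1 exon array) versus when
every exon is observed.
"""

from opnsplice import identifiable_groups
from opnsplice.spp1 import ST21_OBSERVED_EXONS, spp1_incidence

M = spp1_incidence()
print("incidence matrix (isoforms x exons) with per-exon frequency:")
print(M.to_frame(), "\n")

rep = identifiable_groups(M, ST21_OBSERVED_EXONS)
print(f"observed exons {rep.observed_exons} (no exon-6 probe set)")
print(f"design rank {rep.design_rank}, fully identifiable: {rep.fully_identifiable}")
print("estimable isoform groups:", ", ".join(rep.group_labels()))
# Individual isoforms are not resolvable, but three summed groups are:
# OPNa+OPNb, OPNc+OPN4 and OPN5 -- exactly what the subtraction scheme targets.

full = identifiable_groups(M, M.exon_ids)
print(f"\nall 8 exons observed: rank {full.design_rank} of {M.n_isoforms} isoforms")
print("null space:", full.null_space_basis)
# Even the complete exon set cannot separate all five isoforms: the mixture
# OPNa - OPNb - OPNc + OPN4 is invisible to exon-level signals.
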