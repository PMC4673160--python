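"""Packaged OPN/*SPP1* gene model: the five splice isoforms over eight exons.

Exon membership follows the annotated isoform structures: OPNa carries every
exon except exon 4, OPNb additionally lacks exon 6, OPNc lacks exon 5, OPN4
lacks exons 4-6, and OPN5 is the only isoform containing exon 4.  Exons 1-3
and 7-8 are common to all five isoforms.

Exon 5 (81 bp) and exon 6 (42 bp) lengths are fixed by the observed isoform
amplicon ladder (OPNa 253 bp, OPNb 211 bp, OPNc 172 bp: skipping exon 6 or
exon 5 shortens the product by exactly that length).  The remaining lengths
and the primer anchor placement (forward in exon 3, reverse in exon 7,
flanking exons 5 and 6) are a plausible reconstruction chosen so that the
OPNa/b/c ladder is reproduced; they are illustrative, not measured values.
"""

from __future__ import annotations

from .transcript_model import (
    ExonDef,
    IncidenceMatrix,
    IsoformDef,
    PrimerPair,
    build_incidence,
)

__all__ = [
    "SPP1_EXONS",
    "SPP1_ISOFORMS",
    "SPP1_PRIMERS",
    "spp1_incidence",
    "ST21_OBSERVED_EXONS",
]

SPP1_EXONS: tuple[ExonDef, ...] = (
    ExonDef(1, 105),
    ExonDef(2, 54),
    ExonDef(3, 120),
    ExonDef(4, 84),
    ExonDef(5, 81),
    ExonDef(6, 42),
    ExonDef(7, 93),
    ExonDef(8, 1364),
)

SPP1_ISOFORMS: tuple[IsoformDef, ...] = (
    IsoformDef("OPNa", (1, 2, 3, 5, 6, 7, 8)),
    IsoformDef("OPNb", (1, 2, 3, 5, 7, 8)),
    IsoformDef("OPNc", (1, 2, 3, 6, 7, 8)),
    IsoformDef("OPN4", (1, 2, 3, 7, 8)),
    IsoformDef("OPN5", (1, 2, 3, 4, 5, 6, 7, 8)),
)

#: Reconstructed anchors flanking exons 5 and 6: product spans the last 70 bp
#: of exon 3, any retained exons 4-6, and the first 60 bp of exon 7.
SPP1_PRIMERS = PrimerPair(forward_exon=3, forward_offset=50, reverse_exon=7, reverse_offset=60)

#: Exons observed on the ST 2.1 exon array: no probe set targets exon 6.
ST21_OBSERVED_EXONS: tuple[int, ...] = (1, 2, 3, 4, 5, 7, 8)


def spp1_incidence() -> IncidenceMatrix:
    """The 5x8 SPP1 exon-isoform incidence matrix."""
    return build_incidence(SPP1_EXONS, SPP1_ISOFORMS)
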