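"""Gene/isoform/exon structure and what exon-level signals can identify.

A gene is an ordered list of exons; each splice isoform is a strictly
increasing subset of those exons.  The binary exon-isoform incidence matrix
``M`` (isoforms x exons) determines, for any set of *observed* exons, which
linear combinations of isoform abundances are estimable from exon-level
expression signals: the signal on exon ``e`` is the sum of abundances of the
isoforms containing ``e``, so the estimable functionals are exactly the row
space of the observed design and the ambiguity is its null space.

The module also predicts RT-PCR amplicon lengths for a primer pair anchored
in two exons, which gives the isoform band ladder seen on a gel: skipping an
intervening exon shortens the product by exactly that exon's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy

__all__ = [
    "ExonDef",
    "IsoformDef",
    "IncidenceMatrix",
    "IdentifiabilityReport",
    "PrimerPair",
    "NO_PRODUCT",
    "build_incidence",
    "identifiable_groups",
    "predict_amplicons",
]


class StructuralError(ValueError):
    """Raised when gene/isoform/primer definitions are inconsistent."""


@dataclass(frozen=True)
class ExonDef:
    """One exon of a gene, identified by its ordinal number within the gene.

    Coordinates are optional metadata; identity is the ordinal ``exon_id``
    (1-based).  When both coordinates are present they must agree with
    ``length`` (1-based inclusive convention).
    """

    exon_id: int
    length: int
    genomic_start: int | None = None
    genomic_end: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise StructuralError(f"exon {self.exon_id}: length must be >= 1, got {self.length}")
        if (self.genomic_start is None) != (self.genomic_end is None):
            raise StructuralError(f"exon {self.exon_id}: give both coordinates or neither")
        if self.genomic_start is not None:
            span = self.genomic_end - self.genomic_start + 1
            if span != self.length:
                raise StructuralError(
                    f"exon {self.exon_id}: coordinate span {span} != length {self.length}"
                )


@dataclass(frozen=True)
class IsoformDef:
    """A splice isoform: a named, strictly increasing subset of gene exons."""

    isoform_id: str
    exons: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise StructuralError(f"isoform {self.isoform_id}: exon list is empty")
        if any(b <= a for a, b in zip(self.exons, self.exons[1:])):
            raise StructuralError(
                f"isoform {self.isoform_id}: exon ids must be strictly increasing, got {self.exons}"
            )


@dataclass
class IncidenceMatrix:
    """Binary isoform x exon membership with per-exon inclusion frequency.

    ``matrix`` is a pandas DataFrame indexed by isoform id with exon-id
    columns and 0/1 integer entries, in input order.  ``frequency[e]`` is the
    number of isoforms containing exon ``e``; exons present in every isoform
    (``frequency == n_isoforms``) are the *common* exons whose signals proxy
    total expression.
    """

    matrix: pd.DataFrame

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def exon_ids(self) -> list[int]:
        return list(self.matrix.columns)

    @property
    def frequency(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def n_isoforms(self) -> int:
        return self.matrix.shape[0]

    def common_exons(self) -> list[int]:
        """Exons contained in every isoform."""
        freq = self.frequency
        return [e for e in self.exon_ids if freq[e] == self.n_isoforms]

    def carriers(self, exon_id: int) -> tuple[str, ...]:
        """Isoforms containing the given exon."""
        col = self.matrix[exon_id]
        return tuple(i for i in self.isoform_ids if col[i] == 1)

    def to_frame(self) -> pd.DataFrame:
        """Matrix with a trailing ``frequency`` row (the table layout used on disk)."""
        out = self.matrix.copy()
        out.loc["frequency"] = self.frequency
        return out


@dataclass(frozen=True)
class PrimerPair:
    """Primer anchors given as (exon_id, offset-in-bp within that exon).

    The forward offset counts bases consumed before the product starts; the
    reverse offset counts bases of the reverse-anchor exon included in the
    product.  Anchor exons must be in gene order.
    """

    forward_exon: int
    forward_offset: int
    reverse_exon: int
    reverse_offset: int

    def __post_init__(self) -> None:
        if self.forward_exon > self.reverse_exon:
            raise StructuralError(
                f"primer anchors reversed: forward exon {self.forward_exon} "
                f"after reverse exon {self.reverse_exon}"
            )
        if self.forward_offset < 0 or self.reverse_offset < 0:
            raise StructuralError("primer offsets must be non-negative")


#: Sentinel returned by :func:`predict_amplicons` for isoforms missing an anchor exon.
NO_PRODUCT = "no product"


@dataclass
class IdentifiabilityReport:
    """What the observed exon set can and cannot resolve.

    ``estimable_functionals`` is a canonical basis (reduced row echelon,
    smallest-integer coefficients, ordered by first nonzero isoform) of the
    estimable space; functionals whose coefficients are all 0/1 are labelled
    as '+'-joined isoform groups.  ``null_space_basis`` spans the directions
    in isoform-abundance space invisible to the observed exons; it is empty
    iff every isoform is individually resolvable.
    """

    observed_exons: tuple[int, ...]
    design_rank: int
    estimable_functionals: list[tuple[str, dict[str, Fraction]]]
    null_space_basis: list[dict[str, Fraction]]
    fully_identifiable: bool
    #: distinct observed membership patterns -> exon ids carrying that pattern
    pattern_exons: dict[tuple[int, ...], tuple[int, ...]]
    isoform_ids: tuple[str, ...] = field(default_factory=tuple)

    def group_labels(self) -> list[str]:
        return [label for label, _ in self.estimable_functionals]

    def groups(self) -> dict[str, tuple[str, ...]]:
        """0/1 estimable functionals as label -> member isoforms."""
        out: dict[str, tuple[str, ...]] = {}
        for label, coeffs in self.estimable_functionals:
            if all(c in (0, 1) for c in coeffs.values()):
                out[label] = tuple(i for i in self.isoform_ids if coeffs[i] == 1)
        return out


def build_incidence(
    gene_exons: Sequence[ExonDef], isoforms: Sequence[IsoformDef]
) -> IncidenceMatrix:
    """Build the binary exon-isoform incidence matrix in input order."""
    if not isoforms:
        raise StructuralError("at least one isoform is required")
    if not gene_exons:
        raise StructuralError("at least one exon is required")
    exon_ids = [e.exon_id for e in gene_exons]
    if len(set(exon_ids)) != len(exon_ids):
        raise StructuralError(f"duplicate exon ids in gene definition: {exon_ids}")
    known = set(exon_ids)
    rows = {}
    for iso in isoforms:
        unknown = [e for e in iso.exons if e not in known]
        if unknown:
            raise StructuralError(
                f"isoform {iso.isoform_id} references undefined exon(s) {unknown}"
            )
        rows[iso.isoform_id] = [1 if e in iso.exons else 0 for e in exon_ids]
    if len(rows) != len(isoforms):
        raise StructuralError("duplicate isoform ids")
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=exon_ids, dtype=int)
    return IncidenceMatrix(matrix=matrix)


def _canonical_int_vector(vec: Iterable[Fraction]) -> list[Fraction]:
    """Scale a rational vector to coprime integers with positive leading entry."""
    fracs = [Fraction(v) for v in vec]
    denoms = [f.denominator for f in fracs if f != 0]
    if not denoms:
        return fracs
    lcm = np.lcm.reduce(denoms)
    ints = [int(f * lcm) for f in fracs]
    g = np.gcd.reduce([abs(i) for i in ints if i != 0])
    ints = [i // int(g) for i in ints]
    lead = next(i for i in ints if i != 0)
    if lead < 0:
        ints = [-i for i in ints]
    return [Fraction(i) for i in ints]


def _label_functional(coeffs: Mapping[str, Fraction], isoform_ids: Sequence[str]) -> str:
    values = [coeffs[i] for i in isoform_ids]
    if all(v in (0, 1) for v in values):
        return "+".join(i for i in isoform_ids if coeffs[i] == 1)
    parts = []
    for iso in isoform_ids:
        c = coeffs[iso]
        if c == 0:
            continue
        sign = "-" if c < 0 else ("+" if parts else "")
        mag = abs(c)
        term = iso if mag == 1 else f"{mag}*{iso}"
        parts.append(f"{sign}{term}")
    return "".join(parts)


def observed_patterns(
    M: IncidenceMatrix, observed_exons: Iterable[int]
) -> dict[tuple[int, ...], tuple[int, ...]]:
    """Map each distinct membership column over observed exons to its exons.

    Exons with identical membership carry identical information and collapse
    into one design equation (their signals are averaged downstream).
    Patterns are ordered by first occurrence in gene exon order.
    """
    observed = list(dict.fromkeys(observed_exons))
    if not observed:
        raise StructuralError("observed exon set is empty")
    missing = [e for e in observed if e not in M.exon_ids]
    if missing:
        raise StructuralError(f"observed exon(s) {missing} absent from incidence matrix")
    patterns: dict[tuple[int, ...], list[int]] = {}
    for e in M.exon_ids:
        if e not in observed:
            continue
        pat = tuple(int(v) for v in M.matrix[e])
        patterns.setdefault(pat, []).append(e)
    return {p: tuple(es) for p, es in patterns.items()}


def identifiable_groups(
    M: IncidenceMatrix, observed_exons: Iterable[int]
) -> IdentifiabilityReport:
    """Determine which isoform combinations the observed exons can estimate.

    Builds one linear equation per distinct observed membership pattern
    (signal = sum of abundances of carrier isoforms) and reports the rank,
    a canonical integer basis of estimable functionals, and a basis of the
    null space.  Exact rational arithmetic throughout.
    """
    patterns = observed_patterns(M, observed_exons)
    isoform_ids = tuple(M.isoform_ids)
    A = sympy.Matrix([list(p) for p in patterns])
    rref, pivots = A.rref()
    functionals: list[tuple[str, dict[str, Fraction]]] = []
    for r in range(len(pivots)):
        row = [Fraction(sympy.Rational(x).p, sympy.Rational(x).q) for x in rref.row(r)]
        row = _canonical_int_vector(row)
        coeffs = dict(zip(isoform_ids, row))
        functionals.append((_label_functional(coeffs, isoform_ids), coeffs))
    functionals.sort(key=lambda lc: next(i for i, iso in enumerate(isoform_ids) if lc[1][iso] != 0))
    null_basis: list[dict[str, Fraction]] = []
    for v in A.nullspace():
        row = [Fraction(sympy.Rational(x).p, sympy.Rational(x).q) for x in v]
        row = _canonical_int_vector(row)
        null_basis.append(dict(zip(isoform_ids, row)))
    null_basis.sort(key=lambda c: next(i for i, iso in enumerate(isoform_ids) if c[iso] != 0))
    rank = len(pivots)
    return IdentifiabilityReport(
        observed_exons=tuple(dict.fromkeys(observed_exons)),
        design_rank=rank,
        estimable_functionals=functionals,
        null_space_basis=null_basis,
        fully_identifiable=not null_basis,
        pattern_exons=patterns,
        isoform_ids=isoform_ids,
    )


def predict_amplicons(
    M: IncidenceMatrix, exons: Sequence[ExonDef], primers: PrimerPair
) -> dict[str, int | str]:
    """Predict the RT-PCR product length per isoform for one primer pair.

    Product length = (forward-anchor exon length - forward offset)
    + lengths of intervening exons the isoform retains + reverse offset.
    Isoforms lacking either anchor exon yield :data:`NO_PRODUCT`.
    """
    by_id = {e.exon_id: e for e in exons}
    for anchor in (primers.forward_exon, primers.reverse_exon):
        if anchor not in by_id:
            raise StructuralError(f"primer anchor exon {anchor} is not defined")
    fwd = by_id[primers.forward_exon]
    if primers.forward_offset >= fwd.length:
        raise StructuralError("forward offset exceeds anchor exon length")
    if primers.reverse_offset > by_id[primers.reverse_exon].length:
        raise StructuralError("reverse offset exceeds anchor exon length")
    out: dict[str, int | str] = {}
    for iso in M.isoform_ids:
        row = M.matrix.loc[iso]
        if row.get(primers.forward_exon, 0) != 1 or row.get(primers.reverse_exon, 0) != 1:
            out[iso] = NO_PRODUCT
            continue
        intervening = sum(
            by_id[e].length
            for e in M.exon_ids
            if primers.forward_exon < e < primers.reverse_exon and row[e] == 1
        )
        out[iso] = (fwd.length - primers.forward_offset) + intervening + primers.reverse_offset
    return out
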