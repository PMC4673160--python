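"""Cohort-level isoform-group quantification from exon-level signals.

The workflow mirrors how combined isoform abundances are read off an exon
array when not every exon has a probe set:

1. pick a *total-expression proxy*: the ``k`` common-exon probe sets with the
   least cross-sample deviation, averaged on the linear scale;
2. estimate identifiable isoform *groups* either by successive subtraction
   of nested exon signals (the triangular chain: exon-4 signal gives OPN5,
   exon-5 minus exon-4 gives OPNa+OPNb, total minus exon-5 gives OPNc+OPN4)
   or by non-negative least squares on the full observed design;
3. correlate each group with the total to demonstrate co-overexpression.

All arithmetic on abundances is on the linear scale (2**log2 signal), since
isoform abundances add linearly; correlations default to the log2 scale, the
scale on which array expression is conventionally compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .transcript_model import (
    IdentifiabilityReport,
    IncidenceMatrix,
    identifiable_groups,
)

__all__ = [
    "ExpressionMatrix",
    "TotalProxy",
    "GroupEstimate",
    "GroupCorrelation",
    "DeconvolutionError",
    "select_total_proxy",
    "subtraction_estimates",
    "lsq_estimates",
    "correlate_groups",
    "exon_signals",
]


class DeconvolutionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Samples x probe-set log2 signals with a probe-set -> exon map."""

    values: pd.DataFrame  # samples x probesets, log2 units
    probe_to_exon: dict[str, int]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise DeconvolutionError(f"missing values in probe set(s) {bad}")
        unmapped = [p for p in self.values.columns if p not in self.probe_to_exon]
        if unmapped:
            raise DeconvolutionError(f"probe set(s) without exon mapping: {unmapped}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def probesets(self) -> list[str]:
        return list(self.values.columns)

    def probesets_for_exon(self, exon_id: int) -> list[str]:
        return [p for p in self.probesets if self.probe_to_exon[p] == exon_id]

    @property
    def exons(self) -> list[int]:
        return sorted({self.probe_to_exon[p] for p in self.probesets})


@dataclass
class TotalProxy:
    """Total gene expression proxied by the least-deviant common-exon probe sets."""

    selected_probesets: list[str]
    total: pd.Series  # per sample, linear scale
    deviation_scores: pd.Series  # per candidate probe set


@dataclass
class GroupEstimate:
    """Per-sample abundance of one identifiable isoform group (linear scale)."""

    group_label: str
    coefficients: dict[str, float]
    abundances: pd.Series  # >= 0
    clipped: pd.Series  # True where the raw estimate was negative


@dataclass
class GroupCorrelation:
    group_label: str
    pearson_r: float  # NaN when not computable
    p_value: float
    n: int
    computable: bool = True


def exon_signals(X: ExpressionMatrix, exon_ids: Iterable[int] | None = None) -> pd.DataFrame:
    """Per-exon linear-scale signal: probe sets mapping to the same exon are
    averaged on the linear scale."""
    exon_ids = list(exon_ids) if exon_ids is not None else X.exons
    linear = np.power(2.0, X.values)
    cols = {}
    for e in exon_ids:
        probes = X.probesets_for_exon(e)
        if not probes:
            raise DeconvolutionError(f"no probe set maps to exon {e}")
        cols[e] = linear[probes].mean(axis=1)
    return pd.DataFrame(cols, index=X.values.index)


def select_total_proxy(X: ExpressionMatrix, M: IncidenceMatrix, k: int = 3) -> TotalProxy:
    """Select the ``k`` common-exon probe sets with the smallest deviation.

    The deviation score of a candidate is the cross-sample standard deviation
    of its log2 signal after centering each sample at the median of all
    common-exon candidates (robust to genuine per-sample expression
    differences, leaving probe-level inconsistency).  Ties break by probe-set
    id order.  The total is the linear-scale mean of the selected candidates.
    """
    common = set(M.common_exons())
    candidates = [p for p in X.probesets if X.probe_to_exon[p] in common]
    if not candidates:
        raise DeconvolutionError("no probe set maps to a common exon")
    if k < 1:
        raise DeconvolutionError("k must be >= 1")
    if k > len(candidates):
        warnings.warn(
            f"requested k={k} proxy probe sets but only {len(candidates)} common-exon "
            "candidates are available; selecting all",
            stacklevel=2,
        )
        k = len(candidates)
    sub = X.values[candidates]
    centered = sub.sub(sub.median(axis=1), axis=0)
    scores = centered.std(axis=0, ddof=1) if len(sub) > 1 else centered.abs().iloc[0] * 0.0
    order = sorted(candidates, key=lambda p: (scores[p], p))
    selected = order[:k]
    total = np.power(2.0, X.values[selected]).mean(axis=1)
    return TotalProxy(selected_probesets=selected, total=total, deviation_scores=scores)


def _nested_chain(
    report: IdentifiabilityReport, M: IncidenceMatrix
) -> list[tuple[tuple[str, ...], tuple[int, ...]]]:
    """Non-common observed patterns as a nested carrier chain, smallest first.

    Returns (carrier isoforms, exon ids) per pattern; raises if the carrier
    sets do not nest (the design is not triangular).
    """
    isoforms = report.isoform_ids
    chain = []
    for pattern, exons in report.pattern_exons.items():
        carriers = tuple(i for i, bit in zip(isoforms, pattern) if bit)
        if len(carriers) == len(isoforms):
            continue  # common pattern: covered by the total
        chain.append((carriers, exons))
    chain.sort(key=lambda ce: len(ce[0]))
    for (small, _), (big, _) in zip(chain, chain[1:]):
        if not set(small) < set(big):
            raise DeconvolutionError(
                "observed exon patterns do not form a nested subtraction chain; "
                "use lsq_estimates for this design"
            )
    return chain


def subtraction_estimates(
    proxy: TotalProxy,
    X: ExpressionMatrix,
    M: IncidenceMatrix,
    observed_exons: Iterable[int],
) -> list[GroupEstimate]:
    """Estimate isoform groups by successive subtraction from the total.

    Requires a triangular design: the non-common observed exon patterns must
    have nested carrier sets.  Signals are linearized before subtraction;
    negative estimates are clipped to 0 and flagged.
    """
    report = identifiable_groups(M, observed_exons)
    chain = _nested_chain(report, M)
    if not chain:
        raise DeconvolutionError("no isoform-discriminating exon observed")
    signals = exon_signals(X, [e for _, exons in chain for e in exons])
    isoforms = list(report.isoform_ids)

    estimates: list[GroupEstimate] = []
    prev_signal = pd.Series(0.0, index=proxy.total.index)
    prev_carriers: tuple[str, ...] = ()
    for carriers, exons in chain:
        sig = signals[list(exons)].mean(axis=1)
        members = tuple(i for i in carriers if i not in prev_carriers)
        estimates.append(_make_estimate(members, sig - prev_signal, isoforms))
        prev_signal, prev_carriers = sig, carriers
    remainder = tuple(i for i in isoforms if i not in prev_carriers)
    if remainder:
        estimates.append(_make_estimate(remainder, proxy.total - prev_signal, isoforms))
    estimates.sort(key=lambda g: isoforms.index(next(i for i in isoforms if g.coefficients[i])))
    return estimates


def _make_estimate(
    members: tuple[str, ...], raw: pd.Series, isoforms: Sequence[str]
) -> GroupEstimate:
    clipped = raw < 0
    return GroupEstimate(
        group_label="+".join(i for i in isoforms if i in members),
        coefficients={i: float(i in members) for i in isoforms},
        abundances=raw.clip(lower=0.0),
        clipped=clipped,
    )


def lsq_estimates(
    X: ExpressionMatrix,
    M: IncidenceMatrix,
    observed_exons: Iterable[int],
) -> list[GroupEstimate]:
    """Estimate isoform groups by per-sample non-negative least squares.

    One design equation per distinct observed membership pattern (signals of
    same-pattern exons averaged on the linear scale); the reported groups are
    the 0/1 estimable functionals of the design applied to the NNLS solution.
    Estimable functionals are invariant over the solution set of a consistent
    system, so on noise-free data this equals the subtraction estimator.
    """
    report = identifiable_groups(M, observed_exons)
    if report.design_rank == 0:
        raise DeconvolutionError("design has rank 0; nothing is estimable")
    patterns = list(report.pattern_exons.items())
    signals = exon_signals(X, [e for _, exons in patterns for e in exons])
    A = np.array([list(p) for p, _ in patterns], dtype=float)
    B = np.column_stack([signals[list(exons)].mean(axis=1).to_numpy() for _, exons in patterns])

    groups = [
        (label, coeffs)
        for label, coeffs in report.estimable_functionals
        if all(c in (0, 1) for c in coeffs.values())
    ]
    isoforms = list(report.isoform_ids)
    coefs = np.array([[float(coeffs[i]) for i in isoforms] for _, coeffs in groups])
    values = np.empty((len(B), len(groups)))
    for s in range(len(B)):
        x, _ = optimize.nnls(A, B[s])
        values[s] = coefs @ x
    out = []
    for j, (label, coeffs) in enumerate(groups):
        raw = pd.Series(values[:, j], index=X.values.index)
        out.append(
            GroupEstimate(
                group_label=label,
                coefficients={i: float(coeffs[i]) for i in isoforms},
                abundances=raw.clip(lower=0.0),
                clipped=raw < 0,
            )
        )
    return out


def _log2_floor(x: np.ndarray) -> np.ndarray:
    pos = x[x > 0]
    if pos.size == 0:
        return np.full_like(x, np.nan)
    return np.log2(np.where(x > 0, x, pos.min() / 2.0))


def correlate_groups(
    estimates: Sequence[GroupEstimate],
    proxy: TotalProxy,
    scale: str = "log2",
) -> list[GroupCorrelation]:
    """Pearson correlation of each group abundance against the total.

    On the default ``log2`` scale both series are log-transformed and samples
    whose group estimate was clipped at zero are excluded (left-censored by
    the clipping rule).  ``scale="linear"`` correlates the values as given,
    over all samples.  Zero-variance groups are flagged not-computable.
    """
    if scale not in ("log2", "linear"):
        raise DeconvolutionError(f"unknown correlation scale {scale!r}")
    out = []
    for g in estimates:
        keep = ~g.clipped if scale == "log2" else pd.Series(True, index=g.abundances.index)
        x = g.abundances[keep].to_numpy(dtype=float)
        y = proxy.total[keep].to_numpy(dtype=float)
        n = len(x)
        if n < 3 or np.allclose(x, x[0] if n else 0.0) or np.allclose(y, y[0] if n else 0.0):
            out.append(GroupCorrelation(g.group_label, float("nan"), float("nan"), n, False))
            continue
        if scale == "log2":
            x, y = _log2_floor(x), _log2_floor(y)
        r, p = stats.pearsonr(x, y)
        out.append(GroupCorrelation(g.group_label, float(r), float(p), n, True))
    return out
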