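"""Relative quantification from qRT-PCR threshold cycles (Ct).

Implements the 2^-ddCt workflow with a multi-gene reference index:
per sample, replicate Ct values are averaged, the reference index is the
arithmetic mean of the reference-gene Ct values (equivalently the geometric
mean of their linear quantities), dCt = Ct_target - index, ddCt subtracts
the mean dCt of the calibrator samples, and fold = 2^-ddCt.  Amplification
efficiency is assumed to be 2 per cycle.

On top of the fold changes the module provides the tumor-cohort
overexpression caller (threshold = 2 x mean + 1 SD of the Normal/Barrett's
reference group), per-class summaries with Welch t-tests, and the
single-tube copy-number ratio against an internal control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "FoldChangeTable",
    "OverexpressionCall",
    "CopyNumberRatio",
    "ClassComparison",
    "QpcrError",
    "ddct_fold_change",
    "call_overexpression",
    "copy_number_ratio",
    "compare_classes",
]

ASSAY_ROLES = ("target", "reference", "internal_control")


class QpcrError(ValueError):
    pass


@dataclass
class CtTable:
    """Long-format replicate Ct measurements: sample, assay, role, replicate, ct.

    Replicates of one (sample, assay) pair farther apart than
    ``concordance_window`` cycles are flagged in ``discordant`` (kept, not
    dropped; promote to an error with ``strict=True`` downstream).
    """

    records: pd.DataFrame
    concordance_window: float = 1.0

    def __post_init__(self) -> None:
        required = {"sample", "assay", "role", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise QpcrError(f"Ct table missing column(s) {sorted(missing)}")
        bad_roles = set(self.records["role"]) - set(ASSAY_ROLES)
        if bad_roles:
            raise QpcrError(f"unknown assay role(s) {sorted(bad_roles)}; allowed: {ASSAY_ROLES}")
        if (self.records["ct"] <= 0).any():
            bad = self.records.loc[self.records["ct"] <= 0]
            raise QpcrError(f"non-positive Ct value(s): {bad[['sample', 'assay', 'ct']].to_dict('records')}")
        roles = self.records.groupby("assay")["role"].nunique()
        if (roles > 1).any():
            raise QpcrError(f"assay(s) with conflicting roles: {roles[roles > 1].index.tolist()}")

    @property
    def discordant(self) -> pd.DataFrame:
        """(sample, assay) pairs whose replicate spread exceeds the window."""
        spread = self.records.groupby(["sample", "assay"])["ct"].agg(lambda s: s.max() - s.min())
        return spread[spread > self.concordance_window].reset_index(name="ct_spread")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct, one row per (sample, assay)."""
        return self.records.groupby(["sample", "assay"], sort=False)["ct"].mean().reset_index()

    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample"]))

    def assays(self, role: str | None = None) -> list[str]:
        df = self.records if role is None else self.records[self.records["role"] == role]
        return list(dict.fromkeys(df["assay"]))


@dataclass
class FoldChangeTable:
    """Per-sample 2^-ddCt fold change relative to the calibrator set."""

    folds: pd.Series  # > 0, indexed by sample
    reference_index_ct: pd.Series  # mean reference Ct per sample
    target: str
    references: tuple[str, ...]
    calibrator: tuple[str, ...]


@dataclass
class OverexpressionCall:
    sample_id: str
    fold: float
    threshold: float
    called: bool
    reference_group_mean: float
    reference_group_sd: float


@dataclass
class CopyNumberRatio:
    pair_id: tuple[str, str]  # (tumor, matched normal)
    ratio: float
    status: str  # gain | loss | unchanged


@dataclass
class ClassComparison:
    summary: pd.DataFrame  # per class: n, mean, sd (log2 fold by default)
    pairwise_p: pd.DataFrame  # class x reference-class Welch t-test p-values
    skipped: list[str]  # degenerate classes


def _pivot_mean_ct(ct: CtTable, assays: Sequence[str]) -> pd.DataFrame:
    mean = ct.mean_ct().pivot(index="sample", columns="assay", values="ct")
    for a in assays:
        if a not in mean.columns:
            raise QpcrError(f"assay {a!r} not measured in any sample")
        missing = mean.index[mean[a].isna()].tolist()
        if missing:
            raise QpcrError(f"assay {a!r} missing in sample(s) {missing}")
    return mean


def ddct_fold_change(
    ct: CtTable,
    target: str,
    references: Sequence[str],
    calibrator: Iterable[str],
) -> FoldChangeTable:
    """Fold change per sample by 2^-ddCt against a reference-gene index."""
    calibrator = tuple(dict.fromkeys(calibrator))
    if not calibrator:
        raise QpcrError("calibrator sample set is empty")
    if not references:
        raise QpcrError("at least one reference assay is required")
    mean = _pivot_mean_ct(ct, [target, *references])
    unknown = [s for s in calibrator if s not in mean.index]
    if unknown:
        raise QpcrError(f"calibrator sample(s) {unknown} not in Ct table")
    ref_index = mean[list(references)].mean(axis=1)
    dct = mean[target] - ref_index
    ddct = dct - dct.loc[list(calibrator)].mean()
    folds = np.power(2.0, -ddct)
    return FoldChangeTable(
        folds=folds,
        reference_index_ct=ref_index,
        target=target,
        references=tuple(references),
        calibrator=calibrator,
    )


def call_overexpression(
    folds: FoldChangeTable,
    labels: Mapping[str, str],
    reference_classes: Iterable[str] = ("Normal", "BE"),
    rule: str = "2m_plus_s",
) -> list[OverexpressionCall]:
    """Call overexpressed samples against the premalignant reference group.

    Default rule: threshold T = 2*m + s where m, s are the mean and sample SD
    (n-1) of fold changes in the reference classes; a sample is called iff
    fold > T (strict).  The alternative reading ``"2fold_and_m_plus_s"``
    requires fold > 2 and fold > m + s.
    """
    reference_classes = set(reference_classes)
    ref_samples = [s for s in folds.folds.index if labels.get(s) in reference_classes]
    if len(ref_samples) < 2:
        raise QpcrError(
            f"need >= 2 reference samples in classes {sorted(reference_classes)}, "
            f"found {len(ref_samples)}"
        )
    ref = folds.folds.loc[ref_samples]
    m, s = float(ref.mean()), float(ref.std(ddof=1))
    if rule == "2m_plus_s":
        threshold = 2.0 * m + s
        def called(f: float) -> bool:
            return f > threshold
    elif rule == "2fold_and_m_plus_s":
        threshold = max(2.0, m + s)
        def called(f: float) -> bool:
            return f > 2.0 and f > m + s
    else:
        raise QpcrError(f"unknown overexpression rule {rule!r}")
    return [
        OverexpressionCall(
            sample_id=str(sample),
            fold=float(f),
            threshold=threshold,
            called=bool(called(float(f))),
            reference_group_mean=m,
            reference_group_sd=s,
        )
        for sample, f in folds.folds.items()
    ]


def copy_number_ratio(
    ct: CtTable,
    target: str,
    internal_control: str,
    pairs: Sequence[tuple[str, str]],
    gain_bound: float = 1.5,
    loss_bound: float = 0.67,
) -> list[CopyNumberRatio]:
    """Tumor/normal copy ratio from single-tube co-amplification Ct values.

    ratio = 2^-[(Ct_t,target - Ct_t,ctrl) - (Ct_n,target - Ct_n,ctrl)];
    gain if ratio >= gain_bound, loss if ratio <= loss_bound, else unchanged.
    """
    mean = _pivot_mean_ct(ct, [target, internal_control])
    out = []
    for tumor, normal in pairs:
        for member in (tumor, normal):
            if member not in mean.index:
                raise QpcrError(f"pair ({tumor}, {normal}): sample {member!r} not in Ct table")
        dct_t = mean.loc[tumor, target] - mean.loc[tumor, internal_control]
        dct_n = mean.loc[normal, target] - mean.loc[normal, internal_control]
        ratio = float(np.power(2.0, -(dct_t - dct_n)))
        status = "gain" if ratio >= gain_bound else ("loss" if ratio <= loss_bound else "unchanged")
        out.append(CopyNumberRatio(pair_id=(tumor, normal), ratio=ratio, status=status))
    return out


def compare_classes(
    folds: FoldChangeTable,
    labels: Mapping[str, str],
    reference_classes: Iterable[str] = ("Normal", "BE", "Dysplasia"),
    log_scale: bool = True,
) -> ClassComparison:
    """Per-class fold summaries and Welch t-tests against the reference classes.

    Tests are on log2 fold changes by default (fold distributions are
    log-normal-like).  Classes with fewer than 2 samples are skipped.
    """
    values = np.log2(folds.folds) if log_scale else folds.folds
    by_class: dict[str, pd.Series] = {}
    for sample, v in values.items():
        cls = labels.get(sample)
        if cls is not None:
            by_class.setdefault(cls, []).append(v)
    by_class = {c: pd.Series(v) for c, v in by_class.items()}
    skipped = sorted(c for c, v in by_class.items() if len(v) < 2)
    usable = {c: v for c, v in by_class.items() if len(v) >= 2}
    if len(usable) < 2:
        raise QpcrError("need >= 2 classes with >= 2 samples each")
    summary = pd.DataFrame(
        {
            "n": {c: len(v) for c, v in usable.items()},
            "mean": {c: float(v.mean()) for c, v in usable.items()},
            "sd": {c: float(v.std(ddof=1)) for c, v in usable.items()},
        }
    ).sort_index()
    refs = [c for c in reference_classes if c in usable]
    pvals = {}
    for cls, v in usable.items():
        row = {}
        for ref in refs:
            if ref == cls:
                row[ref] = float("nan")
                continue
            w = usable[ref]
            if v.std(ddof=1) == 0 and w.std(ddof=1) == 0:
                # Welch statistic is 0/0; identical degenerate classes are
                # indistinguishable, distinct ones trivially different.
                row[ref] = 1.0 if v.mean() == w.mean() else 0.0
                continue
            t, p = stats.ttest_ind(v, w, equal_var=False)
            row[ref] = float(p)
        pvals[cls] = row
    pairwise = pd.DataFrame(pvals).T.sort_index()
    return ClassComparison(summary=summary, pairwise_p=pairwise, skipped=skipped)
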