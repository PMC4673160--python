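"""Seeded synthetic cohorts with the structure the analysis assumes.

The generative model is deliberately minimal.  Co-overexpression of all
isoforms is induced by one shared per-sample log-normal factor multiplying
every isoform — the simplest mechanism that reproduces strongly correlated
isoform groups in a tumor cohort.  Per sample:

    total   = 2 ** (baseline + class_shift + N(0, sample_factor_sd))
    props   ~ Dirichlet(concentration)          (one draw per sample)
    abund_i = total * props_i

Exon-level probe signals are then the log2 of the summed abundances of the
isoforms containing the exon plus i.i.d. Gaussian probe noise, and Ct tables
follow Ct = intercept - log2(quantity) + noise with constant-quantity
reference genes.

The Dirichlet means (OPNa 0.375, OPNb 0.375, OPNc 0.125, OPN4 0.0625,
OPN5 0.0625) encode the qualitative cohort observations — OPNc scarcer than
OPNa/OPNb, OPN4/OPN5 minor, OPNb above or below OPNa in individual tumors —
and the concentration scale is calibrated so that every identifiable group
co-varies strongly with the total (see docs/methods.md); none of these
numbers are measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .deconvolution import ExpressionMatrix
from .qpcr import CtTable
from .transcript_model import IncidenceMatrix

__all__ = [
    "CLASSES",
    "CohortLabels",
    "SimulationConfig",
    "SimulationError",
    "simulate_cohort",
    "simulate_exon_signals",
    "simulate_ct",
    "simulate_bundle",
]

#: Closed histology vocabulary: normal squamous mucosa, Barrett's esophagus,
#: dysplasia, and esophageal adenocarcinoma by stage.
CLASSES = ("Normal", "BE", "Dysplasia", "EAC_I", "EAC_II", "EAC_III", "EAC_IV")

ISOFORMS = ("OPNa", "OPNb", "OPNc", "OPN4", "OPN5")


class SimulationError(ValueError):
    pass


@dataclass
class CohortLabels:
    """Per-sample histology class from the closed vocabulary."""

    labels: pd.Series  # sample id -> class

    def __post_init__(self) -> None:
        bad = sorted(set(self.labels) - set(CLASSES))
        if bad:
            raise SimulationError(f"unknown class token(s) {bad}; allowed: {list(CLASSES)}")
        if self.labels.index.duplicated().any():
            dup = self.labels.index[self.labels.index.duplicated()].tolist()
            raise SimulationError(f"duplicate sample id(s) {dup}")

    def __getitem__(self, sample: str) -> str:
        return str(self.labels[sample])

    def get(self, sample: str, default=None):
        return self.labels.get(sample, default)

    def samples_in(self, classes) -> list[str]:
        classes = set(classes)
        return [s for s, c in self.labels.items() if c in classes]

    def to_mapping(self) -> dict[str, str]:
        return {str(s): str(c) for s, c in self.labels.items()}


def _default_shifts() -> dict[str, float]:
    # EAC stages +3 log2 (8-fold) over Normal; dysplasia intermediate.
    return {
        "Normal": 0.0,
        "BE": 0.0,
        "Dysplasia": 1.0,
        "EAC_I": 3.0,
        "EAC_II": 3.0,
        "EAC_III": 3.0,
        "EAC_IV": 3.0,
    }


def _default_concentration() -> dict[str, float]:
    return {"OPNa": 18.0, "OPNb": 18.0, "OPNc": 6.0, "OPN4": 3.0, "OPN5": 3.0}


def _default_reference_quantities() -> dict[str, float]:
    return {"GAPDH": 1024.0, "ACTB": 512.0, "RPLP0": 256.0}


@dataclass
class SimulationConfig:
    """All knobs of the generator; fixed seed implies byte-identical outputs."""

    n_per_class: int | Mapping[str, int] = 30
    isoform_concentration: dict[str, float] = field(default_factory=_default_concentration)
    class_log2_shift: dict[str, float] = field(default_factory=_default_shifts)
    baseline_log2: float = 6.0
    sample_factor_sd: float = 1.0
    probe_noise_sd: float = 0.1
    probesets_per_exon: int = 1
    probesets_per_common_exon: int = 4
    #: exons with no probe set on the emulated array (the exon array used for
    #: the cohort carried no probe set for SPP1 exon 6)
    excluded_exons: tuple[int, ...] = (6,)
    ct_intercept: float = 30.0
    ct_noise_sd: float = 0.1
    ct_replicates: int = 2
    reference_quantities: dict[str, float] = field(
        default_factory=_default_reference_quantities
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_factor_sd", "probe_noise_sd", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if isinstance(self.n_per_class, Mapping):
            bad = sorted(set(self.n_per_class) - set(CLASSES))
            if bad:
                raise SimulationError(f"n_per_class: unknown class(es) {bad}")
            if any(n < 0 for n in self.n_per_class.values()):
                raise SimulationError("n_per_class: counts must be >= 0")
        elif self.n_per_class < 0:
            raise SimulationError("n_per_class must be >= 0")
        if set(self.isoform_concentration) != set(ISOFORMS):
            raise SimulationError(
                f"isoform_concentration must cover exactly {list(ISOFORMS)}"
            )
        if any(a <= 0 for a in self.isoform_concentration.values()):
            raise SimulationError("isoform_concentration: concentrations must be > 0")
        bad = sorted(set(self.class_log2_shift) - set(CLASSES))
        if bad:
            raise SimulationError(f"class_log2_shift: unknown class(es) {bad}")
        if self.probesets_per_exon < 1 or self.probesets_per_common_exon < 1:
            raise SimulationError("probesets per exon must be >= 1")
        if self.ct_replicates < 1:
            raise SimulationError("ct_replicates must be >= 1")
        if any(q <= 0 for q in self.reference_quantities.values()):
            raise SimulationError("reference_quantities must be > 0")

    def class_counts(self) -> dict[str, int]:
        if isinstance(self.n_per_class, Mapping):
            return {c: int(self.n_per_class.get(c, 0)) for c in CLASSES}
        return {c: int(self.n_per_class) for c in CLASSES}

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


def simulate_cohort(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CohortLabels, pd.DataFrame]:
    """Draw per-sample class labels and true isoform abundances.

    Returns labels and a samples x isoforms DataFrame of positive
    linear-scale abundances (the ground truth for recovery tests).
    """
    rng = rng if rng is not None else cfg.rng()
    counts = cfg.class_counts()
    samples, classes = [], []
    i = 1
    for cls in CLASSES:
        for _ in range(counts[cls]):
            samples.append(f"S{i:04d}")
            classes.append(cls)
            i += 1
    if not samples:
        raise SimulationError("empty cohort: all class counts are zero")
    labels = CohortLabels(pd.Series(classes, index=samples, name="class"))
    shifts = np.array([cfg.class_log2_shift.get(c, 0.0) for c in classes])
    log2_total = cfg.baseline_log2 + shifts + rng.normal(0.0, cfg.sample_factor_sd, len(samples))
    total = np.power(2.0, log2_total)
    conc = [cfg.isoform_concentration[i] for i in ISOFORMS]
    props = rng.dirichlet(conc, size=len(samples))
    truth = pd.DataFrame(total[:, None] * props, index=samples, columns=list(ISOFORMS))
    return labels, truth


def simulate_exon_signals(
    truth: pd.DataFrame,
    M: IncidenceMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Exon-level probe-set signals from true abundances.

    Each probe set mapped to exon e reads log2(sum of abundances of the
    isoforms containing e) plus N(0, probe_noise_sd).  Common exons get
    ``probesets_per_common_exon`` probe sets, the rest ``probesets_per_exon``.
    """
    rng = rng if rng is not None else cfg.rng()
    if list(truth.columns) != list(M.isoform_ids):
        raise SimulationError(
            f"truth isoforms {list(truth.columns)} do not match incidence rows {M.isoform_ids}"
        )
    freq = M.frequency
    zero = [e for e in M.exon_ids if freq[e] == 0]
    if zero:
        raise SimulationError(f"exon(s) {zero} contained in no isoform")
    excluded = set(cfg.excluded_exons)
    if not set(M.exon_ids) - excluded:
        raise SimulationError("all exons excluded; nothing to simulate")
    common = set(M.common_exons())
    abundances = truth.to_numpy()
    incidence = M.matrix.to_numpy().astype(float)
    cols: dict[str, np.ndarray] = {}
    probe_to_exon: dict[str, int] = {}
    for j, e in enumerate(M.exon_ids):
        if e in excluded:
            continue
        n_probes = cfg.probesets_per_common_exon if e in common else cfg.probesets_per_exon
        exon_sum = abundances @ incidence[:, j]
        for p in range(1, n_probes + 1):
            pid = f"PS{int(e):02d}_{p}"
            noise = rng.normal(0.0, cfg.probe_noise_sd, len(truth))
            cols[pid] = np.log2(exon_sum) + noise
            probe_to_exon[pid] = int(e)
    values = pd.DataFrame(cols, index=truth.index)
    return ExpressionMatrix(values=values, probe_to_exon=probe_to_exon)


def simulate_ct(
    quantities: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    roles: Mapping[str, str] | None = None,
    include_references: bool = True,
) -> CtTable:
    """Replicate Ct table from linear-scale quantities (samples x assays).

    Ct = ct_intercept - log2(quantity) + N(0, ct_noise_sd), replicates
    independent.  Reference genes are appended at their configured constant
    quantities unless ``include_references`` is False.  Columns of
    ``quantities`` default to role 'target'.
    """
    rng = rng if rng is not None else cfg.rng()
    if (quantities <= 0).any().any():
        bad = quantities.columns[(quantities <= 0).any()].tolist()
        raise SimulationError(f"non-positive quantity for assay(s) {bad}")
    roles = dict(roles or {})
    frames = []
    assay_quantities: list[tuple[str, str, pd.Series]] = [
        (a, roles.get(a, "target"), quantities[a]) for a in quantities.columns
    ]
    if include_references:
        for gene, q in cfg.reference_quantities.items():
            assay_quantities.append(
                (gene, "reference", pd.Series(q, index=quantities.index))
            )
    for assay, role, q in assay_quantities:
        base = cfg.ct_intercept - np.log2(q.to_numpy(dtype=float))
        for rep in range(1, cfg.ct_replicates + 1):
            noise = rng.normal(0.0, cfg.ct_noise_sd, len(q))
            frames.append(
                pd.DataFrame(
                    {
                        "sample": q.index,
                        "assay": assay,
                        "role": role,
                        "replicate": rep,
                        "ct": base + noise,
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    return CtTable(records=records)


def simulate_bundle(
    cfg: SimulationConfig, M: IncidenceMatrix, target_assay: str = "SPP1"
) -> dict:
    """One cohort with everything the pipeline consumes, from a single rng.

    Returns labels, truth, the exon-level expression matrix, and a Ct table
    for total gene expression (target = summed isoform abundance).
    """
    rng = cfg.rng()
    labels, truth = simulate_cohort(cfg, rng)
    expression = simulate_exon_signals(truth, M, cfg, rng)
    quantities = pd.DataFrame({target_assay: truth.sum(axis=1)})
    ct = simulate_ct(quantities, cfg, rng)
    return {"labels": labels, "truth": truth, "expression": expression, "ct": ct}
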