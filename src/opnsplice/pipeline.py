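"""End-to-end orchestration: simulate -> incidence -> deconvolve -> qpcr -> report.

The pipeline is configured from a YAML mapping (see :class:`PipelineConfig`),
writes every output atomically under one output directory, and produces a
:class:`RunReport` rendered both as JSON and Markdown.  Given a fixed seed
the tabular outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io, plots, spp1
from .deconvolution import (
    correlate_groups,
    lsq_estimates,
    select_total_proxy,
    subtraction_estimates,
)
from .qpcr import call_overexpression, compare_classes, ddct_fold_change
from .simulate import SimulationConfig, simulate_bundle
from .transcript_model import build_incidence, identifiable_groups

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline"]

log = logging.getLogger("opnsplice")


class PipelineError(RuntimeError):
    pass


_KNOWN_TOP = {"seed", "outdir", "simulate", "inputs", "deconvolution", "qpcr", "plots", "strict"}
_KNOWN_INPUTS = {"annotation", "expression", "probe_map", "ct", "labels"}
_KNOWN_DECONV = {"k_proxy", "estimator", "correlation_scale"}
_KNOWN_QPCR = {"target", "references", "calibrator_classes", "reference_classes", "rule"}


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    k_proxy: int = 3
    estimator: str = "subtraction"
    correlation_scale: str = "log2"
    qpcr_target: str = "SPP1"
    qpcr_references: tuple[str, ...] = ("GAPDH", "ACTB", "RPLP0")
    calibrator_classes: tuple[str, ...] = ("Normal", "BE")
    reference_classes: tuple[str, ...] = ("Normal", "BE")
    overexpression_rule: str = "2m_plus_s"
    make_plots: bool = True
    strict: bool = False

    @classmethod
    def from_mapping(cls, raw: dict[str, Any], base_dir: Path | None = None) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise PipelineError(f"unknown config key(s) {sorted(unknown)}")
        for section, allowed in (("inputs", _KNOWN_INPUTS), ("deconvolution", _KNOWN_DECONV), ("qpcr", _KNOWN_QPCR)):
            extra = set(raw.get(section) or {}) - allowed
            if extra:
                raise PipelineError(f"unknown key(s) {sorted(extra)} in config section {section!r}")
        if "outdir" not in raw:
            raise PipelineError("config must set 'outdir'")
        base = base_dir or Path.cwd()
        resolve = lambda p: str(p) if Path(p).is_absolute() else str(base / p)
        deconv = raw.get("deconvolution") or {}
        qp = raw.get("qpcr") or {}
        return cls(
            outdir=Path(resolve(raw["outdir"])),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            inputs={k: resolve(v) for k, v in (raw.get("inputs") or {}).items() if v is not None},
            k_proxy=int(deconv.get("k_proxy", 3)),
            estimator=str(deconv.get("estimator", "subtraction")),
            correlation_scale=str(deconv.get("correlation_scale", "log2")),
            qpcr_target=str(qp.get("target", "SPP1")),
            qpcr_references=tuple(qp.get("references", ("GAPDH", "ACTB", "RPLP0"))),
            calibrator_classes=tuple(qp.get("calibrator_classes", ("Normal", "BE"))),
            reference_classes=tuple(qp.get("reference_classes", ("Normal", "BE"))),
            overexpression_rule=str(qp.get("rule", "2m_plus_s")),
            make_plots=bool(raw.get("plots", True)),
            strict=bool(raw.get("strict", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_mapping(io.load_yaml(path), base_dir=Path(path).resolve().parent)


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run; every executed stage
    contributes one section.  The Markdown rendering carries the same
    content."""

    sections: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.sections, indent=2, sort_keys=True, default=_jsonable)

    def to_markdown(self) -> str:
        lines = ["# opnsplice run report", ""]
        for name, content in self.sections.items():
            lines.append(f"## {name}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(content, indent=2, sort_keys=True, default=_jsonable))
            lines.append("```")
            lines.append("")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run all stages in dependency order and write outputs under cfg.outdir."""
    report = RunReport()
    warnings_acc: list[str] = []
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.sections["versions"] = {
        "opnsplice": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    report.sections["config"] = {
        "seed": cfg.seed,
        "estimator": cfg.estimator,
        "k_proxy": cfg.k_proxy,
        "correlation_scale": cfg.correlation_scale,
        "qpcr_target": cfg.qpcr_target,
        "qpcr_references": list(cfg.qpcr_references),
        "calibrator_classes": list(cfg.calibrator_classes),
        "reference_classes": list(cfg.reference_classes),
        "overexpression_rule": cfg.overexpression_rule,
        "simulated": cfg.simulate is not None,
    }

    # ---- annotation / incidence ------------------------------------------
    with _stage(report, "incidence"):
        if "annotation" in cfg.inputs:
            exons, isoforms = io.read_annotation(cfg.inputs["annotation"])
        else:
            exons, isoforms = list(spp1.SPP1_EXONS), list(spp1.SPP1_ISOFORMS)
        M = build_incidence(exons, isoforms)
        io.write_incidence(M, outdir / "incidence.tsv")
        report.sections["incidence"] = {
            "n_isoforms": M.n_isoforms,
            "n_exons": len(M.exon_ids),
            "frequency": {str(e): int(f) for e, f in M.frequency.items()},
        }

    # ---- inputs ----------------------------------------------------------
    with _stage(report, "inputs"):
        if cfg.simulate is not None:
            sim_cfg = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
            bundle = simulate_bundle(sim_cfg, M, target_assay=cfg.qpcr_target)
            inp = outdir / "inputs"
            io.write_expression(bundle["expression"], inp / "expression.tsv", inp / "probe_map.tsv")
            io.write_ct(bundle["ct"], inp / "ct.csv")
            io.write_labels(bundle["labels"], inp / "labels.tsv")
            io.write_truth(bundle["truth"], inp / "truth.tsv")
            expression_path, probe_map_path = inp / "expression.tsv", inp / "probe_map.tsv"
            ct_path, labels_path = inp / "ct.csv", inp / "labels.tsv"
        else:
            try:
                expression_path = cfg.inputs["expression"]
                probe_map_path = cfg.inputs["probe_map"]
                ct_path = cfg.inputs["ct"]
                labels_path = cfg.inputs["labels"]
            except KeyError as exc:
                raise PipelineError(f"config inputs missing {exc}") from None
        X = io.read_expression(expression_path, probe_map_path)
        ct = io.read_ct(ct_path)
        labels = io.read_labels(labels_path)
        _check_sample_ids(X.samples, ct.samples(), list(labels.labels.index))
        report.sections["inputs"] = {
            "n_samples_expression": len(X.samples),
            "n_probesets": len(X.probesets),
            "n_ct_records": len(ct.records),
            "n_labelled_samples": len(labels.labels),
            "class_counts": labels.labels.value_counts().sort_index().to_dict(),
        }
        discordant = ct.discordant
        if len(discordant):
            msg = f"{len(discordant)} (sample, assay) pairs with discordant Ct replicates"
            if cfg.strict:
                raise PipelineError(msg)
            warnings_acc.append(msg)

    # ---- identifiability -------------------------------------------------
    with _stage(report, "identifiability"):
        observed = sorted({X.probe_to_exon[p] for p in X.probesets})
        ident = identifiable_groups(M, observed)
        report.sections["identifiability"] = {
            "observed_exons": list(ident.observed_exons),
            "design_rank": ident.design_rank,
            "fully_identifiable": ident.fully_identifiable,
            "estimable_groups": ident.group_labels(),
            "null_space_dim": len(ident.null_space_basis),
        }

    # ---- deconvolution ---------------------------------------------------
    with _stage(report, "deconvolution"):
        proxy = select_total_proxy(X, M, k=cfg.k_proxy)
        if cfg.estimator == "subtraction":
            estimates = subtraction_estimates(proxy, X, M, observed)
        elif cfg.estimator == "lsq":
            estimates = lsq_estimates(X, M, observed)
        else:
            raise PipelineError(f"unknown estimator {cfg.estimator!r}")
        correlations = correlate_groups(estimates, proxy, scale=cfg.correlation_scale)
        io.write_groups(estimates, outdir / "groups.tsv")
        io.write_correlations(correlations, outdir / "correlations.tsv")
        if cfg.make_plots:
            for g in estimates:
                plots.plot_group_scatter(g, proxy, outdir / "plots" / f"scatter_{g.group_label}.png")
            plots.plot_expression_heatmap(X, outdir / "plots" / "expression_heatmap.png")
        report.sections["deconvolution"] = {
            "proxy_probesets": proxy.selected_probesets,
            "estimator": cfg.estimator,
            "groups": {
                c.group_label: {
                    "pearson_r": None if not c.computable else round(c.pearson_r, 6),
                    "p_value": None if not c.computable else c.p_value,
                    "n": c.n,
                }
                for c in correlations
            },
        }

    # ---- qpcr ------------------------------------------------------------
    with _stage(report, "qpcr"):
        calibrator = labels.samples_in(cfg.calibrator_classes)
        ct_samples = set(ct.samples())
        calibrator = [s for s in calibrator if s in ct_samples]
        folds = ddct_fold_change(ct, cfg.qpcr_target, list(cfg.qpcr_references), calibrator)
        calls = call_overexpression(
            folds, labels.to_mapping(), cfg.reference_classes, rule=cfg.overexpression_rule
        )
        comparison = compare_classes(folds, labels.to_mapping(), cfg.reference_classes)
        io.write_table(
            pd.DataFrame({"fold": folds.folds, "reference_index_ct": folds.reference_index_ct}),
            outdir / "folds.tsv",
            index_label="sample",
        )
        io.write_table(
            pd.DataFrame(
                [
                    {
                        "sample": c.sample_id,
                        "fold": c.fold,
                        "threshold": c.threshold,
                        "called": c.called,
                    }
                    for c in calls
                ]
            ),
            outdir / "calls.tsv",
            index=False,
        )
        io.write_table(comparison.summary, outdir / "class_summary.tsv", index_label="class")
        io.write_table(comparison.pairwise_p, outdir / "class_pairwise_p.tsv", index_label="class")
        n_called = sum(c.called for c in calls)
        report.sections["qpcr"] = {
            "n_samples": len(folds.folds),
            "threshold": calls[0].threshold if calls else None,
            "n_called": n_called,
            "called_fraction": round(n_called / len(calls), 6) if calls else None,
            "class_means_log2_fold": {
                c: round(v, 6) for c, v in comparison.summary["mean"].items()
            },
            "skipped_classes": comparison.skipped,
        }
        if comparison.skipped:
            warnings_acc.append(f"classes skipped in comparison: {comparison.skipped}")

    report.sections["warnings"] = warnings_acc
    io.atomic_write_text(outdir / "report.json", report.to_json() + "\n")
    io.atomic_write_text(outdir / "report.md", report.to_markdown())
    return report


def _check_sample_ids(expression: list[str], ct: list[str], labels: list[str]) -> None:
    e, c, l = set(expression), set(ct), set(labels)
    problems = []
    if e - l:
        problems.append(f"expression samples without labels: {sorted(e - l)[:5]}")
    if c - l:
        problems.append(f"Ct samples without labels: {sorted(c - l)[:5]}")
    if problems:
        raise PipelineError("inconsistent sample ids across inputs: " + "; ".join(problems))
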