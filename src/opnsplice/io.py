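"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions are fixed for reproducibility: UTF-8, tab-separated tables with
a header row (Ct tables are comma-separated), ``.`` decimal separator, no
quoting in identifiers.  All writers go through an atomic replace so a
failed run never leaves a partial file.

Annotation can come from GTF/GFF3 (exon ordinals assigned by genomic order
on the gene strand) or from a two-column isoform table
``isoform_id<TAB>comma-separated exon ids`` (exon lengths unknown, set to 1).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .deconvolution import ExpressionMatrix, GroupCorrelation, GroupEstimate
from .qpcr import ASSAY_ROLES, CtTable
from .simulate import CLASSES, CohortLabels
from .transcript_model import ExonDef, IncidenceMatrix, IsoformDef

__all__ = [
    "FormatError",
    "atomic_write_text",
    "write_table",
    "read_annotation",
    "read_isoform_table",
    "write_isoform_table",
    "read_incidence",
    "write_incidence",
    "read_expression",
    "write_expression",
    "read_ct",
    "write_ct",
    "read_labels",
    "write_labels",
    "read_truth",
    "write_truth",
    "write_groups",
    "write_correlations",
    "load_yaml",
]


class FormatError(ValueError):
    """Malformed input file; the message carries file and location."""


def atomic_write_text(path: str | os.PathLike, content: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | os.PathLike, sep: str = "\t", index: bool = True,
                index_label: str | None = None, float_format: str = "%.10g") -> None:
    atomic_write_text(
        path,
        df.to_csv(sep=sep, index=index, index_label=index_label, float_format=float_format),
    )


def _read_frame(path, sep, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep=sep, **kwargs)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- annotation

def read_annotation(path: str | os.PathLike) -> tuple[list[ExonDef], list[IsoformDef]]:
    """Read exon/isoform definitions from GTF/GFF3 or a two-column TSV."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return _read_gxf(path)
    return read_isoform_table(path)


def _read_gxf(path: Path) -> tuple[list[ExonDef], list[IsoformDef]]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exon_feats = list(db.features_of_type("exon"))
    if not exon_feats:
        raise FormatError(f"{path}: no 'exon' features found")
    strands = {f.strand for f in exon_feats}
    if len(strands) > 1:
        raise FormatError(f"{path}: exons on mixed strands {sorted(strands)}")
    strand = strands.pop()
    intervals = sorted({(f.start, f.end) for f in exon_feats}, reverse=(strand == "-"))
    ordinal = {iv: i + 1 for i, iv in enumerate(intervals)}
    exons = [
        ExonDef(exon_id=ordinal[iv], length=iv[1] - iv[0] + 1, genomic_start=iv[0], genomic_end=iv[1])
        for iv in intervals
    ]
    by_transcript: dict[str, set[int]] = {}
    for f in exon_feats:
        tids = f.attributes.get("transcript_id") or [f.attributes.get("Parent", ["?"])[0]]
        for tid in tids:
            by_transcript.setdefault(tid, set()).add(ordinal[(f.start, f.end)])
    isoforms = [
        IsoformDef(isoform_id=tid, exons=tuple(sorted(ids)))
        for tid, ids in by_transcript.items()
    ]
    return exons, isoforms


def read_isoform_table(path: str | os.PathLike) -> tuple[list[ExonDef], list[IsoformDef]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    isoforms: list[IsoformDef] = []
    seen: set[str] = set()
    all_exons: set[int] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
        iso_id, exon_field = parts
        if iso_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate isoform id {iso_id!r}")
        seen.add(iso_id)
        try:
            exon_ids = tuple(int(t) for t in exon_field.split(",") if t.strip() != "")
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer exon id in {exon_field!r}") from None
        isoforms.append(IsoformDef(isoform_id=iso_id, exons=exon_ids))
        all_exons.update(exon_ids)
    if not isoforms:
        raise FormatError(f"{path}: no isoform rows")
    exons = [ExonDef(exon_id=e, length=1) for e in sorted(all_exons)]
    return exons, isoforms


def write_isoform_table(isoforms: Sequence[IsoformDef], path: str | os.PathLike) -> None:
    lines = [f"{iso.isoform_id}\t{','.join(str(e) for e in iso.exons)}" for iso in isoforms]
    atomic_write_text(path, "\n".join(lines) + "\n")


# ----------------------------------------------------------------- incidence

def write_incidence(M: IncidenceMatrix, path: str | os.PathLike) -> None:
    write_table(M.to_frame(), path, index_label="isoform")


def read_incidence(path: str | os.PathLike) -> IncidenceMatrix:
    df = _read_frame(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns = [int(c) for c in df.columns]
    if "frequency" in df.index:
        df = df.drop(index="frequency")
    if not df.isin([0, 1]).all().all():
        raise FormatError(f"{path}: incidence entries must be 0/1")
    return IncidenceMatrix(matrix=df.astype(int))


# ---------------------------------------------------------------- expression

def write_expression(X: ExpressionMatrix, path, probe_map_path) -> None:
    write_table(X.values, path, index_label="sample")
    pm = pd.DataFrame(
        {"probeset": list(X.probe_to_exon), "exon_id": list(X.probe_to_exon.values())}
    )
    write_table(pm, probe_map_path, index=False)


def read_expression(path, probe_map_path) -> ExpressionMatrix:
    df = _read_frame(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dup}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise FormatError(f"{path}: non-numeric value in column {col!r}, row(s) {bad}")
    pm = _read_frame(probe_map_path, sep="\t")
    if not {"probeset", "exon_id"} <= set(pm.columns):
        raise FormatError(f"{probe_map_path}: expected columns 'probeset' and 'exon_id'")
    probe_to_exon = dict(zip(pm["probeset"].astype(str), pm["exon_id"].astype(int)))
    return ExpressionMatrix(values=df.astype(float), probe_to_exon=probe_to_exon)


# ------------------------------------------------------------------------ ct

def write_ct(ct: CtTable, path) -> None:
    write_table(ct.records, path, sep=",", index=False)


def read_ct(path, concordance_window: float = 1.0) -> CtTable:
    df = _read_frame(path, sep=",")
    required = ["sample", "assay", "role", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    bad_roles = sorted(set(df["role"]) - set(ASSAY_ROLES))
    if bad_roles:
        raise FormatError(f"{path}: unknown role(s) {bad_roles}; allowed: {list(ASSAY_ROLES)}")
    ct_num = pd.to_numeric(df["ct"], errors="coerce")
    if ct_num.isna().any():
        rows = (df.index[ct_num.isna()] + 2).tolist()  # +2: header + 1-based
        raise FormatError(f"{path}: non-numeric ct at line(s) {rows}")
    df["ct"] = ct_num
    return CtTable(records=df, concordance_window=concordance_window)


# -------------------------------------------------------------------- labels

def write_labels(labels: CohortLabels, path) -> None:
    df = labels.labels.rename("class").to_frame()
    write_table(df, path, index_label="sample")


def read_labels(path) -> CohortLabels:
    df = _read_frame(path, sep="\t")
    if not {"sample", "class"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'sample' and 'class'")
    unknown = sorted(set(df["class"]) - set(CLASSES))
    if unknown:
        raise FormatError(
            f"{path}: unknown class token(s) {unknown}; allowed vocabulary: {list(CLASSES)}"
        )
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dup}")
    return CohortLabels(pd.Series(df["class"].values, index=df["sample"].values, name="class"))


# --------------------------------------------------------------------- truth

def write_truth(truth: pd.DataFrame, path) -> None:
    write_table(truth, path, index_label="sample")


def read_truth(path) -> pd.DataFrame:
    df = _read_frame(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    return df


# ------------------------------------------------------------------- outputs

def write_groups(estimates: Sequence[GroupEstimate], path) -> None:
    df = pd.DataFrame({g.group_label: g.abundances for g in estimates})
    clip = pd.DataFrame({f"{g.group_label}_clipped": g.clipped for g in estimates})
    write_table(pd.concat([df, clip], axis=1), path, index_label="sample")


def write_correlations(correlations: Sequence[GroupCorrelation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "group": c.group_label,
                "pearson_r": c.pearson_r,
                "p_value": c.p_value,
                "n": c.n,
                "computable": c.computable,
            }
            for c in correlations
        ]
    )
    write_table(df, path, index=False)


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return data
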