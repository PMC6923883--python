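"""Reading and writing the pipeline's file formats.

Matrices are TSV: first column = feature id, header = sample ids, '.'
decimal, UTF-8.  Gene sets are GMT (set name, description, then tab-separated
members).  Tables (skewness, tail assignments, probe results) are TSV;
nested reports are JSON.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .enrich import GeneSetCollection
from .methlink import MethylationMatrix, validate_annotation
from .skewcore import ExpressionMatrix
from .tailsplit import TailAssignment


def _read_tsv_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return frame


def read_matrix(path, kind: str = "expression", platform: str = "other", origin: str = "native-M"):
    """Parse a feature x sample TSV into an ExpressionMatrix or
    MethylationMatrix, validating ids and numeric content."""
    frame = _read_tsv_matrix(path)
    if kind == "expression":
        return ExpressionMatrix(data=frame, platform=platform)
    if kind == "methylation":
        return MethylationMatrix(data=frame, origin=origin)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(frame: pd.DataFrame, path, feature_name: str = "feature_id") -> None:
    frame = frame.copy()
    frame.index.name = feature_name
    frame.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, gene_id, region."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return validate_annotation(frame)


def read_gmt(path, module_map: dict[str, str] | None = None) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a line are deduplicated
    with a warning, empty lines are skipped, short lines are errors."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3")
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated", stacklevel=2)
            sets[name] = frozenset(unique)
            descriptions[name] = desc
    modules = {name: module_map.get(name, "") for name in sets} if module_map else {}
    return GeneSetCollection(sets=sets, descriptions=descriptions, modules=modules)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_skew_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_skew_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "skewness" not in frame.columns:
        raise ValueError(f"{path}: not a skewness table (no 'skewness' column)")
    return frame


def write_tail_assignments(tails: dict[str, TailAssignment], path) -> None:
    """Long-format TSV: gene, sample, group (tail/nontail), direction,
    method, parameter."""
    rows = []
    for gene, a in tails.items():
        for sample in a.tail:
            rows.append((gene, sample, "tail", a.direction, a.method, a.parameter))
        for sample in a.nontail:
            rows.append((gene, sample, "nontail", a.direction, a.method, a.parameter))
    pd.DataFrame(
        rows, columns=["gene", "sample", "group", "direction", "method", "parameter"]
    ).to_csv(path, sep="\t", index=False)


def read_tail_assignments(path) -> dict[str, TailAssignment]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, TailAssignment] = {}
    for gene, sub in frame.groupby("gene"):
        out[str(gene)] = TailAssignment(
            gene=str(gene),
            direction=int(sub["direction"].iloc[0]),
            tail=sub.loc[sub["group"] == "tail", "sample"].tolist(),
            nontail=sub.loc[sub["group"] == "nontail", "sample"].tolist(),
            method=str(sub["method"].iloc[0]),
            parameter=float(sub["parameter"].iloc[0]),
        )
    return out
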