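"""Readers and writers for on-disk artifacts.

All artifacts are tab-separated UTF-8 text (the DREAM convention) or JSON:

* expression matrix: header row of sample ids, first column gene ids;
* gold standard: ``regulator<TAB>target<TAB>{0|1}`` lines (the label is
  optional and defaults to 1);
* TF list: one gene id per line;
* network: ``gene_a  gene_b  score  rank  direction`` TSV;
* association matrix: square TSV with gene ids on both axes;
* metrics: a flat JSON object.

Writers emit Unix newlines and embed a provenance record (tool version,
command, parameters, seeds) as a ``#provenance`` comment line (TSV) or a
``provenance`` key (JSON); readers accept any newline convention and skip
``#`` comment lines.  Gene ids are case-sensitive opaque strings.  Round
trips are lossless at 15 significant digits (scores are serialised with
``repr``-faithful formatting).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import FormatError, UniverseMismatchError
from .evaluation import GoldStandard, MetricSet
from .netinfer import AssociationMatrix, Edge, EdgeList, ExpressionMatrix

__all__ = [
    "ProvenanceRecord",
    "read_expression",
    "write_expression",
    "read_gold_standard",
    "write_gold_standard",
    "read_tf_list",
    "write_tf_list",
    "read_network",
    "write_network",
    "read_association",
    "write_association",
    "write_metrics",
    "read_metrics",
]


@dataclass(frozen=True)
class ProvenanceRecord:
    """How an artifact was produced; attached to every written file.

    The timestamp is empty unless explicitly supplied, so that identical
    inputs and seeds produce byte-identical artifacts.
    """

    tool_version: str = _pkg_version
    command: str = ""
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timestamp: str = ""

    def as_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _prov_line(provenance: ProvenanceRecord | None) -> str:
    return f"#provenance\t{(provenance or ProvenanceRecord()).as_json()}\n"


def _data_lines(path: Path) -> list[tuple[int, str]]:
    """(1-based line number, stripped content) for non-comment, non-blank lines."""
    text = Path(path).read_text(encoding="utf-8")
    out = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append((i, line))
    return out


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV matrix with strict validation."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate gene id {dup[0]!r}")
    values = np.empty(df.shape)
    for i, gene in enumerate(df.index):
        for j, sample in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                values[i, j] = float(cell)
                if not np.isfinite(values[i, j]):
                    raise ValueError
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"sample {sample!r}"
                ) from None
    return ExpressionMatrix(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=values,
    )


def write_expression(
    expr: ExpressionMatrix, path, provenance: ProvenanceRecord | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_prov_line(provenance))
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# gold standards and TF lists
# ---------------------------------------------------------------------------


def read_gold_standard(path, universe) -> GoldStandard:
    """Read a DREAM-style directed edge list.

    Lines are ``regulator<TAB>target`` with an optional trailing ``1``
    (positive) or ``0`` (explicit negative, skipped: unlisted pairs are
    negative by default).  Ids outside `universe` are an error; duplicate
    positive lines are deduplicated.
    """
    universe = frozenset(universe)
    positives: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(Path(path)):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 2:
            reg, tgt, label = *parts, "1"
        elif len(parts) == 3:
            reg, tgt, label = parts
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 fields")
        if label not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: bad label {label!r}")
        if reg not in universe or tgt not in universe:
            bad = reg if reg not in universe else tgt
            raise UniverseMismatchError(
                f"{path}:{lineno}: gene {bad!r} not in the gene universe"
            )
        if label == "1":
            positives.add((reg, tgt))
    return GoldStandard(universe=universe, positives=frozenset(positives))


def write_gold_standard(
    gold: GoldStandard, path, provenance: ProvenanceRecord | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_prov_line(provenance))
        for reg, tgt in sorted(gold.positives):
            fh.write(f"{reg}\t{tgt}\t1\n")


def read_tf_list(path) -> set[str]:
    return {line for _, line in _data_lines(Path(path))}


def write_tf_list(
    tfs, path, provenance: ProvenanceRecord | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_prov_line(provenance))
        for tf in sorted(tfs):
            fh.write(tf + "\n")


# ---------------------------------------------------------------------------
# networks and association matrices
# ---------------------------------------------------------------------------

_NETWORK_HEADER = ["gene_a", "gene_b", "score", "rank", "direction"]


def write_network(
    edges: EdgeList, path, provenance: ProvenanceRecord | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_prov_line(provenance))
        fh.write(
            "#directed\t{}\t#orientation_source\t{}\t#ranked_by_absolute\t{}\n".format(
                edges.directed, edges.orientation_source, edges.ranked_by_absolute
            )
        )
        fh.write("\t".join(_NETWORK_HEADER) + "\n")
        for e in edges.edges:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{format(e.score, '.17g')}\t"
                f"{e.rank}\t{e.direction}\n"
            )


def read_network(path) -> EdgeList:
    path = Path(path)
    directed, source, by_abs = False, "none", True
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.startswith("#directed"):
            parts = raw.split("\t")
            directed = parts[1] == "True"
            source = parts[3]
            by_abs = parts[5] == "True"
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts == _NETWORK_HEADER:
            continue
        if len(parts) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 fields")
        a, b, score, rank, direction = parts
        try:
            rows.append(Edge(a, b, float(score), int(rank), direction))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad score/rank") from None
    return EdgeList(
        edges=tuple(rows),
        directed=directed,
        orientation_source=source,
        ranked_by_absolute=by_abs,
    )


def write_association(
    assoc: AssociationMatrix, path, provenance: ProvenanceRecord | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_prov_line(provenance))
        meta = {
            "measure_id": assoc.measure_id,
            "params": assoc.params,
            "seed": assoc.seed,
            "n_skipped": assoc.n_skipped,
        }
        fh.write("#measure\t" + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("gene\t" + "\t".join(assoc.gene_ids) + "\n")
        for gid, row in zip(assoc.gene_ids, assoc.scores):
            fh.write(
                gid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n"
            )


def read_association(path) -> AssociationMatrix:
    path = Path(path)
    meta = {"measure_id": "unknown", "params": {}, "seed": None, "n_skipped": 0}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.startswith("#measure\t"):
            meta = json.loads(raw.split("\t", 1)[1])
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    ids = tuple(str(g) for g in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise FormatError(f"{path}: association matrix axes disagree")
    return AssociationMatrix(
        gene_ids=ids,
        scores=df.to_numpy(dtype=float),
        measure_id=meta["measure_id"],
        params=meta.get("params", {}),
        seed=meta.get("seed"),
        n_skipped=meta.get("n_skipped", 0),
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def write_metrics(
    metrics, path, provenance: ProvenanceRecord | None = None
) -> None:
    """Write a MetricSet (or a plain dict of metric rows) as flat JSON."""
    path = Path(path)
    payload = metrics.as_dict() if isinstance(metrics, MetricSet) else dict(metrics)
    doc = {
        "metrics": payload,
        "provenance": asdict(provenance or ProvenanceRecord()),
    }
    path.write_text(
        json.dumps(doc, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )


def read_metrics(path) -> dict:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if "metrics" not in doc:
        raise FormatError(f"{path}: missing 'metrics' key")
    return doc["metrics"]
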