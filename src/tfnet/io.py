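"""Readers and writers for every on-disk format the pipeline touches.

All tables are tab-separated UTF-8 with ``#`` comment lines ignored;
readers validate and reject malformed input (with row numbers) rather
than silently coercing, and every writer round-trips through its reader.
Promoters travel as FASTA via Biopython.  Gene identifiers are opaque
strings.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cis import MotifDef
from .config import PipelineConfig, SynthConfig, config_from_mapping
from .deg import DegCall, ExpressionMatrix
from .gonet import AnnotationTable
from .inventory import DomainHit, FamilyCall, GeneRecord
from .synteny import HomologSet

logger = logging.getLogger(__name__)


def _read_rows(path: str | Path, n_fields: int, min_fields: int | None = None):
    """Yield (line_number, fields) from a TSV, skipping comments/blanks."""
    min_fields = n_fields if min_fields is None else min_fields
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not (min_fields <= len(fields) <= n_fields):
                raise ValueError(
                    f"{path}:{lineno}: expected {min_fields}-{n_fields} "
                    f"tab-separated fields, got {len(fields)}"
                )
            yield lineno, fields


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path: str | Path,
    metadata_path: str | Path,
    control: str = "control",
) -> ExpressionMatrix:
    """Load an FPKM table (gene rows x sample columns) plus its sidecar.

    The sidecar maps sample -> condition, replicate.  Validation (shape,
    non-negative finite values, exactly one control condition) happens in
    :class:`~tfnet.deg.ExpressionMatrix`.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    if not {"condition", "replicate"} <= set(meta.columns):
        raise ValueError(
            f"{metadata_path}: need 'condition' and 'replicate' columns"
        )
    return ExpressionMatrix(values, meta, control)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path: str | Path, directed: bool = False
) -> tuple[nx.Graph, dict]:
    """Load a 2-3 column edge list (source, target[, weight]).

    Self-loops are dropped and counted; duplicate edges collapse keeping
    the maximum weight.  Returns ``(graph, report)`` with the drop
    counts.
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    self_loops = 0
    duplicates = 0
    for lineno, fields in _read_rows(path, 3, min_fields=2):
        src, dst = fields[0].strip(), fields[1].strip()
        if not src or not dst:
            raise ValueError(f"{path}:{lineno}: empty gene id")
        if len(fields) == 3:
            try:
                weight = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                ) from None
        else:
            weight = 1.0
        if src == dst:
            self_loops += 1
            continue
        if g.has_edge(src, dst):
            duplicates += 1
            g[src][dst]["weight"] = max(g[src][dst]["weight"], weight)
        else:
            g.add_edge(src, dst, weight=weight)
    report = {"self_loops_dropped": self_loops, "duplicates_collapsed": duplicates}
    if self_loops or duplicates:
        logger.info("edge list %s: %s", path, report)
    return g, report


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# source\ttarget\tweight\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):g}\n")


# ---------------------------------------------------------------------------
# inventory tables


def read_gene_records(path: str | Path) -> list[GeneRecord]:
    records = []
    for lineno, f in _read_rows(path, 7):
        if f[0] == "gene_id":  # header
            continue
        anchored = f[6].strip().lower() in {"1", "true", "yes"}
        records.append(
            GeneRecord(f[0], f[1], f[2], f[3], f[4], f[5], anchored)
        )
    return records


def write_gene_records(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tspecies\tfamily\tsubfamily\tchromosome\tsub_genome\tanchored\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.species}\t{r.family}\t{r.subfamily}\t"
                f"{r.chromosome}\t{r.sub_genome}\t{int(r.anchored)}\n"
            )


def read_domain_hits(path: str | Path) -> dict[str, list[DomainHit]]:
    """Domain-hit TSV -> hits grouped by gene."""
    hits: dict[str, list[DomainHit]] = {}
    for lineno, f in _read_rows(path, 6, min_fields=5):
        if f[0] == "gene_id":
            continue
        try:
            start, end = int(f[2]), int(f[3])
            e_value = float(f[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        variant = f[5] if len(f) == 6 else ""
        hits.setdefault(f[0], []).append(
            DomainHit(f[0], f[1], start, end, e_value, variant)
        )
    return hits


def write_domain_hits(
    hits: Mapping[str, Sequence[DomainHit]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tdomain_name\tstart\tend\te_value\tvariant\n")
        for gene in sorted(hits):
            for h in hits[gene]:
                fh.write(
                    f"{h.gene_id}\t{h.domain_name}\t{h.start}\t{h.end}\t"
                    f"{h.e_value:g}\t{h.variant}\n"
                )


def write_family_calls(calls: Iterable[FamilyCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tfamily\tsubfamily\trejection_reason\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.family}\t{c.subfamily}\t{c.rejection_reason}\n")


# ---------------------------------------------------------------------------
# FASTA promoters


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# motifs


def read_motif_table(path: str | Path) -> list[MotifDef]:
    motifs = []
    for lineno, f in _read_rows(path, 3, min_fields=2):
        if f[0] == "name":
            continue
        motifs.append(MotifDef(f[0], f[1], f[2] if len(f) == 3 else ""))
    return motifs


def write_motif_table(motifs: Iterable[MotifDef], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tconsensus\tassociated_response\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.consensus}\t{m.associated_response}\n")


# ---------------------------------------------------------------------------
# GO annotations (GAF-like: gene, term, namespace)


def read_go_table(
    path: str | Path,
    namespace: str = "BP",
    universe: Iterable[str] | None = None,
) -> AnnotationTable:
    terms: dict[str, set[str]] = {}
    for lineno, f in _read_rows(path, 3, min_fields=2):
        if f[0] == "gene_id":
            continue
        ns = f[2] if len(f) == 3 else "BP"
        if namespace and ns != namespace:
            continue
        terms.setdefault(f[0], set()).add(f[1])
    return AnnotationTable(terms, set(universe or ()))


def write_go_table(
    annotations: AnnotationTable, path: str | Path, namespace: str = "BP"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tterm\tnamespace\n")
        for gene in sorted(annotations.terms):
            for term in sorted(annotations.terms[gene]):
                fh.write(f"{gene}\t{term}\t{namespace}\n")


# ---------------------------------------------------------------------------
# homologous sets & homology maps


def read_homolog_sets(path: str | Path) -> list[HomologSet]:
    members: dict[str, list[tuple[str, str]]] = {}
    for lineno, f in _read_rows(path, 3):
        if f[0] == "set_id":
            continue
        members.setdefault(f[0], []).append((f[1], f[2]))
    return [
        HomologSet(set_id, tuple(mem)) for set_id, mem in sorted(members.items())
    ]


def write_homolog_sets(sets: Iterable[HomologSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\tspecies\tgene_id\n")
        for s in sets:
            for species, gene in s.members:
                fh.write(f"{s.set_id}\t{species}\t{gene}\n")


def read_homology_map(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for lineno, f in _read_rows(path, 2):
        if f[0] in {"gene_a", "source"}:
            continue
        pairs.append((f[0], f[1]))
    return pairs


def write_homology_map(
    pairs: Iterable[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# DEG calls


def write_deg_calls(calls: Iterable[DegCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\ttreatment\tprobability\tlog2fc\tdirection\tis_deg\tis_crucial\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.treatment}\t{c.probability:.6g}\t"
                f"{c.log2fc:.6g}\t{c.direction}\t{int(c.is_deg)}\t{int(c.is_crucial)}\n"
            )


def read_deg_calls(path: str | Path) -> list[DegCall]:
    calls = []
    for lineno, f in _read_rows(path, 7):
        if f[0] == "gene_id":
            continue
        try:
            calls.append(
                DegCall(
                    f[0], f[1], float(f[2]), float(f[3]),
                    bool(int(f[5])), bool(int(f[6])),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return calls


# ---------------------------------------------------------------------------
# config & results


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return config_from_mapping(PipelineConfig, _load_structured(path))


def load_synth_config(path: str | Path) -> SynthConfig:
    return config_from_mapping(SynthConfig, _load_structured(path))


def _load_structured(path: str | Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        return super().default(o)


def write_json(data, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_stringify_keys(data), fh, indent=2, sort_keys=True,
                  cls=_NumpyEncoder)
        fh.write("\n")


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, k))
             if isinstance(k, tuple) else str(k)): _stringify_keys(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj
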