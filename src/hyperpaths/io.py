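"""Reading and writing hypergraphs in the HGR-TSV dialect.

HGR-TSV is a plain UTF-8, tab-separated edge list.  Comment lines start
with ``#``; the conventional first line is ``# hgr v1``.  Each data line is

    edge_id<TAB>tail_csv<TAB>head_csv<TAB>weight

where *tail_csv* / *head_csv* are comma-separated vertex ids (no spaces)
and *weight* is a decimal >= 0.  Writing is deterministic: edges sorted by
id, set members sorted lexicographically, so write -> read -> write is
byte-identical.

Hyperpaths are serialized as JSON objects
``{"edges": [...ids in witness order...], "weight": w, "cyclic": bool}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .model import Hyperedge, Hypergraph, Hyperpath

__all__ = [
    "HgrParseError",
    "read_hypergraph",
    "write_hypergraph",
    "hyperpath_to_json",
    "hyperpath_from_json",
]

HEADER = "# hgr v1"


class HgrParseError(ValueError):
    """Malformed HGR-TSV input; message names the offending line number."""


def _parse_vertex_csv(text: str, line_no: int, what: str) -> frozenset:
    if text == "":
        raise HgrParseError(f"line {line_no}: empty {what}")
    parts = text.split(",")
    if any(p == "" for p in parts):
        raise HgrParseError(f"line {line_no}: empty vertex id in {what}")
    return frozenset(parts)


def read_hypergraph(path: Union[str, Path]) -> Hypergraph:
    """Read an HGR-TSV file into a Hypergraph.

    Raises HgrParseError (naming the line number) on malformed lines,
    duplicate edge ids, empty tail or head sets, or negative weights.
    """
    g = Hypergraph()
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise HgrParseError(
                    f"line {line_no}: expected 4 tab-separated fields, got {len(fields)}"
                )
            eid, tail_csv, head_csv, weight_txt = fields
            if not eid:
                raise HgrParseError(f"line {line_no}: empty edge id")
            tail = _parse_vertex_csv(tail_csv, line_no, "tail")
            head = _parse_vertex_csv(head_csv, line_no, "head")
            try:
                weight = float(weight_txt)
            except ValueError:
                raise HgrParseError(f"line {line_no}: bad weight {weight_txt!r}") from None
            if not (weight >= 0):
                raise HgrParseError(f"line {line_no}: negative weight {weight}")
            if g.has_edge(eid):
                raise HgrParseError(f"line {line_no}: duplicate edge id {eid!r}")
            g.add_edge(Hyperedge(id=eid, tail=tail, head=head, weight=weight))
    return g


def _format_weight(w: float) -> str:
    # integral weights print without a trailing ".0" so unit-weight files stay tidy
    if w == int(w):
        return str(int(w))
    return repr(w)


def write_hypergraph(g: Hypergraph, path: Union[str, Path]) -> None:
    """Write ``g`` as HGR-TSV with deterministic ordering."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(HEADER + "\n")
        for eid in sorted(g.edge_ids):
            e = g.edge(eid)
            fh.write(
                "\t".join(
                    (
                        e.id,
                        ",".join(sorted(e.tail)),
                        ",".join(sorted(e.head)),
                        _format_weight(e.weight),
                    )
                )
                + "\n"
            )


def hyperpath_to_json(p: Hyperpath) -> str:
    return json.dumps(
        {"edges": list(p.edges), "weight": p.weight, "cyclic": p.cyclic},
        sort_keys=True,
    )


def hyperpath_from_json(text: str) -> Hyperpath:
    obj = json.loads(text)
    return Hyperpath(
        edges=tuple(obj["edges"]), weight=float(obj["weight"]), cyclic=bool(obj["cyclic"])
    )
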