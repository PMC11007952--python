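"""Readers and writers for trees, traits, calibrations, and sequences.

Plain Newick and NEXUS parsing is delegated to dendropy; FASTA to Biopython.
The FigTree-style annotated chronogram dialect (bracketed per-node comments
carrying age and HPD bounds) is written and re-read by a small parser of our
own, since comment metadata does not survive a dendropy round trip intact.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import Calibration, CalibrationTable, TraitMatrix
from .tree import MY, SUBST, RootedTree, TreeError

__all__ = [
    "read_newick",
    "write_newick",
    "write_annotated_tree",
    "read_annotated_tree",
    "read_traits",
    "write_traits",
    "read_calibrations",
    "write_calibrations",
    "parse_age_spec",
    "resolve_mrca",
    "resolve_calibrations",
    "read_fasta",
    "write_fasta",
]


# ----------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------
def _from_dendropy(dtree: dendropy.Tree, length_kind: str) -> RootedTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, children, labels, lengths = [], [], [], []
    for nd in nodes:
        parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
        children.append([index[id(c)] for c in nd.child_nodes()])
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise TreeError("unlabelled tip in input tree")
            labels.append(label)
        else:
            labels.append(None)
        lengths.append(nd.edge.length if nd.edge.length is not None else 0.0)
    return RootedTree(
        parent=parent,
        children=children,
        labels=labels,
        lengths=np.array(lengths, dtype=float),
        length_kind=length_kind,
    )


def read_newick(
    text: str | Path,
    length_kind: str = SUBST,
    allow_polytomy: bool = False,
) -> RootedTree:
    """Parse a rooted Newick tree.

    ``text`` may be a Newick string or a path to a file containing one.
    Basal (and internal) polytomies are rejected unless ``allow_polytomy``;
    collapsed gene trees may legitimately contain them.
    """
    if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text and text.strip().endswith((".nwk", ".tre", ".newick", ".tree"))):
        text = Path(text).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    tree = _from_dendropy(dtree, length_kind)
    if not allow_polytomy and tree.has_polytomy():
        raise TreeError("tree contains a polytomy (pass allow_polytomy=True to accept)")
    return tree


def _newick_body(tree: RootedTree, v: int, annotations=None, fmt="%.12g") -> str:
    note = ""
    if annotations and v in annotations:
        items = ",".join(f"{k}={fmt % val}" for k, val in annotations[v].items())
        note = f"[&{items}]"
    if tree.is_tip(v):
        core = tree.labels[v]
    else:
        core = "(" + ",".join(
            _newick_body(tree, c, annotations, fmt) for c in tree.children[v]
        ) + ")"
    length = "" if tree.parent[v] == -1 else (":" + fmt % tree.lengths[v])
    return core + note + length


def write_newick(tree: RootedTree, path: Path | None = None) -> str:
    """Serialize to a Newick string (optionally writing ``path``)."""
    text = _newick_body(tree, tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_annotated_tree(
    tree: RootedTree,
    node_annotations: Mapping[int, Mapping[str, float]],
    path: Path | None = None,
    tree_name: str = "chronogram",
) -> str:
    """Write a NEXUS/FigTree-dialect tree with bracketed per-node comments.

    ``node_annotations`` maps node id -> {key: numeric value}; typical keys
    are ``age``, ``hpd_low``, ``hpd_high``.
    """
    for v in node_annotations:
        if not 0 <= v < tree.n_nodes:
            raise TreeError(f"annotation for unknown node id {v}")
    body = _newick_body(tree, tree.root, annotations=dict(node_annotations))
    text = (
        "#NEXUS\nbegin trees;\n"
        f"tree {tree_name} = [&R] {body};\n"
        "end;\n"
    )
    if path is not None:
        Path(path).write_text(text)
    return text


_TOKEN = re.compile(r"\(|\)|,|;|\[&[^\]]*\]|:[^,()\[\];]+|[^,()\[\]:;]+")


def read_annotated_tree(
    text: str | Path, length_kind: str = MY
) -> tuple[RootedTree, dict[int, dict[str, float]]]:
    """Re-read a tree written by :func:`write_annotated_tree`."""
    if isinstance(text, Path):
        text = Path(text).read_text()
    m = re.search(r"=\s*(\[&R\]\s*)?(\(.*;)", text, re.S)
    newick = m.group(2) if m else text
    tokens = _TOKEN.findall(newick.strip())

    parent: list[int] = []
    children: list[list[int]] = []
    labels: list[str | None] = []
    lengths: list[float] = []
    annotations: dict[int, dict[str, float]] = {}

    def new_node(p: int) -> int:
        parent.append(p)
        children.append([])
        labels.append(None)
        lengths.append(0.0)
        if p >= 0:
            children[p].append(len(parent) - 1)
        return len(parent) - 1

    cur = -1
    last = -1
    for tok in tokens:
        if tok == "(":
            cur = new_node(cur)
            last = cur
        elif tok == ",":
            last = -2  # next bare token starts a sibling tip
        elif tok == ")":
            last = cur
            cur = parent[cur]
        elif tok == ";":
            break
        elif tok.startswith("[&"):
            pairs = tok[2:-1].split(",")
            annotations[last] = {
                k: float(v) for k, v in (p.split("=", 1) for p in pairs)
            }
        elif tok.startswith(":"):
            lengths[last] = float(tok[1:])
        else:
            last = new_node(cur)
            labels[last] = tok.strip()

    tree = RootedTree(
        parent=parent,
        children=children,
        labels=labels,
        lengths=np.array(lengths),
        length_kind=length_kind,
    )
    return tree, annotations


# ----------------------------------------------------------------------
# Traits
# ----------------------------------------------------------------------
def read_traits(
    path: Path | str,
    states_path: Path | str | None = None,
) -> TraitMatrix:
    """Read a discrete trait matrix.

    TSV/CSV: header row of character names, first column taxon names.
    NEXUS (``.nex``/``.nexus``): a standard characters block, read-only.
    ``states_path`` optionally declares state spaces, one line per
    character: ``name<TAB>state1,state2,...``.
    """
    path = Path(path)
    if path.suffix.lower() in (".nex", ".nexus"):
        cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        rows = {}
        for taxon in cm.taxon_namespace:
            rows[taxon.label] = [str(c.symbol) for c in cm[taxon]]
        ncol = len(next(iter(rows.values())))
        data = pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"char{i+1}" for i in range(ncol)]
        )
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        data = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        if data.isna().any().any():
            raise ValueError(f"{path}: ragged or empty cells in trait matrix")
    state_spaces = {}
    if states_path is not None:
        for line in Path(states_path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, states = line.split("\t")
            state_spaces[name] = states.strip().split(",")
    return TraitMatrix(data=data, state_spaces=state_spaces)


def write_traits(tm: TraitMatrix, path: Path | str) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    tm.data.to_csv(path, sep=sep, index_label="taxon")


# ----------------------------------------------------------------------
# Calibrations
# ----------------------------------------------------------------------
_PLUS_MINUS = re.compile(r"^(\d+(?:\.\d+)?)\s*\+(\d+(?:\.\d+)?)/-(\d+(?:\.\d+)?)$")
_SYMMETRIC = re.compile(r"^(\d+(?:\.\d+)?)\s*\+/-\s*(\d+(?:\.\d+)?)$")
_MIN_ONLY = re.compile(r"^MIN:\s*(\d+(?:\.\d+)?)$", re.I)
_RANGE = re.compile(r"^(\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)$")


def parse_age_spec(spec: str) -> tuple[float | None, float | None]:
    """Parse a fossil age specification into (min_age, max_age) in My.

    Conventions: ``"1047 +13/-17"`` -> (1030, 1060); ``"609 +/-5"`` ->
    (604, 614); ``"MIN: 350"`` -> (350, None); ``"1056-948"`` -> (948, 1056)
    (ranges are printed older bound first).
    """
    spec = spec.strip()
    if m := _PLUS_MINUS.match(spec):
        x, a, b = (float(g) for g in m.groups())
        return x - b, x + a
    if m := _SYMMETRIC.match(spec):
        x, a = (float(g) for g in m.groups())
        return x - a, x + a
    if m := _MIN_ONLY.match(spec):
        return float(m.group(1)), None
    if m := _RANGE.match(spec):
        older, younger = (float(g) for g in m.groups())
        if older <= younger:
            raise ValueError(f"age range {spec!r}: expected older bound first")
        return younger, older
    raise ValueError(f"malformed age spec {spec!r}")


def read_calibrations(path: Path | str) -> CalibrationTable:
    """Read a calibration TSV: name, tip_a, tip_b, age_spec[, tail_low, tail_high].

    Default tail masses follow the soft-bound convention: 2.5% per side for
    two-sided calibrations, 5% below a pure minimum.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    rows = []
    for _, r in df.iterrows():
        min_age, max_age = parse_age_spec(r["age_spec"])
        if max_age is None:
            tail_low, tail_high = 0.05, 0.0
        else:
            tail_low = tail_high = 0.025
        if "tail_low" in df.columns and not pd.isna(r.get("tail_low")):
            tail_low = float(r["tail_low"])
        if "tail_high" in df.columns and not pd.isna(r.get("tail_high")):
            tail_high = float(r["tail_high"])
        rows.append(
            Calibration(
                name=r["name"], tip_a=r["tip_a"], tip_b=r["tip_b"],
                min_age=min_age, max_age=max_age,
                tail_low=tail_low, tail_high=tail_high,
            )
        )
    return CalibrationTable(rows)


def write_calibrations(table: CalibrationTable, path: Path | str) -> None:
    lines = ["name\ttip_a\ttip_b\tage_spec\ttail_low\ttail_high"]
    for r in table:
        if r.max_age is None:
            spec = f"MIN: {r.min_age:g}"
        else:
            spec = f"{r.max_age:g}-{r.min_age:g}"
        lines.append(
            f"{r.name}\t{r.tip_a}\t{r.tip_b}\t{spec}\t{r.tail_low:g}\t{r.tail_high:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def resolve_mrca(tree: RootedTree, row: Calibration) -> int:
    """Node id of the MRCA of the calibration's two anchor tips."""
    return tree.mrca(row.tip_a, row.tip_b)


def resolve_calibrations(
    tree: RootedTree, table: CalibrationTable
) -> dict[int, Calibration]:
    """Map node id -> calibration; duplicate node assignments are an error."""
    out: dict[int, Calibration] = {}
    for row in table:
        node = resolve_mrca(tree, row)
        if node in out:
            raise ValueError(
                f"calibrations {out[node].name!r} and {row.name!r} resolve to the same node"
            )
        out[node] = row
    return out


# ----------------------------------------------------------------------
# Sequences
# ----------------------------------------------------------------------
def read_fasta(path: Path | str, rna_to_dna: bool = False) -> dict[str, str]:
    """Ordered map of name -> sequence. Case is preserved.

    ``rna_to_dna`` maps U/u to T/t on read (ITS-2 records are sometimes
    deposited as RNA).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        if rna_to_dna:
            seq = seq.replace("U", "T").replace("u", "t")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path: Path | str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
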