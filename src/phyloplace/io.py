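"""Reading and writing jplace files and per-sample metadata tables.

jplace is the de-facto standard interchange format for phylogenetic
placement results (EPA, EPA-ng, pplacer).  It is a JSON document with a
``tree`` (edge-numbered Newick), a ``fields`` list naming the columns of
each placement record, and a ``placements`` list of placed queries
("pqueries").  Versions 1-3 differ in details that this reader absorbs:
field columns are mapped by name rather than position, pquery names may
appear under ``"n"`` (plain names) or ``"nm"`` (name/multiplicity
pairs), and positions may be given as ``proximal_length`` or
``distal_length``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import ReferenceTree

__all__ = [
    "Placement",
    "Pquery",
    "Sample",
    "JplaceFormatError",
    "read_jplace",
    "write_jplace",
    "likelihoods_to_lwr",
    "read_metadata",
]

LWR_SUM_TOLERANCE = 1e-6


class JplaceFormatError(ValueError):
    """Raised when a jplace document is missing mandatory structure."""


@dataclass
class Placement:
    """One candidate position of a query on a reference-tree edge.

    ``like_weight_ratio`` (LWR) is the per-branch placement probability;
    ``proximal_length`` is the distance of the mass point from the edge's
    root-side node.  ``pendant_length`` is carried through for round
    trips but plays no role in any mass computation.
    """

    edge_num: int
    like_weight_ratio: float
    proximal_length: float = 0.0
    pendant_length: float = 0.0


@dataclass
class Pquery:
    names: list[str]
    placements: list[Placement]
    multiplicity: float = 1.0

    def lwr_sum(self) -> float:
        return sum(p.like_weight_ratio for p in self.placements)


@dataclass
class Sample:
    """A named collection of placed queries on a shared reference tree."""

    name: str
    tree: ReferenceTree
    pqueries: list[Pquery] = field(default_factory=list)

    def total_multiplicity(self) -> float:
        return sum(q.multiplicity for q in self.pqueries)

    def validate(self) -> None:
        for q in self.pqueries:
            if not q.placements:
                raise JplaceFormatError(f"pquery {q.names} has no placements")
            if q.multiplicity <= 0:
                raise JplaceFormatError(f"pquery {q.names} has non-positive multiplicity")
            s = q.lwr_sum()
            if s > 1.0 + LWR_SUM_TOLERANCE:
                raise JplaceFormatError(
                    f"pquery {q.names} has LWR sum {s} > 1"
                )
            for p in q.placements:
                if not self.tree.has_edge(p.edge_num):
                    raise JplaceFormatError(
                        f"placement references edge {p.edge_num} absent from tree"
                    )


def likelihoods_to_lwr(log_likelihoods) -> np.ndarray:
    """Convert per-branch log-likelihood scores into likelihood weight ratios.

    The scores for a single query are turned into probabilities with a
    numerically stable softmax, ``LWR_i = exp(l_i - max l) / sum_j
    exp(l_j - max l)``; the ratios sum to one over all branches.
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.size == 0:
        raise ValueError("need at least one log-likelihood value")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihoods must be finite")
    w = np.exp(ll - ll.max())
    return w / w.sum()


def read_jplace(path, name: str | None = None) -> Sample:
    """Read a jplace file (versions 1-3) into a :class:`Sample`."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("tree", "fields", "placements"):
        if key not in doc:
            raise JplaceFormatError(f"jplace document is missing mandatory field '{key}'")
    version = doc.get("version")
    if version is None:
        raise JplaceFormatError("jplace document is missing mandatory field 'version'")
    try:
        v = int(version)
    except (TypeError, ValueError):
        v = -1
    if v not in (1, 2, 3):
        warnings.warn(f"unknown jplace version {version!r}; attempting best-effort parse")

    tree = ReferenceTree.from_newick(doc["tree"])
    fields: list[str] = list(doc["fields"])
    col = {f: i for i, f in enumerate(fields)}
    if "edge_num" in col:
        edge_col = col["edge_num"]
    elif "edge_number" in col:
        edge_col = col["edge_number"]
    else:
        raise JplaceFormatError("jplace 'fields' lacks an edge_num column")

    has_lwr = "like_weight_ratio" in col
    if not has_lwr and "likelihood" not in col:
        raise JplaceFormatError(
            "jplace 'fields' lacks both like_weight_ratio and likelihood"
        )

    branch_lengths = {
        int(e): tree.branch_lengths[tree.edge_column(int(e))] for e in tree.edge_order
    }

    pqueries: list[Pquery] = []
    for entry in doc["placements"]:
        rows = entry["p"]
        if "nm" in entry:
            names = [str(nm[0]) for nm in entry["nm"]]
            multiplicity = float(sum(nm[1] for nm in entry["nm"]))
        elif "n" in entry:
            names = [str(n) for n in entry["n"]]
            multiplicity = 1.0
        else:
            raise JplaceFormatError("placement entry lacks both 'n' and 'nm' names")

        edge_nums = [int(r[edge_col]) for r in rows]
        for e in edge_nums:
            if e not in branch_lengths:
                raise JplaceFormatError(
                    f"placement of {names} references edge {e} absent from tree"
                )
        if has_lwr:
            lwrs = [float(r[col["like_weight_ratio"]]) for r in rows]
        else:
            lwrs = list(likelihoods_to_lwr([float(r[col["likelihood"]]) for r in rows]))

        placements = []
        for r, e, lwr in zip(rows, edge_nums, lwrs):
            blen = branch_lengths[e]
            if "proximal_length" in col:
                prox = float(r[col["proximal_length"]])
            elif "distal_length" in col:
                prox = blen - float(r[col["distal_length"]])
            else:
                prox = blen / 2.0
            if prox < 0.0 or prox > blen:
                warnings.warn(
                    f"placement position {prox} outside [0, {blen}] on edge {e}; clamped"
                )
                prox = min(max(prox, 0.0), blen)
            pend = float(r[col["pendant_length"]]) if "pendant_length" in col else 0.0
            placements.append(Placement(e, lwr, prox, pend))
        pqueries.append(Pquery(names=names, placements=placements, multiplicity=multiplicity))

    sample = Sample(name=name or path.stem, tree=tree, pqueries=pqueries)
    sample.validate()
    return sample


def write_jplace(sample: Sample, path) -> None:
    """Write a :class:`Sample` as jplace v3 with ``{N}`` edge numbers."""
    fields = ["edge_num", "likelihood", "like_weight_ratio", "proximal_length", "pendant_length"]
    placements = []
    for q in sample.pqueries:
        placements.append(
            {
                "p": [
                    [p.edge_num, 0.0, p.like_weight_ratio, p.proximal_length, p.pendant_length]
                    for p in q.placements
                ],
                "nm": [[q.names[0], q.multiplicity]]
                + [[n, 0] for n in q.names[1:]],
            }
        )
    doc = {
        "version": 3,
        "tree": sample.tree.to_newick(),
        "fields": fields,
        "placements": placements,
        "metadata": {"invocation": "phyloplace"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(
    path,
    sample_names: list[str],
    key_column: str | int = 0,
    sep: str | None = None,
    missing: str = "error",
) -> pd.DataFrame:
    """Read a CSV/TSV metadata table and align its rows to the sample order.

    Parameters
    ----------
    sample_names : order the returned rows must follow.
    key_column : name or position of the column holding sample names.
    sep : delimiter; sniffed from the file extension when ``None``.
    missing : ``"error"`` to fail on samples absent from the table, or
        ``"drop"`` to drop them with a warning (the returned frame then
        covers the intersection, in sample order).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if isinstance(key_column, int):
        key_column = df.columns[key_column]
    if key_column not in df.columns:
        raise KeyError(f"key column {key_column!r} not in metadata table")
    df = df.set_index(key_column)
    df.index = df.index.astype(str)
    absent = [s for s in sample_names if s not in df.index]
    if absent:
        if missing == "error":
            raise KeyError(f"samples missing from metadata table: {absent}")
        warnings.warn(f"dropping samples missing from metadata table: {absent}")
        sample_names = [s for s in sample_names if s not in absent]
    out = df.loc[sample_names]
    # columns that parse fully as numbers become floats; the rest stay categorical
    for c in out.columns:
        if out[c].dtype == object:
            coerced = pd.to_numeric(out[c], errors="coerce")
            if coerced.notna().sum() == out[c].notna().sum():
                out[c] = coerced
    return out
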