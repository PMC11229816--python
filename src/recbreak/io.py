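"""Readers and writers for the pipeline's file formats.

Alignments are FASTA (via Biopython); local trees are Newick with a
tab-separated sidecar interval table (start, end, tree_index; 0-based
half-open boundary coordinates); events and detections are tab-separated
tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

from recbreak.simulate import ARG, Alignment, BASES, LocalTree

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_events",
    "read_events",
    "write_local_trees",
    "read_local_trees",
    "write_detections",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=sid, description="")
        for i, sid in enumerate(aln.ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Alignment:
    """Read an ACGT alignment; other characters are rejected."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            rows.append([_BASE_INDEX[c] for c in seq])
        except KeyError as exc:
            raise ValueError(f"non-ACGT character in {rec.id}: {exc}") from exc
        ids.append(rec.id)
    if not rows:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    return Alignment(ids, np.array(rows, dtype=np.int8))


def write_events(arg: ARG, path) -> None:
    pd.DataFrame(
        {
            "breakpoint": [e.breakpoint for e in arg.events],
            "time": [e.time for e in arg.events],
            "type": [e.event_type for e in arg.events],
            "child_samples": [
                ",".join(f"s{s}" for s in sorted(e.child_samples)) for e in arg.events
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_local_trees(arg: ARG, newick_path, intervals_path) -> None:
    with open(newick_path, "w") as fh:
        for tree in arg.local_trees:
            fh.write(tree.newick() + "\n")
    pd.DataFrame(
        {
            "start": [t.start for t in arg.local_trees],
            "end": [t.end for t in arg.local_trees],
            "tree_index": range(len(arg.local_trees)),
        }
    ).to_csv(intervals_path, sep="\t", index=False)


def _localtree_from_dendropy(tree: dendropy.Tree, start: int, end: int) -> LocalTree:
    """Convert a rooted ultrametric dendropy tree to a LocalTree."""
    leaves = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if not label.startswith("s"):
            raise ValueError(f"leaf labels must be s<index>, got {label!r}")
        leaves[leaf] = int(label[1:])
    n = len(leaves)
    next_id = n
    ids, parent, times = {}, {}, {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ids[node] = leaves[node]
            times[ids[node]] = 0.0
        else:
            ids[node] = next_id
            next_id += 1
            child = node.child_nodes()[0]
            times[ids[node]] = times[ids[child]] + (child.edge.length or 0.0)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent[ids[node]] = ids[node.parent_node]
    return LocalTree(start, end, parent, times, n)


def read_local_trees(newick_path, intervals_path):
    """Read true local trees (one Newick per line) with their interval table."""
    intervals = pd.read_csv(intervals_path, sep="\t")
    with open(newick_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != len(intervals):
        raise ValueError("interval table does not match the number of trees")
    trees = []
    for (_, row), nwk in zip(intervals.iterrows(), lines):
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        trees.append(_localtree_from_dendropy(dt, int(row["start"]), int(row["end"])))
    return trees


def write_detections(events, path, ids=None) -> None:
    """Per-event TSV: method, sequences, roles, statistic, p-value, interval, point."""

    def name(i):
        return ids[i] if ids is not None else f"s{i}"

    rows = []
    for ev in events:
        rows.append(
            {
                "method": ev.method,
                "sequences": ",".join(name(s) for s in ev.sequences),
                "roles": (
                    ";".join(f"{k}={name(v)}" for k, v in ev.roles.items())
                    if ev.roles
                    else ""
                ),
                "statistic": ev.statistic,
                "p_value": "" if ev.pvalue is None else ev.pvalue,
                "interval_start": ev.interval[0],
                "interval_end": ev.interval[1],
                "point_estimate": ev.point,
                "extra_intervals": ";".join(f"{a}-{b}" for a, b in ev.extra_intervals),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "method", "sequences", "roles", "statistic", "p_value",
            "interval_start", "interval_end", "point_estimate", "extra_intervals",
        ],
    ).to_csv(path, sep="\t", index=False)
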