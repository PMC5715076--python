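"""Plain-text serialisation of trees, snapshots and run logs.

Segment tables are CSV with one row per segment; Python's shortest-repr float
formatting makes the round trip exact for both topology (integers) and
geometry (floats).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .architecture import Tree
from .genome import Genome
from .params import SimulationParams

SEGMENT_COLUMNS = [
    "id", "parent", "tx", "ty", "tz", "bx", "by", "bz",
    "x", "y", "z", "d", "year", "strength", "light",
]


def segment_table(tree: Tree) -> pd.DataFrame:
    """One row per segment: topology, frame, base position, state."""
    n = tree.n
    t = tree.col("t")
    b = tree.col("b")
    base = tree.col("base")
    return pd.DataFrame({
        "id": np.arange(n),
        "parent": tree.col("parent").astype(np.int64),
        "tx": t[:, 0], "ty": t[:, 1], "tz": t[:, 2],
        "bx": b[:, 0], "by": b[:, 1], "bz": b[:, 2],
        "x": base[:, 0], "y": base[:, 1], "z": base[:, 2],
        "d": tree.col("d"),
        "year": tree.col("year").astype(np.int64),
        "strength": tree.col("strength"),
        "light": tree.col("light"),
    })


def tree_from_table(
    df: pd.DataFrame,
    params: SimulationParams,
    genome: Genome,
    position: tuple[float, float] = (0.0, 0.0),
    **tree_kwargs,
) -> Tree:
    """Rebuild a tree from its segment table (inverse of segment_table)."""
    rng = np.random.default_rng(0)  # trunk frame is overwritten below
    tree = Tree(params, genome, position, rng, **tree_kwargs)
    n = len(df)
    tree._ensure(n - tree.n)
    tree.n = n
    tree.parent[:n] = df["parent"].to_numpy(np.int32)
    tree.t[:n] = df[["tx", "ty", "tz"]].to_numpy(float)
    tree.b[:n] = df[["bx", "by", "bz"]].to_numpy(float)
    tree.base[:n] = df[["x", "y", "z"]].to_numpy(float)
    tree.d[:n] = df["d"].to_numpy(float)
    tree.year[:n] = df["year"].to_numpy(np.int32)
    tree.strength[:n] = df["strength"].to_numpy(float)
    if "light" in df:
        tree.light[:n] = df["light"].to_numpy(float)
    parent = tree.parent[:n]
    counts = np.bincount(parent[parent >= 0], minlength=n)
    tree.nchild[:n] = counts.astype(np.int8)
    depth = np.zeros(n, dtype=np.int32)
    for i in range(1, n):
        depth[i] = depth[parent[i]] + 1
    tree.depth[:n] = depth
    tree.position = (float(tree.base[0, 0]), float(tree.base[0, 1]))
    return tree


def write_segment_table(tree: Tree, path) -> None:
    segment_table(tree).to_csv(path, index=False)


def read_segment_table(path) -> pd.DataFrame:
    # round_trip parsing keeps shortest-repr floats bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def write_snapshot(forest, out_dir, tag: str = "snapshot") -> str:
    """Write ``trees.csv`` and ``segments.csv`` under ``out_dir/tag/``."""
    snap_dir = os.path.join(str(out_dir), tag)
    os.makedirs(snap_dir, exist_ok=True)
    tree_rows = []
    seg_frames = []
    for tree in forest.trees:
        tree_rows.append({
            "tree_id": tree.id,
            "lineage_id": tree.lineage_id,
            "x": tree.position[0],
            "y": tree.position[1],
            "birth_year": tree.birth_year,
            "reserve": tree.reserve,
            "genome": ";".join(repr(float(v)) for v in tree.genome.genes),
        })
        df = segment_table(tree)
        df.insert(0, "tree_id", tree.id)
        seg_frames.append(df)
    pd.DataFrame(tree_rows).to_csv(os.path.join(snap_dir, "trees.csv"),
                                   index=False)
    if seg_frames:
        pd.concat(seg_frames, ignore_index=True).to_csv(
            os.path.join(snap_dir, "segments.csv"), index=False)
    else:
        pd.DataFrame(columns=["tree_id"] + SEGMENT_COLUMNS).to_csv(
            os.path.join(snap_dir, "segments.csv"), index=False)
    return snap_dir


def read_snapshot(snap_dir, params: SimulationParams) -> list[Tree]:
    trees_df = pd.read_csv(os.path.join(str(snap_dir), "trees.csv"),
                           float_precision="round_trip")
    segs_df = pd.read_csv(os.path.join(str(snap_dir), "segments.csv"),
                          float_precision="round_trip")
    trees = []
    for _, row in trees_df.iterrows():
        genome = Genome(np.array([float(v)
                                  for v in str(row["genome"]).split(";")]))
        sub = segs_df[segs_df["tree_id"] == row["tree_id"]]
        tree = tree_from_table(
            sub.reset_index(drop=True), params, genome,
            position=(row["x"], row["y"]),
            tree_id=int(row["tree_id"]),
            lineage_id=int(row["lineage_id"]),
            birth_year=int(row["birth_year"]),
        )
        tree.reserve = float(row["reserve"])
        trees.append(tree)
    return trees


def write_run_logs(forest, out_dir) -> None:
    os.makedirs(str(out_dir), exist_ok=True)
    forest.summary().to_csv(os.path.join(str(out_dir), "summary.csv"),
                            index=False)
    forest.storms().to_csv(os.path.join(str(out_dir), "storms.csv"),
                           index=False)
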