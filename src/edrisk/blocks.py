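"""ICD-10 block mapping, cumulative-coverage reduction and dominant blocks.

A block is a contiguous range of 3-character ICD-10 code prefixes (e.g.
J09-J18, "Influenza and pneumonia"). Codes map to blocks by their first
three characters. Ranking blocks by presentation frequency and truncating at
a cumulative-coverage threshold (60-100%) reduces several hundred codes to a
shortlist of category groups; a block is *dominant* in a cluster when at
least 75% (configurable) of its presentations fall in that cluster, which is
what makes a block actionable as a single care-pathway category.

A rendering of the WHO block table ships with the package
(``data/icd10_blocks.csv``); callers may substitute their own table.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "BlockDefinition",
    "CoverageCurve",
    "parse_block_table",
    "expand_block_range",
    "code_to_block",
    "assign_blocks",
    "summarize_blocks",
    "cumulative_coverage",
    "dominant_blocks",
    "heatmap_matrix",
]

_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})-([A-Z])([0-9]{2})$")


def _prefix_ord(letter: str, digits: str | int) -> int:
    return (ord(letter) - ord("A")) * 100 + int(digits)


@dataclass(frozen=True)
class BlockDefinition:
    """One WHO block: an inclusive range of 3-character prefixes."""

    block_id: str
    title: str
    chapter: str

    @property
    def start_ord(self) -> int:
        m = _RANGE_RE.match(self.block_id)
        return _prefix_ord(m.group(1), m.group(2))

    @property
    def end_ord(self) -> int:
        m = _RANGE_RE.match(self.block_id)
        return _prefix_ord(m.group(3), m.group(4))


def expand_block_range(block_id: str) -> list[str]:
    """All 3-character prefixes inside a block range, in order."""
    m = _RANGE_RE.match(block_id)
    if m is None:
        raise ValueError(f"malformed block range {block_id!r}")
    out = []
    for o in range(_prefix_ord(m.group(1), m.group(2)),
                   _prefix_ord(m.group(3), m.group(4)) + 1):
        out.append(f"{chr(ord('A') + o // 100)}{o % 100:02d}")
    return out


def parse_block_table(path=None) -> list[BlockDefinition]:
    """Read and validate a block-definition table (block_id, title, chapter).

    Defaults to the packaged WHO table. Ranges must be well-formed,
    start <= end, and mutually non-overlapping; violations raise a parse
    error naming the offending line. Returned sorted by range start.
    """
    if path is None:
        with resources.files("edrisk.data").joinpath("icd10_blocks.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"block_id", "title", "chapter"}
    if not required.issubset(df.columns):
        raise ValueError(f"block table needs columns {sorted(required)}")
    blocks = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        m = _RANGE_RE.match(str(row.block_id).strip())
        if m is None:
            raise ValueError(f"line {line}: malformed block range {row.block_id!r}")
        b = BlockDefinition(str(row.block_id).strip(), str(row.title), str(row.chapter))
        if b.start_ord > b.end_ord:
            raise ValueError(f"line {line}: block range {b.block_id} has start > end")
        blocks.append(b)
    blocks.sort(key=lambda b: b.start_ord)
    for prev, cur in zip(blocks, blocks[1:]):
        if cur.start_ord <= prev.end_ord:
            raise ValueError(
                f"overlapping block ranges {prev.block_id} and {cur.block_id}"
            )
    return blocks


def code_to_block(code: str, blocks: list[BlockDefinition]) -> str | None:
    """Block containing the code's 3-character prefix, or None if unmapped."""
    prefix = code.strip().upper()[:3]
    if not re.match(r"^[A-Z][0-9]{2}$", prefix):
        return None
    o = _prefix_ord(prefix[0], prefix[1:])
    starts = [b.start_ord for b in blocks]
    i = bisect_right(starts, o) - 1
    if i >= 0 and blocks[i].end_ord >= o:
        return blocks[i].block_id
    return None


def assign_blocks(records: pd.DataFrame, blocks: list[BlockDefinition],
                  policy: str = "strict") -> pd.DataFrame:
    """Add a ``block`` column to presentation records.

    ``policy='strict'`` raises on any unmapped code, listing the offenders;
    ``policy='unmapped'`` collects them into an ``UNMAPPED`` pseudo-block.
    """
    if policy not in ("strict", "unmapped"):
        raise ValueError(f"unknown unmapped-code policy {policy!r}")
    mapping = {code: code_to_block(code, blocks) for code in records["icd10"].unique()}
    missing = sorted(c for c, b in mapping.items() if b is None)
    if missing and policy == "strict":
        raise ValueError(f"codes not covered by the block table: {missing}")
    out = records.copy()
    out["block"] = records["icd10"].map(lambda c: mapping[c] or "UNMAPPED")
    return out


def summarize_blocks(records: pd.DataFrame, blocks: list[BlockDefinition] | None = None,
                     policy: str = "strict") -> pd.DataFrame:
    """Per-block presentation counts split by cluster, with the dominant cluster.

    Expects clustered records (``cluster`` column); maps codes to blocks if a
    ``block`` column is not already present. Proportions within each block
    sum to 1; the dominant cluster is the argmax proportion (ties resolve to
    the lower label).
    """
    df = records
    if "block" not in df.columns:
        df = assign_blocks(df, blocks if blocks is not None else parse_block_table(),
                           policy=policy)
    labels = sorted(df["cluster"].unique())
    counts = (df.pivot_table(index="block", columns="cluster", values="id",
                             aggfunc="count", fill_value=0)
              .reindex(columns=labels, fill_value=0))
    n = counts.sum(axis=1)
    props = counts.div(n, axis=0)
    # idxmax scans columns in order; with ascending labels ties go to the lower
    dominant = props.idxmax(axis=1)
    out = pd.DataFrame({
        "block_id": counts.index,
        "n_presentations": n.to_numpy(),
        "dominant_cluster": dominant.to_numpy(),
        "dominant_proportion": props.max(axis=1).to_numpy(),
    }).reset_index(drop=True)
    for lab in labels:
        out[f"n_cluster_{lab}"] = counts[lab].to_numpy()
        out[f"prop_cluster_{lab}"] = props[lab].to_numpy()
    return out.sort_values("block_id", ignore_index=True)


@dataclass
class CoverageCurve:
    """Frequency-ranked blocks and the cumulative share of presentations."""

    ranked_blocks: list[str]
    cumulative_share: np.ndarray
    blocks_at_threshold: dict[float, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.ranked_blocks) + 1),
            "block_id": self.ranked_blocks,
            "cumulative_share": self.cumulative_share,
        })


def cumulative_coverage(block_summaries: pd.DataFrame,
                        thresholds=(0.6, 0.7, 0.8, 0.9, 1.0)) -> CoverageCurve:
    """Rank blocks by frequency and find how many cover each threshold.

    Blocks are sorted by presentation count descending (ties alphabetical);
    ``blocks_at_threshold[t]`` is the smallest number of top blocks whose
    cumulative presentation share reaches at least ``t``.
    """
    thresholds = list(thresholds)
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    ranked = block_summaries.sort_values(
        ["n_presentations", "block_id"], ascending=[False, True], ignore_index=True
    )
    total = ranked["n_presentations"].sum()
    share = np.cumsum(ranked["n_presentations"].to_numpy()) / total
    at = {
        float(t): int(np.searchsorted(share, t - 1e-12) + 1)
        for t in thresholds
    }
    return CoverageCurve(
        ranked_blocks=ranked["block_id"].tolist(),
        cumulative_share=share,
        blocks_at_threshold=at,
    )


def dominant_blocks(block_summaries: pd.DataFrame,
                    min_representation: float = 0.75,
                    cluster: int | None = None,
                    registry_total: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Blocks with >= ``min_representation`` of presentations in one cluster.

    Optionally restricted to a given dominant cluster. The companion summary
    reports the presentations those blocks account for and their share of
    the registry (to 1 decimal, as a percentage).
    """
    if not (0.0 < min_representation <= 1.0):
        raise ValueError("min_representation must lie in (0, 1]")
    sel = block_summaries[block_summaries["dominant_proportion"] >= min_representation]
    if cluster is not None:
        sel = sel[sel["dominant_cluster"] == cluster]
    total = registry_total if registry_total is not None else int(
        block_summaries["n_presentations"].sum())
    covered = int(sel["n_presentations"].sum())
    from ._util import percent
    summary = {
        "n_blocks": int(len(sel)),
        "n_presentations": covered,
        "registry_total": total,
        "share_percent": percent(covered, total) if total else 0.0,
    }
    return sel.reset_index(drop=True), summary


def heatmap_matrix(block_summaries: pd.DataFrame, coverage_threshold: float,
                   blocks: list[BlockDefinition] | None = None) -> pd.DataFrame:
    """Row-normalised block-by-cluster proportion matrix for plotting.

    Rows are the blocks within the cumulative-coverage threshold, grouped by
    chapter (then block id); each row sums to 1. Serialisable as delimited
    text by any plotting layer.
    """
    curve = cumulative_coverage(block_summaries, thresholds=[coverage_threshold])
    n_keep = curve.blocks_at_threshold[float(coverage_threshold)]
    keep = set(curve.ranked_blocks[:n_keep])
    if not keep:
        raise ValueError("coverage threshold excludes all blocks")
    sel = block_summaries[block_summaries["block_id"].isin(keep)].copy()
    chapter = {}
    if blocks is None:
        blocks = parse_block_table()
    chapter = {b.block_id: b.chapter for b in blocks}
    sel["chapter"] = sel["block_id"].map(lambda b: chapter.get(b, ""))
    sel = sel.sort_values(["chapter", "block_id"], ignore_index=True)
    prop_cols = [c for c in sel.columns if c.startswith("prop_cluster_")]
    mat = sel[["block_id", "chapter"] + prop_cols].set_index("block_id")
    assert np.allclose(mat[prop_cols].sum(axis=1), 1.0, atol=1e-9)
    return mat
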