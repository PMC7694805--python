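"""Tabular and graphical outputs.

The similarity/distance matrix is written as a tab-separated square table
with at least three decimals; the heatmap rounds displayed similarities to
one decimal (display only — downstream computation never consumes rounded
values).  The heatmap's upper-right triangle encodes similarity (darker =
more similar); the lower-left triangle stacks, top to bottom per cell, the
aligned fraction of the row genome (orange-to-white, darker = lower), the
genome length ratio (black-to-white, darker = lower) and the aligned
fraction of the column genome.  Genome lengths are annotated along the
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.patches import Rectangle

from igsim.similarity import (
    DirectedAlignmentSummary,
    PairResult,
    SimilarityMatrix,
    pairs_to_frame,
)


def format_cell_label(sim: float, decimals: int = 1) -> str:
    """Heatmap cell label: similarity rounded for display (display only)."""
    return f"{sim:.{decimals}f}"


def write_matrix(
    m: SimilarityMatrix,
    out_path: str | Path,
    kind: str = "sim",
    decimals: int = 3,
) -> Path:
    """Write the matrix as a TSV square table (ids in first row and column).

    ``kind`` selects similarity (``"sim"``) or distance (``"dist"``, i.e.
    ``100 - sim``) values.
    """
    if kind not in {"sim", "dist"}:
        raise ValueError("kind must be 'sim' or 'dist'")
    if decimals < 3:
        raise ValueError("matrix values carry at least 3 decimals")
    values = m.values if kind == "sim" else m.distance()
    out_path = Path(out_path)
    fmt = f"{{:.{decimals}f}}"
    with open(out_path, "w") as out:
        out.write("\t".join([""] + m.ids) + "\n")
        for gid, row in zip(m.ids, values):
            out.write("\t".join([gid] + [fmt.format(v) for v in row]) + "\n")
    return out_path


def read_matrix(path: str | Path) -> SimilarityMatrix:
    """Re-read a similarity matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.index), df.to_numpy())


def write_cluster_table(table, out_path: str | Path) -> Path:
    """Write the species/genus cluster table as TSV."""
    out_path = Path(out_path)
    table.to_frame().to_csv(out_path, sep="\t", index=False)
    return out_path


def write_intermediates(
    pairs: Sequence[PairResult],
    summaries: Mapping[tuple[str, str], DirectedAlignmentSummary],
    work_dir: str | Path,
) -> list[Path]:
    """Write the long-format pair table and per-direction summaries as TSV."""
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pair_path = work_dir / "pairwise_results.tsv"
    pairs_to_frame(pairs).to_csv(pair_path, sep="\t", index=False, float_format="%.6f")
    written.append(pair_path)

    dir_path = work_dir / "directed_summaries.tsv"
    rows = [
        {
            "query_id": s.query_id,
            "subject_id": s.subject_id,
            "ident_sum": s.ident_sum,
            "aligned_query_bases": s.aligned_query_bases,
            "n_retained_intervals": len(s.retained_intervals),
        }
        for s in summaries.values()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "subject_id",
            "ident_sum",
            "aligned_query_bases",
            "n_retained_intervals",
        ],
    ).to_csv(dir_path, sep="\t", index=False, float_format="%.6f")
    written.append(dir_path)
    return written


@dataclass
class HeatmapSpec:
    """Everything needed to render the composite heatmap deterministically."""

    matrix: SimilarityMatrix  # ordered (leaf order) similarity matrix
    indicators: Mapping[tuple[str, str], tuple[float, float, float]]
    lengths: Mapping[str, int]
    sim_cmap: str = "Blues"
    af_cmap: str = "Oranges_r"  # darker = lower aligned fraction
    ratio_cmap: str = "gray"  # darker = lower length ratio
    label_decimals: int = 1
    label_suppress_above: int = 80  # no cell numbers beyond this many genomes

    def __post_init__(self) -> None:
        for gid in self.matrix.ids:
            if gid not in self.lengths:
                raise ValueError(f"no length for genome {gid!r}")

    def indicator(self, row_id: str, col_id: str) -> tuple[float, float, float]:
        """(af of row genome, length ratio, af of column genome)."""
        key = (min(row_id, col_id), max(row_id, col_id))
        af_1, ratio, af_2 = self.indicators[key]
        if key[0] == row_id:
            return af_1, ratio, af_2
        return af_2, ratio, af_1


def heatmap_spec_from_results(
    matrix: SimilarityMatrix, pairs: Sequence[PairResult], lengths: Mapping[str, int]
) -> HeatmapSpec:
    indicators = {
        (p.id_a, p.id_b): (p.af_1, p.length_ratio, p.af_2) for p in pairs
    }
    return HeatmapSpec(matrix=matrix, indicators=indicators, lengths=dict(lengths))


def render_heatmap(spec: HeatmapSpec, out_path: str | Path) -> Path:
    """Render the composite similarity/indicator heatmap to a PDF file."""
    ids = spec.matrix.ids
    n = len(ids)
    values = spec.matrix.values
    show_labels = n <= spec.label_suppress_above

    sim_cmap = colormaps[spec.sim_cmap]
    af_cmap = colormaps[spec.af_cmap]
    ratio_cmap = colormaps[spec.ratio_cmap]

    cell = 0.35 if n > 20 else 0.6
    fig_w = max(4.0, n * cell + 2.5)
    fig_h = max(4.5, n * cell + 3.0)
    fig, (ax_len, ax) = plt.subplots(
        2,
        1,
        figsize=(fig_w, fig_h),
        gridspec_kw={"height_ratios": [1, max(n * 0.6, 4)], "hspace": 0.05},
        sharex=True,
    )

    # column annotation: genome lengths
    ax_len.bar(
        np.arange(n) + 0.5,
        [spec.lengths[g] for g in ids],
        width=0.8,
        color="#666666",
    )
    ax_len.set_ylabel("genome\nlength (bp)", fontsize=8)
    ax_len.tick_params(labelsize=7)

    for i, row_id in enumerate(ids):
        for j, col_id in enumerate(ids):
            x, y = j, n - 1 - i  # row 0 on top
            if j >= i:  # upper-right triangle incl. diagonal: similarity
                sim = values[i, j]
                ax.add_patch(
                    Rectangle((x, y), 1, 1, facecolor=sim_cmap(sim / 100.0), lw=0)
                )
                if show_labels:
                    ax.text(
                        x + 0.5,
                        y + 0.5,
                        format_cell_label(sim, spec.label_decimals),
                        ha="center",
                        va="center",
                        fontsize=max(3.5, min(7.0, 140.0 / max(n, 1))),
                        color="black" if sim < 60 else "white",
                    )
            else:  # lower-left triangle: indicator bands, top to bottom
                af_row, ratio, af_col = spec.indicator(row_id, col_id)
                third = 1.0 / 3.0
                for k, (val, cmap) in enumerate(
                    [(af_row, af_cmap), (ratio, ratio_cmap), (af_col, af_cmap)]
                ):
                    ax.add_patch(
                        Rectangle(
                            (x, y + 1 - (k + 1) * third),
                            1,
                            third,
                            facecolor=cmap(val),
                            lw=0,
                        )
                    )
    ax.set_xlim(0, n)
    ax.set_ylim(0, n)
    ax.set_xticks(np.arange(n) + 0.5)
    ax.set_xticklabels(ids, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(n) + 0.5)
    ax.set_yticklabels(ids[::-1], fontsize=7)
    ax.set_aspect("equal")
    for side in ("top", "right"):
        ax.spines[side].set_visible(False)

    out_path = Path(out_path)
    fig.savefig(out_path, format="pdf", bbox_inches="tight")
    plt.close(fig)
    return out_path
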