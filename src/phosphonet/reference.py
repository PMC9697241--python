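"""Published per-bin interaction summaries and proteome counts used as
reference inputs.

These are the printed summary tables of the comparative phospho-proteome
study this pipeline re-implements: per-bin node/edge counts of the
within-bin STRING subnetworks (combined score > 0.7) for the human decile,
fly zero-plus-quartile and yeast quintile partitions, and the per-category
proteome entry counts.  The underlying databases cannot be bundled, so the
raw node/edge/entry counts serve as *inputs* against which the package's
arithmetic (mean degree 2E/N, category percentages) is recomputed.
"""
from __future__ import annotations

import pandas as pd

# Human proteins by phospho-site decile: bin ranges, node and edge counts,
# published mean degree, components (>= 2 nodes) and singleton percentage.
HUMAN_DECILES = pd.DataFrame(
    {
        "bin": range(1, 11),
        "range_lo": [0, 3, 6, 9, 12, 15, 20, 27, 38, 62],
        "range_hi": [2, 5, 8, 11, 14, 19, 26, 37, 61, 2518],
        "nb_nodes": [2368, 2130, 1985, 1818, 1538, 2042, 1964, 1892, 1984, 1924],
        "nb_edges": [1455, 1607, 2021, 2217, 1499, 2840, 3819, 4240, 7688, 9188],
        "avg_neighbors": [1.229, 1.509, 2.036, 2.439, 1.950, 2.781, 3.889,
                          4.482, 7.750, 9.551],
        "nb_connected": [120, 135, 89, 83, 80, 76, 52, 39, 33, 22],
        "pct_singletons": [67.95, 55.77, 48.51, 46.97, 48.57, 42.36, 37.58,
                           33.51, 23.14, 15.96],
    }
)

# Fly proteins: non-phosphorylated bin followed by quartiles of the rest.
FLY_BINS = pd.DataFrame(
    {
        "bin": range(1, 6),
        "range_lo": [0, 1, 2, 4, 9],
        "range_hi": [0, 1, 3, 8, 454],
        "nb_nodes": [7338, 1111, 1273, 1110, 1137],
        "nb_edges": [28323, 2232, 2965, 3156, 4514],
        "avg_neighbors": [7.72, 4.02, 4.66, 5.69, 7.94],
        "nb_connected": [123, 38, 36, 15, 17],
        "pct_singletons": [35.12, 41.49, 34.72, 29.46, 19.88],
    }
)

# Yeast proteins by phospho-site quintile.
YEAST_QUINTILES = pd.DataFrame(
    {
        "bin": range(1, 6),
        "range_lo": [0, 2, 6, 12, 24],
        "range_hi": [1, 5, 11, 23, 227],
        "nb_nodes": [1020, 1029, 1072, 987, 1011],
        "nb_edges": [3190, 3628, 7945, 8366, 5508],
        "avg_neighbors": [6.25, 7.05, 14.82, 16.95, 10.90],
        "nb_connected": [29, 29, 17, 16, 8],
        "pct_singletons": [14.12, 11.47, 20.15, 6.18, 12.56],
    }
)

# Proteome entry counts per category (all / phosphorylated /
# non-phosphorylated) with the published percentages.
PROTEOME_COUNTS = pd.DataFrame(
    [
        ("H. sapiens", 157160, 148400, 8760, 94.43, 5.57),
        ("M. musculus", 169976, 135096, 34880, 79.48, 20.52),
        ("D. rerio", 175752, 16936, 158816, 9.64, 90.36),
        ("D. melanogaster", 95752, 37048, 58704, 38.69, 61.31),
        ("C. elegans", 81312, 22808, 58504, 28.05, 71.95),
        ("S. cerevisiae", 40952, 35640, 5312, 87.03, 12.97),
        ("A. thaliana", 122984, 65992, 56992, 53.66, 46.34),
    ],
    columns=[
        "species", "total", "phosphorylated", "non_phosphorylated",
        "pct_phosphorylated", "pct_non_phosphorylated",
    ],
)

#: number of human proteins in the binned interaction dataset
HUMAN_BINNED_TOTAL = 19645
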