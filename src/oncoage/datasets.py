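"""Bundled reference tables from a published TCGA THCA analysis.

Cluster-by-parameter counts for 481 papillary thyroid carcinoma samples
stratified by composite-score sign into four aggressiveness clusters —
LAYC/MAYC (less/more aggressive young, < 55 y) and LAAC/MAAC (less/more
aggressive aging, >= 55 y).  These counts drive worked examples for the
hierarchy statistics; they are inputs, not recomputed quantities.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CLUSTERS",
    "cluster_sizes",
    "cluster_parameter_counts",
    "enrichment_call_counts",
]

CLUSTERS = ("LAYC", "MAYC", "LAAC", "MAAC")

_CLUSTER_SIZES = {"LAYC": 189, "MAYC": 132, "LAAC": 103, "MAAC": 57}

# parameter -> {level: (LAYC, MAYC, LAAC, MAAC)}; the second level listed
# is the aggressive one
_PARAMETER_COUNTS = {
    "lymph_node_metastasis": {"N0": (90, 41, 67, 21), "N1": (77, 80, 26, 33)},
    "tumor_size_1cm": {"<1cm": (62, 36, 32, 20), ">=1cm": (127, 96, 71, 37)},
    "tumor_size_2cm": {"<2cm": (137, 103, 75, 35), ">=2cm": (52, 29, 28, 22)},
    "extrathyroidal_extension": {
        "absent": (151, 80, 66, 25),
        "present": (33, 50, 30, 32),
    },
    "ete_gross": {"no_gross": (184, 128, 90, 47), "gross": (0, 2, 6, 10)},
    "distant_metastasis": {"M0": (97, 81, 57, 31), "M1": (3, 1, 2, 3)},
    "histological_type": {"FPTC": (62, 4, 30, 4), "C/TPTC": (123, 124, 72, 53)},
    "histological_type_tall": {
        "C/FPTC": (183, 113, 97, 44),
        "TPTC": (2, 15, 5, 13),
    },
    "braf_mutation": {"WT": (56, 3, 28, 3), "MUT": (64, 93, 37, 39)},
    "tert_mutation": {"WT": (145, 98, 67, 27), "MUT": (2, 5, 11, 18)},
    "differentiation_score": {"high": (98, 17, 54, 12), "low": (54, 93, 28, 34)},
    "disease_free_survival": {
        "non_recurrence": (177, 120, 89, 37),
        "recurrence": (11, 13, 8, 12),
    },
    "overall_survival": {"alive": (188, 133, 97, 47), "dead": (0, 0, 6, 10)},
    "progression_free_interval": {
        "non_recurrence": (177, 120, 91, 43),
        "recurrence": (11, 13, 11, 14),
    },
    "disease_specific_survival": {
        "alive": (188, 133, 98, 48),
        "dead": (0, 0, 3, 4),
    },
}

# enrichment calls reported per cluster across the 12 significant parameters
_ENRICHMENT_CALLS = {
    "non_aggressive": {"LAYC": 11, "MAYC": 4, "LAAC": 4, "MAAC": 0},
    "aggressive": {"LAYC": 0, "MAYC": 7, "LAAC": 5, "MAAC": 12},
}

#: number of parameters with a significant four-cluster association
N_SIGNIFICANT_PARAMETERS = 12


def cluster_sizes() -> pd.Series:
    """Sample count per cluster (481 tumors in total)."""
    return pd.Series(_CLUSTER_SIZES, name="n_samples").reindex(list(CLUSTERS))


def cluster_parameter_counts(parameter: str | None = None):
    """Level x cluster counts for one parameter (or the dict of all).

    The aggressive level of each parameter is the last row of its table.
    """
    if parameter is None:
        return {p: cluster_parameter_counts(p) for p in _PARAMETER_COUNTS}
    levels = _PARAMETER_COUNTS[parameter]
    return pd.DataFrame(levels, index=list(CLUSTERS)).T


def enrichment_call_counts() -> pd.DataFrame:
    """Reported aggressive / non-aggressive enrichment calls per cluster."""
    return pd.DataFrame(_ENRICHMENT_CALLS).reindex(list(CLUSTERS))
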