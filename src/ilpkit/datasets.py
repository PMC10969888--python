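"""Bundled reference data from the tea ILP marker study system.

These are published summary tables for genome-wide tea (Camellia
sinensis) intron-length-polymorphism markers and their application to
176 cultivated C. tetracocca trees from three town populations of Puan
County (Guizhou, China). They serve as small worked inputs: the package
recomputes derived quantities (column means, percentages, variance
partitions, genetic distances) from them rather than asserting them.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: Individuals genotyped in the C. tetracocca diversity study and the
#: sizes of its three town populations (Qingshan, Louxia, Digua).
N_INDIVIDUALS = 176
POPULATION_SIZES = {"Qingshan": 55, "Louxia": 30, "Digua": 91}


def load_locus_panel() -> pd.DataFrame:
    """The 40-locus ILP diversity panel scored on 176 C. tetracocca trees.

    Columns: Na, Ne, I (Shannon), Obs_Ho, Obs_He, Exp_Ho, Exp_He,
    H (Nei gene diversity), PIC_pct. One row per Tea_ILP locus.
    """
    ref = importlib.resources.files("ilpkit") / "data" / "tetracocca_locus_panel.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="locus")


def validation_counts() -> dict[str, tuple[int, int, int]]:
    """Six-species wet-lab validation screen of 230 ILP primer pairs:
    (tested, amplified-in-all-six, polymorphic) per source genome."""
    return {
        "Shuchazao": (39, 35, 9),
        "Longjing43": (91, 87, 38),
        "DASZ": (100, 91, 65),
    }


def amova_observed() -> dict[str, dict[str, float]]:
    """Published AMOVA table for the 176-tree, three-population study:
    degrees of freedom, sums of squares, and variance components."""
    return {
        "among": {"df": 2, "SS": 183.68, "sigma2": 1.35},
        "within": {"df": 173, "SS": 3419.25, "sigma2": 19.76},
    }


def population_nei_similarity() -> pd.DataFrame:
    """Nei genetic identity S between the three C. tetracocca populations."""
    pops = ["Qingshan", "Louxia", "Digua"]
    S = [
        [1.00, 0.92, 0.93],
        [0.92, 1.00, 0.94],
        [0.93, 0.94, 1.00],
    ]
    return pd.DataFrame(S, index=pops, columns=pops)
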