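"""Published wheat chromosome 3B reference numbers used as analysis inputs.

The deletion-bin table (contig lengths, anchored loci, barley/rice mapping
and collinearity counts) and a handful of whole-chromosome counts from the
same screen.  These are inputs to the arithmetic re-analyses (densities,
synteny and collinearity percentages, extrapolations); nothing here is a
computed result of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: probes on the expression microarray
N_UNIGENES = 15_208
#: share of the barley genome on chromosome 3H
CHR3H_GENOME_FRACTION = 0.148
#: fraction of wheat 3B covered by the minimal tiling path
MTP_COVERAGE_FRACTION = 0.82

#: whole-chromosome mapping counts (syntenic, non-syntenic) for loci with a
#: reference assignment; these are chromosome-level counts and differ from
#: the bin-table column sums, which include only deletion-bin-assigned loci
#: plus a separately tabulated unassigned remainder.
BARLEY_MAPPED = (209, 99)
RICE_MAPPED = (389, 270)

#: collinear / binned-syntenic counts per reference
BARLEY_COLLINEAR = (102, 153)
RICE_COLLINEAR = (185, 285)

#: loci on contigs not assigned to any deletion bin
UNASSIGNED = {
    "contig_length_mb": 438.8,
    "n_loci": 238,
    "barley_3h": 66,
    "barley_other": 42,
    "rice_os01": 111,
    "rice_other": 104,
}

#: normalized gene densities of the two telomeric bins in an independent
#: RFLP/EST deletion-bin study, used as the reference profile for the
#: tandem-duplication correction
EST_REFERENCE_NORMALIZED = {"3BS8-0.78-1.00": 1.190, "3BL7-0.63-1.00": 1.421}

#: whole-chromosome gene count estimate used for density extrapolation
TARGET_GENE_TOTAL = 8400


def load_wheat3b_table() -> pd.DataFrame:
    """The per-bin mapping table (8 deletion bins, telomere-S to telomere-L)."""
    ref = resources.files("poolanchor").joinpath("data/wheat3b_bin_table.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def bin_lengths_mb() -> dict[str, float]:
    df = load_wheat3b_table()
    return dict(zip(df["bin"], df["contig_length_mb"]))


def bin_locus_counts() -> dict[str, int]:
    df = load_wheat3b_table()
    return dict(zip(df["bin"], df["n_loci"]))
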