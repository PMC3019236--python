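"""Synteny and collinearity of anchored loci against barley and rice references.

Synteny is residence on the orthologous chromosome, irrespective of gene
order.  Collinearity additionally requires the locus's reference position to
fall inside the synteny block of its own deletion bin; the blocks are built
from a maximal order-consistent subset of the loci (longest increasing
subsequence over bin-ordered reference positions), since the relative order
of loci *within* a bin is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SyntenyBlock:
    bin: str
    reference: str
    start: float | None  # min reference position of the bin's retained loci
    end: float | None

    @property
    def empty(self) -> bool:
        return self.start is None

    def contains(self, position: float) -> bool:
        return (not self.empty) and self.start <= position <= self.end


# ---------------------------------------------------------------------------
# statistical primitives


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value (t transform,
    n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_test needs two vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_test is undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sample Welch t-test, two-sided.  Returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t_test needs at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("t_test is undefined when both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi2_uniformity(
    observed: Sequence[float], totals: Sequence[float]
) -> tuple[float, int, float, np.ndarray]:
    """Chi-square test of uniformity with constructed expected values.

    The global proportion p = sum(observed) / sum(totals) is applied to each
    category's total to build the expected counts (for density uniformity
    the totals are the bin contig lengths, so expected_i is proportional to
    length).  Degrees of freedom = categories - 1.  Returns
    (stat, df, p, expected); a warning is attached to the expected array's
    metadata when any expected count is below 1.
    """
    observed = np.asarray(observed, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if len(observed) != len(totals) or len(observed) < 2:
        raise ValueError("chi2_uniformity needs >= 2 matched categories")
    if (totals <= 0).any():
        raise ValueError("all category totals must be > 0")
    p_bar = observed.sum() / totals.sum()
    expected = p_bar * totals
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    pvalue = float(stats.chi2.sf(stat, df))
    return stat, df, pvalue, expected


def bias_tests(
    counts: Mapping[str, int], chromosome_totals: Mapping[str, int]
) -> dict:
    """Test whether non-syntenic loci are biased towards particular
    chromosomes, against the null of proportionality to each chromosome's
    gene total.

    Chromosomes with a zero expected count are pooled into an ``other``
    category (with a warning flag in the output).  Returns the chi-square
    statistic/df/p and the Pearson correlation between counts and totals.
    """
    keys = [k for k in chromosome_totals if k in counts]
    if len(keys) < 2:
        raise ValueError("bias_tests needs counts on >= 2 chromosomes")
    obs = np.array([counts[k] for k in keys], dtype=float)
    tot = np.array([chromosome_totals[k] for k in keys], dtype=float)
    pooled = False
    if (tot == 0).any():
        pooled = True
        zero = tot == 0
        obs = np.append(obs[~zero], obs[zero].sum())
        tot = np.append(tot[~zero], max(tot[zero].sum(), 1.0))
    expected = obs.sum() * tot / tot.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    out = {
        "chi2_stat": stat,
        "chi2_df": df,
        "chi2_p": float(stats.chi2.sf(stat, df)),
        "pooled_zero_total": pooled,
    }
    if np.ptp(obs) > 0 and np.ptp(tot) > 0:
        r, p = pearson_test(obs, tot)
        out["pearson_r"] = r
        out["pearson_p"] = p
    else:
        out["pearson_r"] = None
        out["pearson_p"] = None
    return out


# ---------------------------------------------------------------------------
# attaching reference positions


def attach_map_positions(
    loci: pd.DataFrame,
    gmap,
    alignments: Mapping[str, Sequence[tuple[str, float, int]]],
) -> pd.DataFrame:
    """Attach genetic-map positions to loci via probe-marker alignments.

    ``alignments`` maps probe_id to candidate hits ``(marker_id,
    identity_pct, aligned_length_nt)``.  Per probe, hits failing the map's
    link rule (default >= 85% identity over >= 100 nt) are discarded and the
    best remaining hit (highest identity, then longest) is attached.
    Returns a copy of ``loci`` with ``ref_chromosome`` / ``ref_position``
    columns (NaN when unmapped).
    """
    out = loci.copy()
    chroms: list[str | None] = []
    positions: list[float] = []
    for probe_id in out["probe_id"]:
        hits = [
            h
            for h in alignments.get(probe_id, [])
            if h[1] >= gmap.min_identity_pct and h[2] >= gmap.min_length_nt
        ]
        if not hits:
            chroms.append(None)
            positions.append(np.nan)
            continue
        marker = max(hits, key=lambda h: (h[1], h[2]))[0]
        chrom, cm = gmap.position(marker)
        chroms.append(chrom)
        positions.append(cm)
    out["ref_chromosome"] = chroms
    out["ref_position"] = positions
    return out


def attach_ortholog_positions(loci: pd.DataFrame, table) -> pd.DataFrame:
    """Attach rice ortholog chromosome and ordinal position to loci."""
    out = loci.copy()
    merged = out.merge(
        table.entries.rename(
            columns={"chromosome": "ref_chromosome", "ordinal_index": "ref_position"}
        ),
        on="probe_id",
        how="left",
    )
    merged["ref_position"] = merged["ref_position"].astype(float)
    return merged


# ---------------------------------------------------------------------------
# synteny


def synteny_summary(
    loci: pd.DataFrame, orthologous_chromosome: str, bin_order: Sequence[str] | None = None
) -> dict:
    """Count syntenic vs non-syntenic loci overall and per deletion bin.

    Only loci with a reference chromosome label are considered.  A locus is
    syntenic when it sits on the orthologous chromosome.
    """
    mapped = loci[loci["ref_chromosome"].notna()]
    syntenic = mapped["ref_chromosome"] == orthologous_chromosome
    n_syn = int(syntenic.sum())
    n_non = int((~syntenic).sum())
    per_bin = []
    if bin_order is not None:
        binned = mapped[mapped["bin"].notna()]
        for name in bin_order:
            sub = binned[binned["bin"] == name]
            s = int((sub["ref_chromosome"] == orthologous_chromosome).sum())
            per_bin.append(
                {
                    "bin": name,
                    "n_syntenic": s,
                    "n_nonsyntenic": len(sub) - s,
                    "pct_syntenic": 100.0 * s / len(sub) if len(sub) else None,
                }
            )
    return {
        "reference": orthologous_chromosome,
        "n_mapped": len(mapped),
        "n_syntenic": n_syn,
        "n_nonsyntenic": n_non,
        "pct_syntenic": 100.0 * n_syn / (n_syn + n_non) if n_syn + n_non else None,
        "per_bin": per_bin,
    }


def mean_per_bin_synteny(per_bin: Sequence[Mapping]) -> float:
    """Average per-bin synteny as pooled counts: sum syntenic / sum mapped."""
    s = sum(b["n_syntenic"] for b in per_bin)
    n = sum(b["n_syntenic"] + b["n_nonsyntenic"] for b in per_bin)
    return 100.0 * s / n if n else float("nan")


# ---------------------------------------------------------------------------
# collinearity


def _lis_mask(values: np.ndarray, penalties: np.ndarray) -> np.ndarray:
    """Boolean mask of a longest non-decreasing subsequence (O(n^2) DP).

    Ties in length are broken by the smallest total penalty, so among
    equally long order-consistent subsets the one keeping loci nearest
    their own bin's typical position wins.
    """
    n = len(values)
    if n == 0:
        return np.zeros(0, dtype=bool)
    length = np.ones(n, dtype=int)
    cost = penalties.astype(float).copy()
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            if values[j] > values[i]:
                continue
            cand_len = length[j] + 1
            cand_cost = cost[j] + penalties[i]
            if cand_len > length[i] or (
                cand_len == length[i] and cand_cost < cost[i]
            ):
                length[i] = cand_len
                cost[i] = cand_cost
                prev[i] = j
    order = sorted(range(n), key=lambda i: (-length[i], cost[i]))
    best = order[0]
    mask = np.zeros(n, dtype=bool)
    while best != -1:
        mask[best] = True
        best = int(prev[best])
    return mask


def build_synteny_blocks(
    loci: pd.DataFrame, bin_order: Sequence[str], reference: str
) -> tuple[list[SyntenyBlock], pd.DataFrame]:
    """Build one synteny block per deletion bin from binned syntenic loci.

    Loci are sorted by bin order (ties by reference position) and a maximal
    order-consistent subset is retained (longest increasing subsequence of
    reference positions; both chromosome orientations are tried and the
    better one kept).  Each bin's block is the [min, max] reference-position
    interval of its retained loci; loci excluded by the subsequence are the
    out-of-place ones and will be classified non-collinear downstream.
    Returns the blocks and the input frame with a ``retained`` column.
    """
    sub = loci[
        loci["bin"].notna()
        & (loci["ref_chromosome"] == reference)
        & loci["ref_position"].notna()
    ].copy()
    rank = {name: i for i, name in enumerate(bin_order)}
    sub["_bin_rank"] = sub["bin"].map(rank)
    medians = sub.groupby("bin")["ref_position"].median()
    sub["_penalty"] = (sub["ref_position"] - sub["bin"].map(medians)).abs()
    fwd = sub.sort_values(["_bin_rank", "ref_position"], kind="stable")
    fwd_mask = _lis_mask(
        fwd["ref_position"].to_numpy(dtype=float),
        fwd["_penalty"].to_numpy(dtype=float),
    )
    rev = sub.sort_values(
        ["_bin_rank", "ref_position"], ascending=[True, False], kind="stable"
    )
    rev_mask = _lis_mask(
        -rev["ref_position"].to_numpy(dtype=float),
        rev["_penalty"].to_numpy(dtype=float),
    )
    if fwd_mask.sum() >= rev_mask.sum():
        sub = fwd
        sub["retained"] = fwd_mask
    else:
        sub = rev
        sub["retained"] = rev_mask
    sub = sub.drop(columns=["_penalty"])
    blocks = []
    for name in bin_order:
        kept = sub[(sub["bin"] == name) & sub["retained"]]
        if kept.empty:
            blocks.append(SyntenyBlock(bin=name, reference=reference, start=None, end=None))
        else:
            blocks.append(
                SyntenyBlock(
                    bin=name,
                    reference=reference,
                    start=float(kept["ref_position"].min()),
                    end=float(kept["ref_position"].max()),
                )
            )
    return blocks, sub.drop(columns=["_bin_rank"])


def collinearity_summary(
    loci: pd.DataFrame, blocks: Sequence[SyntenyBlock], reference: str
) -> dict:
    """Count collinear loci: binned syntenic loci whose reference position
    lies inside their own bin's synteny block."""
    by_bin = {b.bin: b for b in blocks}
    sub = loci[
        loci["bin"].notna()
        & (loci["ref_chromosome"] == reference)
        & loci["ref_position"].notna()
    ]
    per_bin = []
    total = 0
    collinear = 0
    for name, block in by_bin.items():
        rows = sub[sub["bin"] == name]
        n_col = int(
            sum(block.contains(p) for p in rows["ref_position"]) if not block.empty else 0
        )
        per_bin.append(
            {
                "bin": name,
                "n_binned_syntenic": len(rows),
                "n_collinear": n_col,
                "pct_collinear": 100.0 * n_col / len(rows) if len(rows) else None,
            }
        )
        total += len(rows)
        collinear += n_col
    return {
        "reference": reference,
        "n_binned_syntenic": total,
        "n_collinear": collinear,
        "pct_collinear": 100.0 * collinear / total if total else None,
        "per_bin": per_bin,
    }


# ---------------------------------------------------------------------------
# expected-probe arithmetic


def round_sig(x: float, figures: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + figures - 1)


def expected_probe_counts(
    n_probes: int, chromosome_genome_fraction: float, mtp_coverage_fraction: float
) -> dict:
    """Expected probes on the orthologous chromosome and on the MTP.

    Assuming a comparable gene density across the reference genome, the
    expected number of probes residing on the orthologous chromosome is the
    chromosome's genome fraction times the probe count (reported to three
    significant figures); the expected number detectable on the physical
    map scales by the MTP's chromosome coverage.
    """
    on_chromosome = round_sig(n_probes * chromosome_genome_fraction, 3)
    on_map = round(on_chromosome * mtp_coverage_fraction)
    return {"expected_on_chromosome": on_chromosome, "expected_on_map": on_map}
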