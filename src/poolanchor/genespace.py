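"""Gene-density and gene-island analysis along the chromosome.

Densities are loci per megabase of contig length assigned to each deletion
bin.  Gene islands are groups of loci on the same BAC, on overlapping BACs,
or on BACs whose intervals lie closer than a gap threshold (150 kb by
default) within one contig; island membership is the transitive closure of
this pairwise relation (connected components), and islands have at least
two members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from poolanchor.comparative import chi2_uniformity, pearson_test
from poolanchor.core_io import DeletionBin, PhysicalMap
from poolanchor.deconvolve import GeneLocus

DEFAULT_ISLAND_GAP_BP = 150_000


# ---------------------------------------------------------------------------
# densities


def count_loci_by_bin(loci: Sequence[GeneLocus]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for locus in loci:
        if locus.bin is not None:
            counts[locus.bin] = counts.get(locus.bin, 0) + 1
    return counts


def bin_density(
    counts: Mapping[str, int], lengths_mb: Mapping[str, float]
) -> pd.DataFrame:
    """Loci per megabase for each bin, plus a ``total`` row.

    ``lengths_mb`` fixes the bin order; its values are cumulative contig
    lengths in Mb and must be positive.
    """
    rows = []
    for name, length in lengths_mb.items():
        if length is None or length <= 0:
            raise ValueError(f"bin {name!r} has non-positive contig length")
        n = int(counts.get(name, 0))
        rows.append(
            {"bin": name, "n_loci": n, "contig_length_mb": float(length),
             "density": n / length}
        )
    df = pd.DataFrame(rows)
    total_n = int(df["n_loci"].sum())
    total_len = float(df["contig_length_mb"].sum())
    total = pd.DataFrame(
        [{"bin": "total", "n_loci": total_n, "contig_length_mb": total_len,
          "density": total_n / total_len}]
    )
    return pd.concat([df, total], ignore_index=True)


def normalized_density(densities: Sequence[float]) -> np.ndarray:
    """Each density divided by the mean density (unrounded); the mean of the
    result is exactly 1."""
    d = np.asarray(densities, dtype=float)
    if len(d) == 0:
        raise ValueError("no densities given")
    return d / d.mean()


def centromere_distance(
    bin_spans_mb: Mapping[str, tuple[float, float]], centromere_mb: float
) -> dict[str, float]:
    """Distance (Mb) from the centromere to each bin's midpoint."""
    return {
        name: abs(centromere_mb - (start + end) / 2.0)
        for name, (start, end) in bin_spans_mb.items()
    }


def gradient_tests(
    densities: Sequence[float],
    distances_mb: Sequence[float],
    counts: Sequence[int],
    lengths_mb: Sequence[float],
) -> dict:
    """Gradient statistics: Pearson correlation of density against distance
    to the centromere, and a chi-square uniformity test of the counts with
    length-weighted expected values."""
    r, p = pearson_test(distances_mb, densities)
    stat, df, chi_p, expected = chi2_uniformity(counts, lengths_mb)
    return {
        "pearson_r": r,
        "pearson_p": p,
        "chi2_stat": stat,
        "chi2_df": df,
        "chi2_p": chi_p,
        "expected": expected.tolist(),
    }


# ---------------------------------------------------------------------------
# gene islands


@dataclass
class IslandAssignment:
    """Partition of loci into islands (>= 2 members) and isolated loci."""

    island_of: dict[str, str | None] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_island_loci(self) -> int:
        return sum(len(m) for m in self.members.values())


def detect_islands(
    loci: Sequence[GeneLocus],
    pm: PhysicalMap,
    gap_bp: int = DEFAULT_ISLAND_GAP_BP,
) -> IslandAssignment:
    """Group loci into gene islands by transitive closure.

    Two loci are linked when they share a BAC, sit on overlapping BACs, or
    their BAC-interval footprints within one contig are separated by less
    than ``gap_bp``.  Contig boundaries always break islands (the physical
    distance across an inter-contig gap is unknown).
    """
    by_contig: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig_id, []).append(locus)
    parent: dict[str, str] = {l.locus_id: l.locus_id for l in loci}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for members in by_contig.values():
        for i, a in enumerate(members):
            ia = a.interval(pm)
            for b in members[i + 1 :]:
                ib = b.interval(pm)
                if set(a.bac_ids) & set(b.bac_ids):
                    union(a.locus_id, b.locus_id)
                    continue
                if ia is None or ib is None:
                    continue
                separation = max(ia[0], ib[0]) - min(ia[1], ib[1])
                if separation < gap_bp:  # negative separation = overlap
                    union(a.locus_id, b.locus_id)
    groups: dict[str, list[str]] = {}
    for locus in loci:
        groups.setdefault(find(locus.locus_id), []).append(locus.locus_id)
    assignment = IslandAssignment()
    counter = 0
    for root in sorted(groups):
        ids = sorted(groups[root])
        if len(ids) >= 2:
            counter += 1
            island_id = f"ISL{counter:04d}"
            assignment.members[island_id] = ids
            for lid in ids:
                assignment.island_of[lid] = island_id
        else:
            assignment.island_of[ids[0]] = None
    return assignment


def island_bin_stats(
    loci: Sequence[GeneLocus],
    assignment: IslandAssignment,
    lengths_mb: Mapping[str, float],
) -> pd.DataFrame:
    """Per-bin island / isolated counts and densities, plus a ``total`` row."""
    rows = []
    total_island = total_n = 0
    total_len = 0.0
    for name, length in lengths_mb.items():
        binned = [l for l in loci if l.bin == name]
        n_isl = sum(1 for l in binned if assignment.island_of.get(l.locus_id))
        n = len(binned)
        rows.append(
            {
                "bin": name,
                "n_loci": n,
                "n_island_loci": n_isl,
                "n_isolated_loci": n - n_isl,
                "island_density": n_isl / length,
                "isolated_density": (n - n_isl) / length,
                "pct_island": 100.0 * n_isl / n if n else None,
            }
        )
        total_island += n_isl
        total_n += n
        total_len += length
    rows.append(
        {
            "bin": "total",
            "n_loci": total_n,
            "n_island_loci": total_island,
            "n_isolated_loci": total_n - total_island,
            "island_density": total_island / total_len,
            "isolated_density": (total_n - total_island) / total_len,
            "pct_island": 100.0 * total_island / total_n if total_n else None,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# extrapolation


def extrapolate(
    densities: Mapping[str, float],
    full_sizes_mb: Mapping[str, float],
    target_total: float,
) -> pd.DataFrame:
    """Project observed densities onto full bin sizes, then rescale to a
    target chromosome-wide locus count.

    Step 1: projected_i = density_i x full_size_i.  Step 2: all projections
    are rescaled so they sum to ``target_total``.  kb-per-gene is
    1000 x full_size_i / rescaled_i.
    """
    if target_total <= 0:
        raise ValueError("target_total must be > 0")
    names = list(densities)
    missing = [n for n in names if full_sizes_mb.get(n) is None]
    if missing:
        raise ValueError(f"missing full bin sizes for {missing}")
    projected = np.array([densities[n] * full_sizes_mb[n] for n in names])
    scale = target_total / projected.sum()
    rescaled = projected * scale
    kb_per_gene = np.array([1000.0 * full_sizes_mb[n] for n in names]) / rescaled
    return pd.DataFrame(
        {
            "bin": names,
            "full_size_mb": [full_sizes_mb[n] for n in names],
            "projected_loci": projected,
            "rescaled_loci": rescaled,
            "kb_per_gene": kb_per_gene,
        }
    )


def tandem_correction(
    normalized_observed: Mapping[str, float], normalized_reference: Mapping[str, float]
) -> dict[str, float | None]:
    """Fraction of genes missed per bin relative to a reference profile.

    missed_i = 1 - observed_i / reference_i, floored at 0 (None when the
    reference is 0).  The reference profile is an independent normalized-
    density estimate (for wheat 3B, an RFLP/EST deletion-bin study); the
    difference is attributed to tandemly duplicated genes invisible to
    presence/absence hybridisation.
    """
    out: dict[str, float | None] = {}
    for name, obs in normalized_observed.items():
        ref = normalized_reference.get(name)
        if ref is None or ref == 0:
            out[name] = None
        else:
            out[name] = max(0.0, 1.0 - obs / ref)
    return out
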