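"""Deconvolution: positive pools -> BAC addresses -> gene loci -> deletion bins.

A probe's positive pools imply a set of candidate wells (the Cartesian
product of its positive coordinates per axis).  A *covering well set* is a
subset of occupied candidate wells that uses every positive pool.  A probe
is resolved when, at the smallest feasible set size, there is exactly one
covering set whose BACs are mutually overlapping on the physical map (one
to three BACs), or — failing that — exactly one covering pair of BACs on
disjoint contigs, which is recorded as a duplicated placement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from poolanchor.alignment import LocalAlignment, smith_waterman
from poolanchor.core_io import AXES, PhysicalMap, RepeatLibrary, Well
from poolanchor.pooling import PoolLayout, ScoringResult

RESOLUTIONS = {1: "unique", 2: "overlapping_pair", 3: "overlapping_triple"}


@dataclass(frozen=True)
class BACAddress:
    probe_id: str
    bac_id: str
    well: Well
    method: str
    resolution: str  # unique | overlapping_pair | overlapping_triple


@dataclass
class GeneLocus:
    locus_id: str
    probe_id: str
    bac_ids: tuple[str, ...]
    contig_id: str
    bin: str | None = None
    method: str = ""
    duplicated: bool = False

    def interval(self, pm: PhysicalMap) -> tuple[int, int] | None:
        """Union of the locus's BAC intervals on the chromosome."""
        spans = [pm.bac_interval(b) for b in self.bac_ids]
        spans = [s for s in spans if s is not None]
        if not spans:
            return None
        return (min(s for s, _ in spans), max(e for _, e in spans))


# ---------------------------------------------------------------------------
# address resolution


def _covering_sets(
    wells: Sequence[Well],
    required: Mapping[str, frozenset],
    size: int,
) -> Iterable[tuple[Well, ...]]:
    """Subsets of ``wells`` of the given size using every positive coordinate."""
    for combo in itertools.combinations(wells, size):
        plates = frozenset(w[0] for w in combo)
        rows = frozenset(w[1] for w in combo)
        cols = frozenset(w[2] for w in combo)
        if (
            plates == required["plate"]
            and rows == required["row"]
            and cols == required["column"]
        ):
            yield combo


def _mutually_overlapping(bacs: Sequence[str], pm: PhysicalMap) -> bool:
    return all(pm.overlap(a, b) for a, b in itertools.combinations(bacs, 2))


def resolve_probe(
    coords: Mapping[str, Sequence], pm: PhysicalMap, max_per_axis: int = 4
) -> tuple[list[Well], str] | None:
    """Resolve one probe's positive coordinates to wells.

    Returns ``(wells, resolution)`` or ``None`` when unresolved.  The
    minimal covering-set size is preferred; at that size the covering set
    must be unique.  ``resolution`` is ``duplicated_pair`` for two BACs on
    disjoint contigs (same probe placed twice on the chromosome).
    """
    if any(len(coords[a]) == 0 or len(coords[a]) > max_per_axis for a in AXES):
        return None
    required = {a: frozenset(coords[a]) for a in AXES}
    candidates = [
        (p, r, c)
        for p in coords["plate"]
        for r in coords["row"]
        for c in coords["column"]
    ]
    occupied = [w for w in candidates if pm.bac_at(w) is not None]
    min_size = max(len(v) for v in required.values())
    for size in range(min_size, 4):
        if size > len(occupied):
            break
        overlapping: list[tuple[Well, ...]] = []
        disjoint_pairs: list[tuple[Well, ...]] = []
        for combo in _covering_sets(occupied, required, size):
            bacs = [pm.bac_at(w) for w in combo]
            if len(set(bacs)) != len(bacs):
                continue
            if size == 1 or _mutually_overlapping(bacs, pm):
                overlapping.append(combo)
            elif (
                size == 2
                and all(len(required[a]) == 2 for a in AXES)
                and pm.contig_of(bacs[0]) != pm.contig_of(bacs[1])
            ):
                # two complete, independent addresses (a 2/2/2 pattern):
                # the same probe placed twice on the chromosome
                disjoint_pairs.append(combo)
        if len(overlapping) == 1:
            combo = overlapping[0]
            return (list(combo), RESOLUTIONS[len(combo)])
        if len(overlapping) > 1:
            return None  # ambiguous
        if len(disjoint_pairs) == 1:
            return (list(disjoint_pairs[0]), "duplicated_pair")
        if disjoint_pairs:
            return None
    return None


def resolve_addresses(
    result: ScoringResult,
    layout: PoolLayout,
    pm: PhysicalMap,
    max_per_axis: int = 4,
) -> tuple[list[BACAddress], list[str]]:
    """Turn a scoring result into BAC addresses.

    Probes with direct well assignments (semi-automated / manual completion)
    are taken as-is; all other probes with at least one positive pool per
    axis go through covering-set resolution.  Returns the addresses and the
    list of unresolved probe IDs (probes with positives that could not be
    resolved).
    """
    addresses: list[BACAddress] = []
    unresolved: list[str] = []
    for probe_id, wells in result.assigned.items():
        bacs = [pm.bac_at(w) for w in wells]
        if None in bacs:
            unresolved.append(probe_id)
            continue
        if len(wells) == 1:
            resolution = "unique"
        elif _mutually_overlapping(bacs, pm):
            resolution = RESOLUTIONS[len(wells)]
        else:
            resolution = "duplicated_pair"
        res_label = "unique" if resolution == "duplicated_pair" else resolution
        for well, bac in zip(wells, bacs):
            addresses.append(
                BACAddress(probe_id, bac, well, result.method, res_label)
            )
    for probe_id, call in result.calls.items():
        if probe_id in result.assigned:
            continue
        if call.n_positive == 0:
            continue
        coords = {
            a: [layout.coord_of(pid) for pid in call.positives[a]] for a in AXES
        }
        resolved = resolve_probe(coords, pm, max_per_axis=max_per_axis)
        if resolved is None:
            unresolved.append(probe_id)
            continue
        wells, resolution = resolved
        res_label = "unique" if resolution == "duplicated_pair" else resolution
        for well in wells:
            addresses.append(
                BACAddress(probe_id, pm.bac_at(well), well, result.method, res_label)
            )
    return addresses, unresolved


# ---------------------------------------------------------------------------
# repeat-probe filtering


def te_filter(
    probes: Mapping[str, str],
    library: RepeatLibrary,
    min_identity: float = 0.80,
    min_span_nt: int = 45,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[set[str], pd.DataFrame]:
    """Flag probes whose best local alignment to any repeat reaches
    ``min_identity`` over at least ``min_span_nt`` alignment columns.

    Returns the flagged probe IDs and a per-probe table of the best
    alignment found (by score; identity and span are those of that
    alignment), so stricter identity cut-offs can be applied downstream.
    """
    flagged: set[str] = set()
    rows = []
    for probe_id, seq in probes.items():
        best: LocalAlignment | None = None
        best_repeat = None
        for rep_id, rep_seq in library.sequences.items():
            aln = smith_waterman(seq, rep_seq, match=match, mismatch=mismatch, gap=gap)
            if best is None or aln.score > best.score:
                best = aln
                best_repeat = rep_id
        hit = (
            best is not None
            and best.span >= min_span_nt
            and best.identity >= min_identity
        )
        if hit:
            flagged.add(probe_id)
        rows.append(
            {
                "probe_id": probe_id,
                "repeat_id": best_repeat if best and best.score > 0 else None,
                "score": best.score if best else 0.0,
                "identity_pct": 100.0 * best.identity if best else 0.0,
                "span_nt": best.span if best else 0,
                "flagged": hit,
            }
        )
    return flagged, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loci


def build_loci(addresses: Sequence[BACAddress], pm: PhysicalMap) -> list[GeneLocus]:
    """Merge each probe's addresses into loci.

    Addresses of one probe on mutually overlapping BACs form one locus;
    disjoint placements become separate loci flagged ``duplicated``.  Locus
    IDs are assigned deterministically in probe order.
    """
    by_probe: dict[str, list[BACAddress]] = {}
    for addr in addresses:
        by_probe.setdefault(addr.probe_id, []).append(addr)
    loci: list[GeneLocus] = []
    counter = 0
    for probe_id in sorted(by_probe):
        addrs = by_probe[probe_id]
        bacs = sorted({a.bac_id for a in addrs})
        # connected components under the overlap relation
        parent = {b: b for b in bacs}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in itertools.combinations(bacs, 2):
            if pm.overlap(a, b):
                parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for b in bacs:
            groups.setdefault(find(b), []).append(b)
        duplicated = len(groups) > 1
        method = addrs[0].method
        for root in sorted(groups):
            members = tuple(sorted(groups[root]))
            contigs = {pm.contig_of(b) for b in members}
            if len(contigs) != 1:
                raise ValueError(
                    f"locus for probe {probe_id} spans contigs {sorted(contigs)}"
                )
            counter += 1
            loci.append(
                GeneLocus(
                    locus_id=f"L{counter:05d}",
                    probe_id=probe_id,
                    bac_ids=members,
                    contig_id=contigs.pop(),
                    method=method,
                    duplicated=duplicated,
                )
            )
    return loci


def assign_bins(loci: Sequence[GeneLocus], pm: PhysicalMap) -> dict:
    """Assign each locus the deletion bin of its contig (in place).

    Returns a summary with the assigned / not-assigned split.
    """
    assigned = 0
    for locus in loci:
        bins = {pm.bin_of_bac(b) for b in locus.bac_ids}
        bins_present = {b for b in bins if b is not None}
        if len(bins_present) > 1:
            raise ValueError(
                f"locus {locus.locus_id} maps to conflicting bins {sorted(bins_present)}"
            )
        locus.bin = bins_present.pop() if bins_present else None
        assigned += locus.bin is not None
    return {
        "n_loci": len(loci),
        "assigned": assigned,
        "not_assigned": len(loci) - assigned,
    }


def loci_frame(loci: Sequence[GeneLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "probe_id": l.probe_id,
                "bac_ids": ",".join(l.bac_ids),
                "contig": l.contig_id,
                "bin": l.bin,
                "method": l.method,
                "duplicated": l.duplicated,
            }
            for l in loci
        ]
    )


# ---------------------------------------------------------------------------
# validation against independent annotation


def validate_against_annotation(
    loci: Sequence[GeneLocus],
    annotation: Mapping[str, Mapping[str, bool]],
    annotated_contigs: Iterable[str],
) -> dict:
    """Confirmation rates of hybridisation placements on annotated contigs.

    ``annotation`` maps probe_id to ``{"hit": bool, "expected": bool}`` —
    whether the probe's sequence hits the annotated contig at all, and
    whether the hit falls at the expected location.  Only loci on
    ``annotated_contigs`` are evaluated.  Fractions are percentages
    (rounded to the nearest integer), ``None`` when undefined.
    """
    contigs = set(annotated_contigs)
    placed = [l for l in loci if l.contig_id in contigs]
    n_placed = len(placed)
    hits = [l for l in placed if annotation.get(l.probe_id, {}).get("hit", False)]
    n_hit = len(hits)
    n_expected = sum(
        1 for l in hits if annotation.get(l.probe_id, {}).get("expected", False)
    )
    return {
        "n_placed": n_placed,
        "n_hit": n_hit,
        "n_at_expected": n_expected,
        "pct_hit": round(100.0 * n_hit / n_placed) if n_placed else None,
        "pct_at_expected": round(100.0 * n_expected / n_hit) if n_hit else None,
    }


# ---------------------------------------------------------------------------
# orchestration


def deconvolve_all(
    scoring_results: Sequence[ScoringResult],
    layout: PoolLayout,
    pm: PhysicalMap,
    max_per_axis: int = 4,
) -> tuple[list[BACAddress], pd.DataFrame]:
    """Combine scoring methods with fixed precedence.

    Methods are applied in the order given (convention: automated, boxplot,
    semi_automated, manual); the first method that resolves a probe wins.
    Boxplot calls are kept only when they resolve to two or more overlapping
    BACs (the method is too permissive for single-well calls).  Returns the
    combined addresses and a log of every method's call per probe.
    """
    claimed: set[str] = set()
    combined: list[BACAddress] = []
    log_rows = []
    for result in scoring_results:
        addresses, unresolved = resolve_addresses(
            result, layout, pm, max_per_axis=max_per_axis
        )
        by_probe: dict[str, list[BACAddress]] = {}
        for addr in addresses:
            by_probe.setdefault(addr.probe_id, []).append(addr)
        for probe_id, addrs in by_probe.items():
            keep = probe_id not in claimed
            if keep and result.method == "boxplot":
                keep = all(
                    a.resolution in ("overlapping_pair", "overlapping_triple")
                    for a in addrs
                )
            log_rows.append(
                {
                    "probe_id": probe_id,
                    "method": result.method,
                    "bac_ids": ",".join(sorted(a.bac_id for a in addrs)),
                    "resolution": addrs[0].resolution,
                    "kept": keep,
                }
            )
            if keep:
                combined.extend(addrs)
                claimed.add(probe_id)
        for probe_id in unresolved:
            log_rows.append(
                {
                    "probe_id": probe_id,
                    "method": result.method,
                    "bac_ids": "",
                    "resolution": "unresolved",
                    "kept": False,
                }
            )
    return combined, pd.DataFrame(log_rows)
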