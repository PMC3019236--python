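"""Domain model of the physical map and reference tables, with TSV/FASTA readers.

Coordinates are 0-based half-open base pairs throughout; megabases are
``bp / 1e6`` exactly.  Well addresses use 1-based plate numbers, letter rows
and 1-based column numbers (formatted ``P01`` / ``A`` / ``1``).  All tabular
formats are tab-separated with ``#`` comment lines.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

AXES = ("plate", "row", "column")

ROW_LETTERS = string.ascii_uppercase

_SINGLETON_PREFIX = "sgl:"


class PhysicalMapError(ValueError):
    """Raised when a physical-map file violates a structural invariant."""


class SignalMatrixError(ValueError):
    """Raised when a signal-matrix file is malformed."""


Well = tuple[int, str, int]


def format_well(well: Well) -> str:
    plate, row, column = well
    return f"P{plate:02d}-{row}{column:02d}"


@dataclass(frozen=True)
class BACRecord:
    """One BAC clone: its well address and (optionally) its map placement.

    ``contig_id`` is ``None`` for singletons; the :class:`PhysicalMap`
    constructor gives every singleton a pseudo-contig of one BAC.
    ``start_bp`` / ``end_bp`` are chromosome coordinates, ``None`` when the
    contig is unplaced.
    """

    bac_id: str
    plate: int
    row: str
    column: int
    contig_id: str | None = None
    start_bp: int | None = None
    end_bp: int | None = None

    @property
    def well(self) -> Well:
        return (self.plate, self.row, self.column)

    @property
    def is_singleton(self) -> bool:
        return self.contig_id is None

    def __post_init__(self) -> None:
        if self.start_bp is not None and self.end_bp is not None:
            if self.end_bp <= self.start_bp:
                raise PhysicalMapError(
                    f"BAC {self.bac_id}: end_bp ({self.end_bp}) must exceed "
                    f"start_bp ({self.start_bp})"
                )


@dataclass
class DeletionBin:
    """A deletion-line interval used as a coarse mapping unit.

    ``contig_length_mb`` is the cumulative length of contigs assigned to the
    bin; ``full_size_mb`` (the physical size of the bin) and
    ``midpoint_dist_mb`` (distance from the centromere to the bin midpoint)
    are optional because they come from cytogenetic data, not from the map
    file itself.
    """

    name: str
    arm: str | None = None
    contig_length_mb: float | None = None
    full_size_mb: float | None = None
    midpoint_dist_mb: float | None = None


class PhysicalMap:
    """BACs, contigs, the overlap relation and contig-to-bin assignments.

    The overlap relation is derived from coordinate intersection of BACs of
    the same contig (half-open intervals: abutting BACs do not overlap).
    """

    def __init__(
        self,
        bacs: Iterable[BACRecord],
        bin_of: Mapping[str, str | None] | None = None,
        bins: list[DeletionBin] | None = None,
    ) -> None:
        self.bacs: dict[str, BACRecord] = {}
        self.well_index: dict[Well, str] = {}
        self.contigs: dict[str, list[str]] = {}
        raw_bin_of = dict(bin_of or {})
        for rec in bacs:
            if rec.bac_id in self.bacs:
                raise PhysicalMapError(f"duplicate bac_id {rec.bac_id}")
            if rec.well in self.well_index:
                other = self.well_index[rec.well]
                raise PhysicalMapError(
                    f"duplicate well address {format_well(rec.well)} shared by "
                    f"{other} and {rec.bac_id}"
                )
            self.bacs[rec.bac_id] = rec
            self.well_index[rec.well] = rec.bac_id
            contig = self._contig_key(rec)
            self.contigs.setdefault(contig, []).append(rec.bac_id)
        for contig, members in self.contigs.items():
            members.sort(
                key=lambda b: (
                    self.bacs[b].start_bp if self.bacs[b].start_bp is not None else -1,
                    b,
                )
            )
        self.bin_of: dict[str, str | None] = {
            contig: raw_bin_of.get(contig) for contig in self.contigs
        }
        self.overlaps: set[frozenset[str]] = self._derive_overlaps()
        if bins is not None:
            self.bins = bins
        else:
            seen: dict[str, DeletionBin] = {}
            for contig in self.contigs:
                name = self.bin_of.get(contig)
                if name is not None and name not in seen:
                    seen[name] = DeletionBin(name=name)
            self.bins = list(seen.values())
        self._update_bin_lengths()

    @staticmethod
    def _contig_key(rec: BACRecord) -> str:
        return rec.contig_id if rec.contig_id is not None else _SINGLETON_PREFIX + rec.bac_id

    def _derive_overlaps(self) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        for members in self.contigs.values():
            recs = [self.bacs[b] for b in members]
            for i, a in enumerate(recs):
                if a.start_bp is None:
                    continue
                for b in recs[i + 1 :]:
                    if b.start_bp is None:
                        continue
                    if a.start_bp < b.end_bp and b.start_bp < a.end_bp:
                        pairs.add(frozenset((a.bac_id, b.bac_id)))
        return pairs

    def _update_bin_lengths(self) -> None:
        lengths: dict[str, float] = {}
        for contig in self.contigs:
            name = self.bin_of.get(contig)
            if name is None:
                continue
            lengths[name] = lengths.get(name, 0.0) + self.contig_length_bp(contig)
        for b in self.bins:
            if b.name in lengths:
                b.contig_length_mb = lengths[b.name] / 1e6

    # -- queries -----------------------------------------------------------

    def overlap(self, bac_a: str, bac_b: str) -> bool:
        return frozenset((bac_a, bac_b)) in self.overlaps

    def contig_of(self, bac_id: str) -> str:
        return self._contig_key(self.bacs[bac_id])

    def bac_at(self, well: Well) -> str | None:
        return self.well_index.get(well)

    def contig_length_bp(self, contig_id: str) -> int:
        members = [self.bacs[b] for b in self.contigs[contig_id]]
        starts = [m.start_bp for m in members if m.start_bp is not None]
        ends = [m.end_bp for m in members if m.end_bp is not None]
        if not starts:
            return 0
        return max(ends) - min(starts)

    def bin_of_bac(self, bac_id: str) -> str | None:
        return self.bin_of.get(self.contig_of(bac_id))

    def bac_interval(self, bac_id: str) -> tuple[int, int] | None:
        rec = self.bacs[bac_id]
        if rec.start_bp is None:
            return None
        return (rec.start_bp, rec.end_bp)

    def __len__(self) -> int:
        return len(self.bacs)


# ---------------------------------------------------------------------------
# reference tables


@dataclass
class GeneticMap:
    """A genetic map (marker, chromosome, position in cM) plus the rule for
    linking probes to markers (minimum identity %, minimum aligned length nt)."""

    entries: pd.DataFrame  # columns marker_id, chromosome, position_cM
    min_identity_pct: float = 85.0
    min_length_nt: int = 100

    def __post_init__(self) -> None:
        if (self.entries["position_cM"] < 0).any():
            raise ValueError("genetic map positions must be >= 0 cM")
        if self.entries["marker_id"].duplicated().any():
            dup = self.entries["marker_id"][self.entries["marker_id"].duplicated()]
            raise ValueError(f"duplicated markers in genetic map: {sorted(set(dup))}")

    def position(self, marker_id: str) -> tuple[str, float]:
        row = self.entries.loc[self.entries["marker_id"] == marker_id].iloc[0]
        return (row["chromosome"], float(row["position_cM"]))


@dataclass
class OrthologTable:
    """Probe-to-rice-ortholog table: chromosome and ordinal gene index.

    Ordinal indices follow the reference genome's gene-numbering annotation
    and must be unique within a chromosome.
    """

    entries: pd.DataFrame  # columns probe_id, chromosome, ordinal_index

    def __post_init__(self) -> None:
        dup = self.entries.duplicated(subset=["chromosome", "ordinal_index"])
        if dup.any():
            raise ValueError("ordinal_index must be unique within a chromosome")

    def lookup(self, probe_id: str) -> tuple[str, int] | None:
        hit = self.entries.loc[self.entries["probe_id"] == probe_id]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return (row["chromosome"], int(row["ordinal_index"]))


@dataclass
class RepeatLibrary:
    """Nucleotide repeat sequences used to flag cross-hybridising probes."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValueError(
                    f"repeat {name} contains non-ACGTN characters: {sorted(bad)}"
                )
            self.sequences[name] = seq.upper()


# ---------------------------------------------------------------------------
# readers / writers

_MAP_COLUMNS = ["bac_id", "plate", "row", "column", "contig_id", "start_bp", "end_bp", "bin"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_physical_map(
    path: str | Path, known_bins: Iterable[str] | None = None
) -> PhysicalMap:
    """Read a physical map TSV (columns ``bac_id plate row column contig_id
    start_bp end_bp bin``; empty fields for singletons / unplaced contigs).

    Bin order is taken from first appearance in the file; bin names are
    opaque labels.  When ``known_bins`` is given, any other bin name is
    rejected with its line number.
    """
    df = _read_tsv(path)
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PhysicalMapError(f"{path}: missing columns {missing}")
    known = set(known_bins) if known_bins is not None else None
    records: list[BACRecord] = []
    bin_of: dict[str, str | None] = {}
    bin_order: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header line
        contig = row["contig_id"] or None
        start = int(row["start_bp"]) if row["start_bp"] != "" else None
        end = int(row["end_bp"]) if row["end_bp"] != "" else None
        if start is not None and end is not None and end <= start:
            raise PhysicalMapError(
                f"{path}:{line}: end_bp ({end}) <= start_bp ({start}) for {row['bac_id']}"
            )
        bin_name = row["bin"] or None
        if bin_name is not None:
            if known is not None and bin_name not in known:
                raise PhysicalMapError(f"{path}:{line}: unknown bin name {bin_name!r}")
            if bin_name not in bin_order:
                bin_order.append(bin_name)
            if contig is not None:
                previous = bin_of.get(contig)
                if previous is not None and previous != bin_name:
                    raise PhysicalMapError(
                        f"{path}:{line}: contig {contig} assigned to both "
                        f"{previous!r} and {bin_name!r}"
                    )
                bin_of[contig] = bin_name
            else:
                bin_of[_SINGLETON_PREFIX + row["bac_id"]] = bin_name
        records.append(
            BACRecord(
                bac_id=row["bac_id"],
                plate=int(row["plate"]),
                row=row["row"],
                column=int(row["column"]),
                contig_id=contig,
                start_bp=start,
                end_bp=end,
            )
        )
    bins = [DeletionBin(name=name) for name in bin_order]
    return PhysicalMap(records, bin_of=bin_of, bins=bins)


def write_physical_map(pm: PhysicalMap, path: str | Path) -> None:
    """Write a physical map in the same TSV layout :func:`read_physical_map` reads."""
    rows = []
    for rec in pm.bacs.values():
        contig = pm.contig_of(rec.bac_id)
        rows.append(
            {
                "bac_id": rec.bac_id,
                "plate": rec.plate,
                "row": rec.row,
                "column": rec.column,
                "contig_id": rec.contig_id or "",
                "start_bp": rec.start_bp if rec.start_bp is not None else "",
                "end_bp": rec.end_bp if rec.end_bp is not None else "",
                "bin": pm.bin_of.get(contig) or "",
            }
        )
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bin_geometry(path: str | Path) -> list[DeletionBin]:
    """Read optional bin geometry: ``bin arm contig_length_mb full_size_mb
    midpoint_dist_mb`` (empty fields allowed for the optional sizes)."""
    df = _read_tsv(path)
    bins = []
    for _, row in df.iterrows():
        bins.append(
            DeletionBin(
                name=row["bin"],
                arm=row.get("arm") or None,
                contig_length_mb=float(row["contig_length_mb"])
                if row.get("contig_length_mb")
                else None,
                full_size_mb=float(row["full_size_mb"]) if row.get("full_size_mb") else None,
                midpoint_dist_mb=float(row["midpoint_dist_mb"])
                if row.get("midpoint_dist_mb")
                else None,
            )
        )
    return bins


def read_signal_matrix(path: str | Path, layout) -> "SignalMatrix":
    """Read a probe x pool intensity TSV.

    The first column is the probe identifier; the remaining columns must be
    exactly the layout's pool IDs (any order; reordered to layout order).
    Values must be non-negative and finite.
    """
    from poolanchor.pooling import SignalMatrix  # avoid a module cycle

    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    expected = list(layout.pool_ids())
    got = list(df.columns)
    missing = sorted(set(expected) - set(got))
    extra = sorted(set(got) - set(expected))
    if missing or extra:
        raise SignalMatrixError(
            f"{path}: pool columns do not match layout "
            f"(missing {missing}, unexpected {extra})"
        )
    df = df[expected]
    if df.isna().any().any():
        probe = df.index[df.isna().any(axis=1)][0]
        pool = df.columns[df.loc[probe].isna()][0]
        raise SignalMatrixError(f"{path}: NaN value for probe {probe}, pool {pool}")
    values = df.to_numpy(dtype=float)
    if not (values >= 0).all() or not pd.notna(values).all():
        bad = df[(df < 0).any(axis=1)]
        probe = bad.index[0] if not bad.empty else "?"
        raise SignalMatrixError(f"{path}: negative intensity for probe {probe}")
    return SignalMatrix(data=df.astype(float), state="raw")


def read_genetic_map(
    path: str | Path, min_identity_pct: float = 85.0, min_length_nt: int = 100
) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = ["marker_id", "chromosome", "position_cM"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return GeneticMap(
        entries=df[need].copy(),
        min_identity_pct=min_identity_pct,
        min_length_nt=min_length_nt,
    )


def read_ortholog_table(path: str | Path) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = ["probe_id", "chromosome", "ordinal_index"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return OrthologTable(entries=df[need].copy())


def read_repeat_library(path: str | Path) -> RepeatLibrary:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return RepeatLibrary(sequences=seqs)


def read_probe_sequences(path: str | Path) -> dict[str, str]:
    """Read probe 60-mers from FASTA (id -> sequence)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
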