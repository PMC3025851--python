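"""Specificity-determining position (SDP) scan over protein alignments.

Given an aligned set of receptor ligand-binding-domain (LBD) sequences split
into two functional groups — e.g. mineralocorticoid-sensitive versus
-insensitive GRs — the scan reports every alignment column whose residue is
conserved within each group but differs between the groups. Such columns are
the classic candidates for residues controlling ligand specificity.

Columns containing a gap in any sequence are never reported: a gap-versus-
residue difference reflects an indel, not a substitution, and cannot be
interpreted as a specificity switch.

A small coordinate helper maps 1-based LBD alignment positions onto
full-length receptor numbering (LBD position 1 sits at residue 538 of the
full-length mouse GR and 532 of the human GR).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, InputError, ParseError

__all__ = [
    "LBD_OFFSETS",
    "MsaAlignment",
    "DiscriminatingSite",
    "read_alignment",
    "write_alignment",
    "read_group_assignment",
    "scan_discriminating_sites",
    "map_lbd_position",
    "sites_table",
]

#: Full-length coordinate of LBD alignment position 1, minus 1, per species.
LBD_OFFSETS: dict[str, int] = {"mouse": 537, "human": 531}

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")


@dataclass(frozen=True)
class MsaAlignment:
    """A protein multiple alignment; columns are 1-based."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InputError("alignment needs >= 2 sequences")
        ids = [rid for rid, _ in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ParseError(f"duplicate sequence ids: {sorted(dupes)}")
        length = len(self.records[0][1])
        for rid, seq in self.records:
            if len(seq) != length:
                raise ParseError(
                    f"record {rid!r}: length {len(seq)} differs from first record ({length})"
                )
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ParseError(f"record {rid!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def column(self, col: int) -> dict[str, str]:
        """Residues at 1-based column ``col`` keyed by sequence id."""
        if not 1 <= col <= self.length:
            raise InputError(f"column {col} outside [1, {self.length}]")
        return {rid: seq[col - 1].upper() for rid, seq in self.records}


@dataclass(frozen=True)
class DiscriminatingSite:
    """An alignment column conserved within but differing between groups."""

    column: int
    residue_by_group: tuple[tuple[str, str], ...]  # (group label, residue)
    mapped_coords: tuple[tuple[str, int], ...] = ()

    def residues(self) -> dict[str, str]:
        return dict(self.residue_by_group)


def read_alignment(source: str | Path | IO[str]) -> MsaAlignment:
    """Read an aligned FASTA file (gaps as '-'); ids cut at first whitespace."""
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse FASTA: {exc}") from exc
    if not records:
        raise ParseError("FASTA stream contains no sequences")
    return MsaAlignment(records=tuple(records))


def write_alignment(aln: MsaAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


def read_group_assignment(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a two-column ``id,group`` CSV into a mapping."""
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ParseError("group assignment CSV needs two columns (id, group)")
    idc, grpc = df.columns[:2]
    if df[idc].duplicated().any():
        raise ParseError(f"duplicate ids in group assignment: {sorted(df[idc][df[idc].duplicated()])}")
    return {str(i): str(g) for i, g in zip(df[idc], df[grpc])}


def scan_discriminating_sites(
    aln: MsaAlignment, groups: Mapping[str, str]
) -> list[DiscriminatingSite]:
    """Report columns conserved within each group but different between them.

    A column qualifies iff all group-A residues are identical, all group-B
    residues are identical, the two residues differ, and no grouped sequence
    carries a gap there. Output is sorted by column. Exactly two group
    labels are required; every assigned id must exist in the alignment.
    Sequences not assigned to a group are ignored.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ConfigError(f"group assignment must define exactly 2 groups, got {labels}")
    missing = sorted(set(groups) - set(aln.ids))
    if missing:
        raise InputError(f"group assignment names ids absent from the alignment: {missing}")
    members = {lab: [rid for rid in aln.ids if groups.get(rid) == lab] for lab in labels}
    for lab, mem in members.items():
        if not mem:
            raise ConfigError(f"group {lab!r} has no sequences")

    sites: list[DiscriminatingSite] = []
    for col in range(1, aln.length + 1):
        residues = aln.column(col)
        per_group = {lab: {residues[rid] for rid in mem} for lab, mem in members.items()}
        if any(len(s) != 1 for s in per_group.values()):
            continue
        ra, rb = (next(iter(per_group[lab])) for lab in labels)
        if ra == rb or "-" in (ra, rb):
            continue
        sites.append(
            DiscriminatingSite(
                column=col, residue_by_group=((labels[0], ra), (labels[1], rb))
            )
        )
    return sites


def map_lbd_position(
    column: int, species: str, offsets: Mapping[str, int] = LBD_OFFSETS
) -> int:
    """Map a 1-based LBD alignment position to full-length receptor numbering."""
    if column < 1:
        raise InputError(f"column must be >= 1, got {column}")
    try:
        return column + offsets[species]
    except KeyError:
        raise ConfigError(
            f"species {species!r} has no configured LBD offset (known: {sorted(offsets)})"
        ) from None


def sites_table(sites: Iterable[DiscriminatingSite],
                offsets: Mapping[str, int] = LBD_OFFSETS) -> pd.DataFrame:
    """Serialize scan output: one row per site with mapped coordinates."""
    rows = []
    for s in sites:
        row: dict[str, object] = {"column": s.column}
        for lab, res in s.residue_by_group:
            row[f"residue_{lab}"] = res
        for sp, off in offsets.items():
            row[f"{sp}_coord"] = s.column + off
        rows.append(row)
    return pd.DataFrame(rows)
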