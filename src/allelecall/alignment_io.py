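"""Haplotype-alignment and region-map containers and I/O.

The universal substrate of the pipeline is a gap-aware multiple alignment of
haplotype sequences over the alphabet ``{A, C, G, T, N, -}`` together with a
region map assigning alignment intervals to functional classes: the 5' region
upstream of the start codon, coding exons, introns, the 3' region, and a
co-genomic neutral *baseline* sequence (an intergenic stretch or a long
intron) used as the background-mutation reference.

Coordinates are 0-based half-open throughout the library; human-facing
reports printed by the CLI convert to 1-based inclusive.  Only the '+'
strand is supported: inputs must be pre-oriented.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from allelecall.errors import AlignmentError, FormatError, RegionError

ALPHABET = frozenset("ACGTN-")
GAP = "-"

#: taxon roles an aligned haplotype may play
ROLES = ("hybrid", "parent_a", "parent_b", "outgroup")

#: region classes of the allele span plus the neutral baseline
REGION_TYPES = ("five_prime", "exon", "intron", "three_prime", "baseline")


@dataclass(frozen=True)
class AlignedHaplotype:
    """One gap-aware sequence in an alignment.

    Parameters
    ----------
    id : str
        Unique identifier within the alignment.
    sequence : str
        Residues over ``{A, C, G, T, N, -}``; uppercased on construction.
    taxon_role : str
        One of ``hybrid``, ``parent_a``, ``parent_b``, ``outgroup``.
    subgroup : str or None
        Optional population label of the carrier (e.g. ``indica``).
    """

    id: str
    sequence: str
    taxon_role: str = "hybrid"
    subgroup: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise FormatError("haplotype id must be non-empty")
        if not self.sequence:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise FormatError(f"{self.id}: illegal symbols {sorted(bad)}")
        if self.taxon_role not in ROLES:
            raise FormatError(f"{self.id}: unknown taxon_role {self.taxon_role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def degapped(self) -> str:
        return self.sequence.replace(GAP, "")

    def slice(self, start: int, end: int) -> "AlignedHaplotype":
        return AlignedHaplotype(
            self.id, self.sequence[start:end], self.taxon_role, self.subgroup
        )


class HaplotypeAlignment:
    """An ordered collection of equal-length :class:`AlignedHaplotype`.

    At most one haplotype each may carry the ``parent_a``, ``parent_b`` and
    ``outgroup`` roles; any number may be ``hybrid``.
    """

    def __init__(self, members: Iterable[AlignedHaplotype]):
        self.members: list[AlignedHaplotype] = list(members)
        if not self.members:
            raise AlignmentError("alignment needs at least one sequence")
        self.n_columns = len(self.members[0])
        seen: set[str] = set()
        role_count: dict[str, int] = {}
        for m in self.members:
            if len(m) != self.n_columns:
                raise AlignmentError(
                    f"{m.id}: length {len(m)} != {self.n_columns} of first record"
                )
            if m.id in seen:
                raise FormatError(f"duplicate haplotype id {m.id!r}")
            seen.add(m.id)
            role_count[m.taxon_role] = role_count.get(m.taxon_role, 0) + 1
        for role in ("parent_a", "parent_b", "outgroup"):
            if role_count.get(role, 0) > 1:
                raise FormatError(f"more than one haplotype with role {role!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[AlignedHaplotype]:
        return iter(self.members)

    def __getitem__(self, hap_id: str) -> AlignedHaplotype:
        for m in self.members:
            if m.id == hap_id:
                return m
        raise KeyError(hap_id)

    def by_role(self, role: str) -> AlignedHaplotype | None:
        """Return the single haplotype with ``role``, or None."""
        for m in self.members:
            if m.taxon_role == role:
                return m
        return None

    @property
    def hybrids(self) -> list[AlignedHaplotype]:
        return [m for m in self.members if m.taxon_role == "hybrid"]

    @property
    def parent_a(self) -> AlignedHaplotype | None:
        return self.by_role("parent_a")

    @property
    def parent_b(self) -> AlignedHaplotype | None:
        return self.by_role("parent_b")

    @property
    def outgroup(self) -> AlignedHaplotype | None:
        return self.by_role("outgroup")

    def slice(self, start: int, end: int) -> "HaplotypeAlignment":
        if not (0 <= start < end <= self.n_columns):
            raise RegionError(f"slice [{start}, {end}) outside [0, {self.n_columns})")
        return HaplotypeAlignment(m.slice(start, end) for m in self.members)


@dataclass(frozen=True)
class Region:
    """One typed interval of a :class:`GeneRegionMap` (0-based half-open)."""

    region_type: str
    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.region_type not in REGION_TYPES:
            raise RegionError(f"unknown region_type {self.region_type!r}")
        if self.end <= self.start or self.start < 0:
            raise RegionError(
                f"degenerate interval [{self.start}, {self.end}) for "
                f"{self.region_type} {self.index}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneRegionMap:
    """Typed intervals of one locus in alignment coordinates.

    Invariants enforced at construction: intervals lie within the alignment,
    same-type intervals do not overlap, and exons are ordered 5'->3'.
    """

    locus: str
    regions: list[Region] = field(default_factory=list)
    n_columns: int | None = None

    def __post_init__(self) -> None:
        by_type: dict[str, list[Region]] = {}
        for r in self.regions:
            if self.n_columns is not None and r.end > self.n_columns:
                raise RegionError(
                    f"{self.locus}: {r.region_type} {r.index} ends at {r.end} "
                    f"beyond alignment width {self.n_columns}"
                )
            by_type.setdefault(r.region_type, []).append(r)
        for rtype, rs in by_type.items():
            rs_sorted = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs_sorted, rs_sorted[1:]):
                if b.start < a.end:
                    raise RegionError(
                        f"{self.locus}: overlapping {rtype} intervals "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
        exons = by_type.get("exon", [])
        if [e.index for e in sorted(exons, key=lambda r: r.start)] != sorted(
            e.index for e in exons
        ):
            raise RegionError(f"{self.locus}: exon indices not ordered 5'->3'")

    def of_type(self, region_type: str) -> list[Region]:
        return sorted(
            (r for r in self.regions if r.region_type == region_type),
            key=lambda r: r.start,
        )

    def get(self, region_type: str, index: int) -> Region:
        for r in self.regions:
            if r.region_type == region_type and r.index == index:
                return r
        raise RegionError(f"{self.locus}: no {region_type} with index {index}")

    def region_type_at(self, column: int) -> str | None:
        """Region class covering ``column``, or None if unassigned."""
        for r in self.regions:
            if r.start <= column < r.end:
                return r.region_type
        return None

    def aligned_length(self, region_type: str) -> int:
        return sum(r.length for r in self.of_type(region_type))

    def exon_columns(self) -> list[int]:
        """Alignment columns of the concatenated exons, 5'->3'."""
        cols: list[int] = []
        for e in self.of_type("exon"):
            cols.extend(range(e.start, e.end))
        return cols

    def coding_length(self, reference: AlignedHaplotype) -> int:
        """Degapped length of the concatenated exons in ``reference``."""
        return sum(
            1 for c in self.exon_columns() if reference.sequence[c] != GAP
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_role_map(path: str | os.PathLike) -> dict[str, tuple[str, str | None]]:
    """Read a role map TSV: ``id  taxon_role  [subgroup]``."""
    roles: dict[str, tuple[str, str | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"role map line needs >=2 columns: {line!r}")
            subgroup = parts[2] if len(parts) > 2 and parts[2] else None
            roles[parts[0]] = (parts[1], subgroup)
    return roles


def read_alignment(
    path: str | os.PathLike,
    role_map: Mapping[str, tuple[str, str | None]] | None = None,
) -> HaplotypeAlignment:
    """Read an aligned multi-FASTA into a validated :class:`HaplotypeAlignment`.

    Records absent from ``role_map`` default to the ``hybrid`` role.
    """
    role_map = role_map or {}
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role, subgroup = role_map.get(rec.id, ("hybrid", None))
        members.append(AlignedHaplotype(rec.id, str(rec.seq), role, subgroup))
    if not members:
        raise FormatError(f"{path}: no FASTA records")
    return HaplotypeAlignment(members)


def write_alignment(alignment: HaplotypeAlignment, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.id, description="") for m in alignment
    ]
    _atomic_write(path, lambda fh: SeqIO.write(records, fh, "fasta-2line"))


def read_region_map(
    path: str | os.PathLike, alignment: HaplotypeAlignment | None = None
) -> dict[str, GeneRegionMap]:
    """Read a 5-column region-map TSV (``locus region_type index start end``).

    ``#`` starts a comment line.  One file may describe several loci; the
    result maps locus name to its :class:`GeneRegionMap`.  When ``alignment``
    is given, intervals are checked against its width.
    """
    rows: dict[str, list[Region]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            locus, rtype, idx, start, end = parts
            try:
                region = Region(rtype, int(idx), int(start), int(end))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            rows.setdefault(locus, []).append(region)
    n_cols = alignment.n_columns if alignment is not None else None
    return {
        locus: GeneRegionMap(locus, regions, n_columns=n_cols)
        for locus, regions in rows.items()
    }


def write_region_map(
    maps: Mapping[str, GeneRegionMap] | GeneRegionMap, path: str | os.PathLike
) -> None:
    if isinstance(maps, GeneRegionMap):
        maps = {maps.locus: maps}

    def _write(fh) -> None:
        for locus in maps:
            for r in maps[locus].regions:
                fh.write(f"{locus}\t{r.region_type}\t{r.index}\t{r.start}\t{r.end}\n")

    _atomic_write(path, _write)


def slice_region(
    alignment: HaplotypeAlignment,
    region_map: GeneRegionMap,
    region_type: str,
    index: int = 0,
) -> HaplotypeAlignment:
    """Sub-alignment of exactly the columns of one mapped region."""
    region = region_map.get(region_type, index)
    return alignment.slice(region.start, region.end)


def _atomic_write(path: str | os.PathLike, writer) -> None:
    """Write via a temp file in the target directory, then atomic rename."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
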