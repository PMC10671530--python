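"""Lineage-specific mutation cataloguing.

Two modes are supported, matching the two data regimes:

* **hybrid mode** -- both parental reference haplotypes are present; a
  mutation is any event where a hybrid allele differs from BOTH parents
  (these are exactly the 'neither'-origin sites of the ancestry painting,
  plus merged indel events).
* **outgroup / frequency mode** -- no parents, but >= 10 conspecific
  haplotypes and an aligned outgroup; a polymorphic site whose minor-state
  frequency is below a threshold (default 0.30) is a *tentative* recent
  mutation, and tentative calls whose minor state equals the outgroup state
  are excluded as ancestral standing variation by parsimony.  The fraction
  excluded estimates the error rate of the frequency heuristic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from allelecall.alignment_io import (
    GAP,
    AlignedHaplotype,
    GeneRegionMap,
    HaplotypeAlignment,
)
from allelecall.alleles import AlleleSet, SiteDifference, find_homopolymer_runs
from allelecall.coding import CodingFrame
from allelecall.errors import PreconditionError
from allelecall.painting import informative_sites, paint

__all__ = [
    "MutationRecord",
    "PolarizationResult",
    "CodingFrame",
    "hybrid_mode_mutations",
    "classify_coding_effect",
    "polarize_with_outgroup",
    "sharing_class",
]


@dataclass
class MutationRecord:
    """One lineage-specific mutation event.

    ``carrier_alleles`` holds every allele (hybrid mode) or haplotype
    (outgroup mode) bearing the derived state; a mutation carried by several
    alleles still counts once at locus level.
    """

    id: str
    locus: str
    anchor_column: int
    kind: str  # substitution | indel
    length: int = 1
    region_type: str | None = None
    coding_effect: str = "not_applicable"
    derived_state: str = ""
    carrier_alleles: frozenset[str] = frozenset()
    sharing: str | None = None  # private | shared_within_subgroup | shared_across_subgroups
    mode: str = "hybrid"
    in_string: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.carrier_alleles:
            raise PreconditionError(f"{self.id}: carrier set must be non-empty")
        if (self.coding_effect != "not_applicable") != (self.region_type == "exon"):
            raise PreconditionError(
                f"{self.id}: coding_effect {self.coding_effect!r} inconsistent "
                f"with region {self.region_type!r}"
            )


def classify_coding_effect(
    event: SiteDifference, frame: CodingFrame
) -> str:
    """Coding effect of one exon event against a reference reading frame.

    Substitutions are classified codon-by-codon under the standard genetic
    code (a substitution creating a stop is ``nonsense``); indels are
    ``frameshift`` when the inserted/deleted residue count is not a multiple
    of 3 and in-frame (``nonsynonymous``) otherwise.
    """
    if event.region_type != "exon":
        raise PreconditionError(
            f"event at column {event.column} is {event.region_type}, not exon"
        )
    if event.kind == "indel":
        n_res = max(
            len(event.state_1.replace(GAP, "")),
            len(event.state_2.replace(GAP, "")),
        )
        return "frameshift" if n_res % 3 else "nonsynonymous"
    alt = event.state_2 if event.state_1 == frame.reference.sequence[event.column] else event.state_1
    return frame.classify_substitution(event.column, alt)


def sharing_class(
    record: MutationRecord, subgroup_of: dict[str, str | None]
) -> str:
    """Sharing pattern of a mutation across population subgroups."""
    groups = set()
    for carrier in record.carrier_alleles:
        sub = subgroup_of.get(carrier)
        if sub is None:
            raise PreconditionError(
                f"{record.id}: carrier {carrier} has no subgroup label"
            )
        groups.add(sub)
    if len(record.carrier_alleles) == 1:
        return "private"
    return (
        "shared_within_subgroup" if len(groups) == 1 else "shared_across_subgroups"
    )


def _derived_events(
    rep: AlignedHaplotype,
    pa: AlignedHaplotype,
    pb: AlignedHaplotype,
) -> list[tuple[int, int, str, str]]:
    """(start, end, kind, derived_state) events where ``rep`` differs from
    both parents, with contiguous same-pattern indel columns merged."""
    n = len(rep)
    events: list[tuple[int, int, str, str]] = []
    c = 0
    while c < n:
        r, a, b = rep.sequence[c], pa.sequence[c], pb.sequence[c]
        if "N" in (r, a, b) or r == a or r == b:
            c += 1
            continue
        if r == GAP:
            start = c
            while c < n:
                r2, a2, b2 = rep.sequence[c], pa.sequence[c], pb.sequence[c]
                if "N" in (r2, a2, b2) or r2 != GAP or a2 == GAP or b2 == GAP:
                    break
                c += 1
            events.append((start, c, "indel", rep.sequence[start:c]))
        elif a == GAP and b == GAP:
            start = c
            while c < n:
                r2, a2, b2 = rep.sequence[c], pa.sequence[c], pb.sequence[c]
                if "N" in (r2, a2, b2) or r2 == GAP or a2 != GAP or b2 != GAP:
                    break
                c += 1
            events.append((start, c, "indel", rep.sequence[start:c]))
        else:
            events.append((c, c + 1, "substitution", r))
            c += 1
    return events


def hybrid_mode_mutations(
    alleles: AlleleSet,
    alignment: HaplotypeAlignment,
    region_map: GeneRegionMap,
    min_run: int = 4,
) -> list[MutationRecord]:
    """Catalogue of events where >= 1 hybrid allele differs from both parents.

    One record per unique event: identical derived states at the same columns
    in several alleles collapse into one record carrying all of them (a
    derived state shared by ALL alleles is still a mutation -- fixed after
    hybridization).  Exon substitutions are classified against the reading
    frame of the locally matching parent according to each allele's ancestry
    painting; sharing labels are filled when all carriers have subgroup
    labels.
    """
    pa, pb = alignment.parent_a, alignment.parent_b
    if pa is None or pb is None:
        raise PreconditionError("hybrid mode needs both parental haplotypes")
    frames: dict[str, CodingFrame | None] = {}
    for which, ref in (("A", pa), ("B", pb)):
        try:
            frames[which] = CodingFrame(region_map, ref)
        except PreconditionError:
            frames[which] = None

    subgroup_of: dict[str, str | None] = {}
    grouped: dict[tuple[int, int, str, str], set[str]] = {}
    origin_of: dict[tuple[str, int], str] = {}
    for name, group in alleles.alleles.items():
        rep = alignment[group.representative]
        subgroup_of[name] = rep.subgroup
        try:
            painting = paint(
                informative_sites(rep, pa, pb), alignment.n_columns, rep.id
            )
        except Exception:
            painting = None
        for start, end, kind, state in _derived_events(rep, pa, pb):
            key = (start, end, kind, state)
            grouped.setdefault(key, set()).add(name)
            if painting is not None:
                try:
                    origin_of[(name, start)] = painting.origin_at(start)
                except Exception:
                    pass

    runs: list[tuple[int, int]] = []
    for m in [pa, pb] + [alignment[g.representative] for g in alleles.alleles.values()]:
        runs.extend(find_homopolymer_runs(m.sequence, min_run))

    records: list[MutationRecord] = []
    all_labeled = all(v is not None for v in subgroup_of.values())
    for k, (key, carriers) in enumerate(sorted(grouped.items()), start=1):
        start, end, kind, state = key
        rtype = region_map.region_type_at(start)
        effect = "not_applicable"
        if rtype == "exon":
            if kind == "indel":
                # event columns are base-vs-gap throughout, so the residue
                # count of the indel equals the column count
                effect = "frameshift" if (end - start) % 3 else "nonsynonymous"
            else:
                carrier = sorted(carriers)[0]
                origin = origin_of.get((carrier, start), "A")
                frame = frames.get(origin if origin in ("A", "B") else "A") or frames.get("A") or frames.get("B")
                if frame is not None and start in frame.col_to_pos:
                    effect = frame.classify_substitution(start, state)
                else:
                    effect = "nonsynonymous"
        record = MutationRecord(
            id=f"{alleles.locus}.m{k}",
            locus=alleles.locus,
            anchor_column=start,
            kind=kind,
            length=end - start,
            region_type=rtype,
            coding_effect=effect,
            derived_state=state,
            carrier_alleles=frozenset(carriers),
            mode="hybrid",
            in_string=any(start < r_end and r_start < end for r_start, r_end in runs),
        )
        if all_labeled:
            record.sharing = sharing_class(record, subgroup_of)
        records.append(record)
    return records


@dataclass
class PolarizationResult:
    """Outcome of outgroup/frequency polarization.

    ``tentative`` holds every low-frequency polymorphism; ``excluded`` the
    subset judged ancestral because the outgroup shares the minor state;
    ``unresolved`` the subset where the outgroup is gapped or missing data
    (retained, flagged).  ``error_rate`` = excluded / tentative.
    """

    tentative: list[MutationRecord] = field(default_factory=list)
    excluded: list[MutationRecord] = field(default_factory=list)
    retained: list[MutationRecord] = field(default_factory=list)
    unresolved: list[MutationRecord] = field(default_factory=list)

    @property
    def error_rate(self) -> float | None:
        if not self.tentative:
            return None
        return len(self.excluded) / len(self.tentative)

    @property
    def error_rate_report(self) -> float | None:
        """Error rate rounded half-up to 2 decimals, as reported."""
        rate = self.error_rate
        if rate is None:
            return None
        return float(Decimal(rate).quantize(Decimal("0.01"), ROUND_HALF_UP))


def polarize_with_outgroup(
    alignment: HaplotypeAlignment,
    outgroup: AlignedHaplotype | None = None,
    freq_threshold: float = 0.30,
    strict: bool = True,
    locus: str = "",
    region_map: GeneRegionMap | None = None,
) -> PolarizationResult:
    """Frequency-based mutation calls checked against an outgroup.

    Polymorphic columns among the conspecific (hybrid-role) haplotypes whose
    minor-state frequency is below ``freq_threshold`` (strictly, unless
    ``strict=False`` makes the comparison <=) become tentative recent
    mutations.  Frequency denominators exclude haplotypes with N or a gap at
    the column.  Tentative calls are excluded as ancestral when the outgroup
    carries the minor state; columns where the outgroup itself is gapped or N
    stay unresolved (retained with a flag), since parsimony cannot decide.
    """
    haps = alignment.hybrids
    if len(haps) < 10:
        warnings.warn(
            f"only {len(haps)} conspecific haplotypes (< 10); frequency-based "
            "polarization may be unreliable",
            stacklevel=2,
        )
    if outgroup is None:
        outgroup = alignment.outgroup

    frame: CodingFrame | None = None
    if region_map is not None and haps:
        try:
            frame = CodingFrame(region_map, haps[0])
        except PreconditionError:
            frame = None

    result = PolarizationResult()
    counter = 0
    for c in range(alignment.n_columns):
        states = [
            h.sequence[c] for h in haps if h.sequence[c] not in ("N", GAP)
        ]
        if len(states) < 2:
            continue
        counts = Counter(states)
        if len(counts) < 2:
            continue
        total = len(states)
        major, _ = counts.most_common(1)[0]
        for state, n in counts.items():
            if state == major:
                continue
            freq = n / total
            below = freq < freq_threshold if strict else freq <= freq_threshold
            if not below:
                continue
            counter += 1
            carriers = frozenset(
                h.id for h in haps if h.sequence[c] == state
            )
            rtype = region_map.region_type_at(c) if region_map else None
            effect = "not_applicable"
            if rtype == "exon":
                if frame is not None and c in frame.col_to_pos:
                    effect = frame.classify_substitution(c, state)
                else:
                    effect = "nonsynonymous"
            record = MutationRecord(
                id=f"{locus or 'locus'}.p{counter}",
                locus=locus,
                anchor_column=c,
                kind="substitution",
                region_type=rtype,
                coding_effect=effect,
                derived_state=state,
                carrier_alleles=carriers,
                mode="outgroup",
            )
            result.tentative.append(record)
            og_state = outgroup.sequence[c] if outgroup is not None else None
            if og_state is None or og_state in ("N", GAP):
                record.flags = ("outgroup_unresolved",)
                result.unresolved.append(record)
                result.retained.append(record)
            elif og_state == state:
                result.excluded.append(record)
            else:
                result.retained.append(record)
    return result
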