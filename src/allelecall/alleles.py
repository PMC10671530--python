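"""Grouping hybrid haplotypes into alleles and allelets.

An *allele* here is the functional unit of a gene: the ~1 kb 5' region, the
coding exons (with or without introns) and at least 100 bp of 3' region.
Two haplotypes belong to different alleles when they differ by at least one
*defining mutation*:

* any 5' difference outside a homopolymer string (a run of more than three
  identical nucleotides, which is prone to sequencing slippage), or
* any coding difference that changes the protein (nonsynonymous substitution,
  premature stop, or frameshift), or
* a 5' string difference corroborated by at least one additional independent
  non-string change anywhere in the allele span.

Haplotypes that differ only by intron changes or string-length changes are
*allelets* -- neutral within-allele variants.  Synonymous-only coding
divergence is recorded but does not separate alleles on its own.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

from allelecall.alignment_io import (
    GAP,
    AlignedHaplotype,
    GeneRegionMap,
    HaplotypeAlignment,
)
from allelecall.coding import CodingFrame
from allelecall.errors import AlignmentError, PreconditionError

PROTEIN_CHANGING = frozenset({"nonsynonymous", "frameshift", "nonsense"})

#: region classes that belong to the allele span (the baseline is co-genomic
#: neutral sequence and never informs allele identity)
ALLELE_SPAN = frozenset({"five_prime", "exon", "intron", "three_prime"})


@dataclass(frozen=True)
class SiteDifference:
    """One difference event between two aligned sequences.

    A contiguous indel spanning k gap columns is recorded as ONE event
    anchored at its leftmost column; substitutions are per-column events.
    """

    column: int
    kind: str  # substitution | indel
    length: int = 1
    region_type: str | None = None
    in_string: bool = False
    coding_effect: str | None = None
    state_1: str = ""
    state_2: str = ""

    @property
    def end(self) -> int:
        return self.column + self.length


def find_homopolymer_runs(
    sequence: str, min_run: int = 4
) -> list[tuple[int, int]]:
    """Maximal homopolymer runs of degapped length >= ``min_run``.

    Runs are detected on the degapped sequence and mapped back to alignment
    coordinates; the returned half-open intervals span from the first to the
    last residue of the run (enclosing any interleaved gap columns).
    """
    cols = [i for i, ch in enumerate(sequence) if ch != GAP]
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(cols):
        j = i
        base = sequence[cols[i]]
        while j < len(cols) and sequence[cols[j]] == base:
            j += 1
        if base in "ACGT" and j - i >= min_run:
            runs.append((cols[i], cols[j - 1] + 1))
        i = j
    return runs


def _in_any_run(start: int, end: int, runs: list[tuple[int, int]]) -> bool:
    return any(start < r_end and r_start < end for r_start, r_end in runs)


def pairwise_differences(
    h1: AlignedHaplotype,
    h2: AlignedHaplotype,
    region_map: GeneRegionMap | None = None,
    min_run: int = 4,
) -> list[SiteDifference]:
    """All difference events between two rows of one alignment.

    'N' participates in no difference call.  Adjacent gap-vs-base columns
    with the same gapped side merge into a single indel event.  Events are
    annotated with the region class, the homopolymer-string flag (a run in
    either sequence), and -- for exon events when ``region_map`` is given --
    the coding effect, classified against the reading frame of ``h1`` (or
    ``h2`` when ``h1`` is gapped at the site).
    """
    if len(h1) != len(h2):
        raise AlignmentError(
            f"{h1.id} and {h2.id} differ in length ({len(h1)} vs {len(h2)})"
        )
    runs = find_homopolymer_runs(h1.sequence, min_run) + find_homopolymer_runs(
        h2.sequence, min_run
    )
    frames: dict[str, CodingFrame | None] = {}

    def frame_for(which: str) -> CodingFrame | None:
        if which not in frames:
            ref = h1 if which == "h1" else h2
            try:
                frames[which] = CodingFrame(region_map, ref)
            except PreconditionError:
                frames[which] = None
        return frames[which]

    diffs: list[SiteDifference] = []
    n = len(h1)
    c = 0
    while c < n:
        a, b = h1.sequence[c], h2.sequence[c]
        if a == b or "N" in (a, b):
            c += 1
            continue
        if GAP in (a, b):
            # merge the maximal stretch of columns gapped on the same side
            gap_in_h1 = a == GAP
            start = c
            while c < n:
                a2, b2 = h1.sequence[c], h2.sequence[c]
                if "N" in (a2, b2) or a2 == b2:
                    break
                if (a2 == GAP) != gap_in_h1 or GAP not in (a2, b2):
                    break
                c += 1
            diffs.append(
                _annotate(
                    SiteDifference(
                        column=start,
                        kind="indel",
                        length=c - start,
                        state_1=h1.sequence[start:c],
                        state_2=h2.sequence[start:c],
                    ),
                    region_map,
                    runs,
                    frame_for,
                )
            )
        else:
            diffs.append(
                _annotate(
                    SiteDifference(
                        column=c, kind="substitution", state_1=a, state_2=b
                    ),
                    region_map,
                    runs,
                    frame_for,
                )
            )
            c += 1
    return diffs


def _annotate(diff, region_map, runs, frame_for) -> SiteDifference:
    in_string = _in_any_run(diff.column, diff.end, runs)
    region_type = (
        region_map.region_type_at(diff.column) if region_map is not None else None
    )
    effect: str | None = None
    if region_type == "exon":
        if diff.kind == "indel":
            # indel length counts inserted/deleted residues, not columns
            n_res = max(
                len(diff.state_1.replace(GAP, "")),
                len(diff.state_2.replace(GAP, "")),
            )
            effect = "frameshift" if n_res % 3 else "nonsynonymous"
        else:
            frame = frame_for("h1")
            alt = diff.state_2
            if frame is None or diff.column not in frame.col_to_pos:
                frame = frame_for("h2")
                alt = diff.state_1
            if frame is not None and diff.column in frame.col_to_pos:
                effect = frame.classify_substitution(diff.column, alt)
    elif region_type is not None:
        effect = "not_applicable"
    return replace(
        diff, region_type=region_type, in_string=in_string, coding_effect=effect
    )


def defining_differences(
    diffs: list[SiteDifference], three_prime_defining: bool = False
) -> list[SiteDifference]:
    """Subset of ``diffs`` that individually or jointly define a new allele."""
    span = [d for d in diffs if d.region_type in ALLELE_SPAN]
    defining: list[SiteDifference] = []
    for d in span:
        if d.region_type == "five_prime" and not d.in_string:
            defining.append(d)
        elif d.region_type == "exon":
            if d.coding_effect is None:
                raise PreconditionError(
                    f"exon difference at column {d.column} lacks coding_effect"
                )
            if d.coding_effect in PROTEIN_CHANGING:
                defining.append(d)
        elif (
            three_prime_defining
            and d.region_type == "three_prime"
            and not d.in_string
        ):
            defining.append(d)
    if not defining:
        # a 5' string change corroborated by an independent non-string change
        string_5p = [
            d for d in span if d.region_type == "five_prime" and d.in_string
        ]
        independent = [d for d in span if not d.in_string]
        if string_5p and independent:
            defining = string_5p + independent
    return defining


def classify_pair(
    diffs: list[SiteDifference], three_prime_defining: bool = False
) -> str:
    """Verdict for one haplotype pair from its difference list.

    Returns ``distinct_alleles`` if at least one defining difference exists,
    ``allelet_pair`` if all allele-span differences are intron-only and/or
    string-only, and ``same_allele`` otherwise (no differences, or only
    non-defining ones such as synonymous coding changes, which are retained
    as within-allele variation).
    """
    span = [d for d in diffs if d.region_type in ALLELE_SPAN]
    if not span:
        return "same_allele"
    if defining_differences(diffs, three_prime_defining):
        return "distinct_alleles"
    if all(d.region_type == "intron" or d.in_string for d in span):
        return "allelet_pair"
    return "same_allele"


@dataclass
class AlleleGroup:
    """One named allele: its members, representative, and the defining
    differences of the representative against every other allele."""

    name: str
    representative: str
    members: list[str] = field(default_factory=list)
    defining: dict[str, list[SiteDifference]] = field(default_factory=dict)


@dataclass
class AlleleSet:
    """Partition of the hybrid haplotypes of one locus into alleles and
    allelets."""

    locus: str
    alleles: dict[str, AlleleGroup] = field(default_factory=dict)
    allelets: dict[str, list[tuple[str, list[SiteDifference]]]] = field(
        default_factory=dict
    )

    @property
    def names(self) -> list[str]:
        return list(self.alleles)

    def allele_of(self, hap_id: str) -> str:
        """Allele name a haplotype belongs to (as member or allelet)."""
        for name, group in self.alleles.items():
            if hap_id in group.members:
                return name
        for name, variants in self.allelets.items():
            if any(v == hap_id for v, _ in variants):
                return name
        raise KeyError(hap_id)

    def status_of(self, hap_id: str) -> str:
        for group in self.alleles.values():
            if hap_id in group.members:
                return "allele_member"
        for variants in self.allelets.values():
            if any(v == hap_id for v, _ in variants):
                return "allelet"
        raise KeyError(hap_id)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def n_allelets(self) -> int:
        return sum(len(v) for v in self.allelets.values())


def _letters() -> "itertools.chain":
    singles = (chr(ord("a") + i) for i in range(26))
    doubles = (
        a + b
        for a in (chr(ord("a") + i) for i in range(26))
        for b in (chr(ord("a") + i) for i in range(26))
    )
    return itertools.chain(singles, doubles)


def call_alleles(
    alignment: HaplotypeAlignment,
    region_map: GeneRegionMap,
    min_run: int = 4,
    three_prime_defining: bool = False,
    name_by: str = "input_order",
) -> AlleleSet:
    """Partition all hybrid haplotypes into alleles and allelets.

    Single-linkage clustering on the same-allele/allelet relation, followed
    by a greedy split of any cluster that still contains an internal defining
    difference (with a warning -- such triangles arise only from conflicting
    data).  Allele names are assigned ``<locus>_a``, ``_b``, ... in input
    order of each allele's first representative (or by decreasing member
    count with ``name_by='count'``); allelets get the parent name plus a
    prime.
    """
    hybrids = alignment.hybrids
    if not hybrids:
        raise PreconditionError("allele calling needs at least one hybrid haplotype")
    ids = [h.id for h in hybrids]
    index = {hid: i for i, hid in enumerate(ids)}

    cache: dict[tuple[int, int], tuple[list[SiteDifference], str]] = {}

    def pair(i: int, j: int) -> tuple[list[SiteDifference], str]:
        key = (min(i, j), max(i, j))
        if key not in cache:
            diffs = pairwise_differences(
                hybrids[key[0]], hybrids[key[1]], region_map, min_run
            )
            cache[key] = (diffs, classify_pair(diffs, three_prime_defining))
        return cache[key]

    # single linkage over same_allele / allelet_pair edges
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(ids)), 2):
        if pair(i, j)[1] != "distinct_alleles":
            parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(ids)):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=min)

    # split clusters with an internal defining difference (greedy, leftmost
    # representative kept)
    final: list[list[int]] = []
    for members in ordered:
        members = sorted(members)
        conflict = any(
            pair(i, j)[1] == "distinct_alleles"
            for i, j in itertools.combinations(members, 2)
        )
        if not conflict:
            final.append(members)
            continue
        warnings.warn(
            f"{region_map.locus}: intransitive allele relation among "
            f"{[ids[i] for i in members]}; resolved by greedy split",
            stacklevel=2,
        )
        subclusters: list[list[int]] = []
        for i in members:
            for sub in subclusters:
                if pair(sub[0], i)[1] != "distinct_alleles":
                    sub.append(i)
                    break
            else:
                subclusters.append([i])
        final.extend(subclusters)

    if name_by == "count":
        final.sort(key=lambda m: (-len(m), m[0]))
    elif name_by != "input_order":
        raise ValueError(f"unknown name_by {name_by!r}")

    result = AlleleSet(locus=region_map.locus)
    letters = _letters()
    for members in final:
        rep = members[0]
        name = f"{region_map.locus}_{next(letters)}"
        group = AlleleGroup(name=name, representative=ids[rep])
        variants: list[tuple[str, list[SiteDifference]]] = []
        for i in members:
            diffs, verdict = pair(rep, i) if i != rep else ([], "same_allele")
            if verdict == "allelet_pair":
                variants.append((ids[i], diffs))
            else:
                group.members.append(ids[i])
        result.alleles[name] = group
        if variants:
            result.allelets[name] = [
                (vid, diffs) for k, (vid, diffs) in enumerate(variants)
            ]

    # defining differences between every pair of allele representatives
    names = list(result.alleles)
    for a, b in itertools.combinations(names, 2):
        i = index[result.alleles[a].representative]
        j = index[result.alleles[b].representative]
        diffs, _ = pair(i, j)
        shared = defining_differences(diffs, three_prime_defining)
        result.alleles[a].defining[b] = shared
        result.alleles[b].defining[a] = shared
    return result
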