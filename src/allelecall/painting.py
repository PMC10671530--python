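"""Parental-origin painting of hybrid alleles and breakpoint inference.

At every *informative site* -- an alignment column where the two parental
haplotypes differ -- a hybrid sequence either matches parent A, matches
parent B, or matches neither (a candidate lineage-specific mutation).
Consecutive runs of same-origin sites define the minimal-switch segmentation;
a recombination *breakpoint interval* is the open column interval between the
last informative site of one origin and the first of the next.  Spans before
the first and after the last informative site are of unknown origin.

'neither' sites are transparent to the segmentation: they neither break nor
switch a segment, because they are candidate new mutations handled by the
mutation catalogue, not ancestry signals.  Columns where exactly one parent
is gapped ARE informative (the gap acts as a fifth character state);
shared-gap and N-bearing columns are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from allelecall.alignment_io import GAP, AlignedHaplotype, GeneRegionMap
from allelecall.errors import PaintingError


@dataclass(frozen=True)
class InformativeSite:
    """One column where the parents differ, with the hybrid's origin call."""

    column: int
    parent_a_state: str
    parent_b_state: str
    hybrid_state: str
    origin: str  # A | B | neither


@dataclass
class AncestryPainting:
    """Minimal-switch segmentation of one hybrid haplotype.

    ``segments`` tile ``[0, n_columns)`` with origins A, B or unknown;
    ``breakpoints`` are open intervals ``(left, right)`` between flanking
    informative sites of opposite origin, so ``n_switches`` equals their
    count by construction.
    """

    hybrid_id: str
    n_columns: int
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    breakpoints: list[tuple[int, int]] = field(default_factory=list)
    sites: list[InformativeSite] = field(default_factory=list)

    @property
    def n_switches(self) -> int:
        return len(self.breakpoints)

    def origin_at(self, column: int) -> str:
        """Origin label of the segment covering ``column``."""
        for start, end, origin in self.segments:
            if start <= column < end:
                return origin
        raise PaintingError(f"column {column} outside painted span")

    @property
    def contributions(self) -> tuple[float, float]:
        """Overall (frac_A, frac_B) among informative sites."""
        n = len(self.sites)
        a = sum(1 for s in self.sites if s.origin == "A")
        b = sum(1 for s in self.sites if s.origin == "B")
        return a / n, b / n


def informative_sites(
    hybrid: AlignedHaplotype,
    parent_a: AlignedHaplotype,
    parent_b: AlignedHaplotype,
) -> list[InformativeSite]:
    """All columns where the parents differ, with the hybrid matched exactly."""
    if not len(hybrid) == len(parent_a) == len(parent_b):
        raise PaintingError("hybrid and parents must come from one alignment")
    sites: list[InformativeSite] = []
    for c in range(len(hybrid)):
        a, b = parent_a.sequence[c], parent_b.sequence[c]
        if a == b or "N" in (a, b):
            continue
        h = hybrid.sequence[c]
        if h == "N":
            origin = "neither"
        elif h == a:
            origin = "A"
        elif h == b:
            origin = "B"
        else:
            origin = "neither"
        sites.append(InformativeSite(c, a, b, h, origin))
    if not sites:
        raise PaintingError(
            f"no informative sites: parents are identical over the span of "
            f"{hybrid.id}"
        )
    return sites


def paint(
    sites: list[InformativeSite], n_columns: int, hybrid_id: str = ""
) -> AncestryPainting:
    """Minimal-switch segmentation from origin calls at informative sites."""
    anchored = [s for s in sites if s.origin in ("A", "B")]
    if not anchored:
        raise PaintingError(
            "painting impossible: no informative site matches either parent"
        )
    # group consecutive anchored sites by origin ('neither' is transparent)
    runs: list[tuple[str, int, int]] = []  # (origin, first_col, last_col)
    for s in anchored:
        if runs and runs[-1][0] == s.origin:
            runs[-1] = (s.origin, runs[-1][1], s.column)
        else:
            runs.append((s.origin, s.column, s.column))

    segments: list[tuple[int, int, str]] = []
    breakpoints: list[tuple[int, int]] = []
    first = runs[0][1]
    if first > 0:
        segments.append((0, first, "unknown"))
    for k, (origin, start, last) in enumerate(runs):
        segments.append((start, last + 1, origin))
        if k + 1 < len(runs):
            nxt = runs[k + 1][1]
            breakpoints.append((last, nxt))
            if nxt - last > 1:
                segments.append((last + 1, nxt, "unknown"))
    tail = runs[-1][2] + 1
    if tail < n_columns:
        segments.append((tail, n_columns, "unknown"))
    return AncestryPainting(
        hybrid_id=hybrid_id,
        n_columns=n_columns,
        segments=segments,
        breakpoints=breakpoints,
        sites=list(sites),
    )


@dataclass(frozen=True)
class ContributionSummary:
    frac_a: float | None
    frac_b: float | None
    n_sites: int
    bias: str  # A_biased | B_biased | balanced | undefined


def _bias(frac_a: float, frac_b: float, threshold: float) -> str:
    if frac_a >= threshold:
        return "A_biased"
    if frac_b >= threshold:
        return "B_biased"
    return "balanced"


def contribution_fractions(
    painting: AncestryPainting,
    region_map: GeneRegionMap,
    bias_threshold: float = 0.6,
) -> dict[str, ContributionSummary]:
    """Fraction of informative sites of each parental origin per region class.

    Fractions are over all informative sites of the region, so frac_A +
    frac_B <= 1 with the remainder matching neither parent.  Regions with no
    informative sites are reported as undefined.  The overall entry carries
    the bias label (A-biased when frac_A >= ``bias_threshold``, mirrored for
    B; the threshold is a reporting convention, not an inference).
    """
    buckets: dict[str, list[InformativeSite]] = {
        r.region_type: [] for r in region_map.regions
    }
    for s in painting.sites:
        rtype = region_map.region_type_at(s.column)
        if rtype is not None:
            buckets.setdefault(rtype, []).append(s)
    buckets["overall"] = list(painting.sites)

    out: dict[str, ContributionSummary] = {}
    for rtype, sites in buckets.items():
        n = len(sites)
        if n == 0:
            out[rtype] = ContributionSummary(None, None, 0, "undefined")
            continue
        fa = sum(1 for s in sites if s.origin == "A") / n
        fb = sum(1 for s in sites if s.origin == "B") / n
        out[rtype] = ContributionSummary(fa, fb, n, _bias(fa, fb, bias_threshold))
    return out
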