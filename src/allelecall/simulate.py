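"""Synthetic haplotype alignments with a machine-readable truth ledger.

The generator emulates the data regime of a hybrid-origin species survey:

* an ancestral sequence and two parental haplotypes diverged from it by
  independent per-site substitution (coding changes restricted to synonymous
  third-position swaps so parents stay frame-clean),
* hybrid alleles built by copying parental segments between planted
  recombination breakpoints,
* planted post-hybridization ("derived") substitutions and deletions per
  region per allele with a controllable synonymous/nonsynonymous mix,
* allelets produced purely by homopolymer-length slips,
* an outgroup derived independently from the ancestor, sharing ancestral
  states,
* optional low-frequency variant planting (recent vs ancestral) for
  outgroup/frequency polarization scenarios.

Every stochastic draw goes through a single :class:`numpy.random.Generator`
seeded from ``config.seed``, so identical configurations give byte-identical
alignments.  No column receives more than one planted change, and there is
no back-mutation: at the <= 2% divergences simulated here multiple hits are
negligible and an unambiguous truth ledger is worth more than the bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from allelecall.alignment_io import (
    GAP,
    AlignedHaplotype,
    GeneRegionMap,
    HaplotypeAlignment,
    Region,
)
from allelecall.coding import translate_codon
from allelecall.errors import PreconditionError

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = sorted(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated locus.

    Defaults mirror the surveyed data regime: a ~1 kb 5' region, a ~2.2 kb
    coding region split by a long (> 800 bp) intron, a short 3' region, an
    875 bp downstream neutral baseline, parents at 1% per-site divergence,
    six hybrid alleles each sampled in two genomes, one recombination
    breakpoint per allele, and one 5' plus one coding derived mutation per
    allele.
    """

    seed: int = 0
    locus: str = "LOC1"
    five_prime_len: int = 1014
    exon_lens: tuple[int, ...] = (1080, 1080)
    intron_lens: tuple[int, ...] = (850,)
    three_prime_len: int = 150
    baseline_len: int = 875
    parental_divergence: float = 0.01
    outgroup_divergence: float = 0.02
    n_hybrid_alleles: int = 6
    members_per_allele: int = 2
    breakpoints_per_allele: int = 1
    explicit_breakpoints: dict[int, tuple[int, ...]] | None = None
    derived_per_region: dict[str, int] = field(
        default_factory=lambda: {"five_prime": 1, "exon": 1}
    )
    fraction_nonsynonymous: float = 0.7
    derived_deletions_per_allele: int = 0
    n_shared_five_prime: int = 0
    n_allelets: int = 0
    n_recent_variants: int = 0
    n_ancestral_variants: int = 0
    recent_carrier_max: int = 2
    subgroups: tuple[str, ...] = ("indica", "japonica")
    include_outgroup: bool = True

    def __post_init__(self) -> None:
        for p in (self.parental_divergence, self.outgroup_divergence):
            if not 0 <= p <= 1:
                raise PreconditionError("divergence probabilities must be in [0, 1]")
        if sum(self.exon_lens) % 3:
            raise PreconditionError("total exon length must be a multiple of 3")
        if self.n_hybrid_alleles < 1:
            raise PreconditionError("need at least one hybrid allele")
        if self.n_allelets > self.n_hybrid_alleles:
            raise PreconditionError("more allelets than alleles")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted difference, as ground truth for recovery tests."""

    column: int
    kind: str  # substitution | indel
    length: int
    region_type: str
    coding_effect: str | None
    derived_state: str
    carrier_alleles: tuple[str, ...]
    carrier_haps: tuple[str, ...]
    status: str  # derived | recent | ancestral | slip


@dataclass
class TruthLedger:
    """Everything the generator planted, keyed the way the pipeline reports."""

    locus: str
    allele_members: dict[str, list[str]] = field(default_factory=dict)
    allelets: dict[str, str] = field(default_factory=dict)  # variant id -> allele
    breakpoints: dict[str, list[int]] = field(default_factory=dict)
    origins: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    planted: list[PlantedEvent] = field(default_factory=list)
    string_noise: dict[str, int] = field(default_factory=dict)

    def allele_of(self, hap_id: str) -> str:
        for name, members in self.allele_members.items():
            if hap_id in members:
                return name
        if hap_id in self.allelets:
            return self.allelets[hap_id]
        raise KeyError(hap_id)

    def derived_events(self, status: str = "derived") -> list[PlantedEvent]:
        return [e for e in self.planted if e.status == status]

    def to_json_dict(self) -> dict:
        return {
            "locus": self.locus,
            "allele_members": self.allele_members,
            "allelets": self.allelets,
            "breakpoints": self.breakpoints,
            "origins": {k: [list(s) for s in v] for k, v in self.origins.items()},
            "planted": [dataclasses.asdict(e) for e in self.planted],
            "string_noise": self.string_noise,
        }

    def self_check(self, alignment: HaplotypeAlignment) -> None:
        """Verify the emitted alignment against the ledger by re-deriving
        every hybrid from the parental mosaic plus planted events."""
        pa, pb = alignment.parent_a, alignment.parent_b
        if pa is None or pb is None:
            return

        def mosaic_of(allele: str) -> str:
            parts = []
            for start, end, origin in self.origins[allele]:
                src = pa if origin == "A" else pb
                parts.append(src.sequence[start:end])
            return "".join(parts)

        def check(hap: str, allele: str, is_allelet: bool) -> None:
            expected = list(mosaic_of(allele))
            for e in self.planted:
                applies = hap in e.carrier_haps or (
                    # allelets inherit the derived events of their allele
                    is_allelet
                    and e.status == "derived"
                    and allele in e.carrier_alleles
                )
                if applies:
                    for k in range(e.length):
                        expected[e.column + k] = e.derived_state[k]
            actual = alignment[hap].sequence
            if "".join(expected) != actual:
                bad = [
                    i for i, (x, y) in enumerate(zip(expected, actual)) if x != y
                ]
                raise AssertionError(
                    f"ledger mismatch for {hap}: columns {bad[:10]}"
                )

        for name, members in self.allele_members.items():
            for hap in members:
                check(hap, name, is_allelet=False)
        for hap, name in self.allelets.items():
            check(hap, name, is_allelet=True)


def _build_region_map(config: SimulationConfig) -> GeneRegionMap:
    regions: list[Region] = []
    pos = 0
    regions.append(Region("five_prime", 0, pos, pos + config.five_prime_len))
    pos += config.five_prime_len
    for i, exon_len in enumerate(config.exon_lens):
        regions.append(Region("exon", i, pos, pos + exon_len))
        pos += exon_len
        if i < len(config.intron_lens):
            regions.append(Region("intron", i, pos, pos + config.intron_lens[i]))
            pos += config.intron_lens[i]
    regions.append(Region("three_prime", 0, pos, pos + config.three_prime_len))
    pos += config.three_prime_len
    regions.append(Region("baseline", 0, pos, pos + config.baseline_len))
    pos += config.baseline_len
    return GeneRegionMap(config.locus, regions, n_columns=pos)


#: (offset within the 5' region, base, run length) of deliberately written
#: homopolymer strings -- the substrate for allelet slips
_PLANTED_RUNS = ((40, "A", 5), (90, "C", 4))


def simulate(
    config: SimulationConfig,
) -> tuple[HaplotypeAlignment, GeneRegionMap, TruthLedger]:
    """Generate one locus alignment plus region map and truth ledger."""
    rng = np.random.default_rng(config.seed)
    region_map = _build_region_map(config)
    n_cols = region_map.n_columns
    exon_cols = region_map.exon_columns()
    exon_col_set = set(exon_cols)
    noncoding_cols = [c for c in range(n_cols) if c not in exon_col_set]

    # --- ancestor ---------------------------------------------------------
    ancestor = [BASES[i] for i in rng.integers(0, 4, n_cols)]
    n_codons = len(exon_cols) // 3
    codon_choices = rng.integers(0, len(NONSTOP_CODONS), n_codons)
    for ci in range(n_codons):
        codon = NONSTOP_CODONS[codon_choices[ci]]
        for k in range(3):
            ancestor[exon_cols[3 * ci + k]] = codon[k]
    run_cols: set[int] = set()
    for offset, base, length in _PLANTED_RUNS:
        if offset + length <= config.five_prime_len:
            for c in range(offset, offset + length):
                ancestor[c] = base
                run_cols.add(c)
            # guard columns so neighbours cannot extend or shadow the run
            for c in (offset - 1, offset + length):
                if 0 <= c < config.five_prime_len:
                    ancestor[c] = "G" if base != "G" else "T"
                    run_cols.add(c)

    def synonymous_third_swap(codon_index: int, seq: list[str], r) -> bool:
        cols = exon_cols[3 * codon_index : 3 * codon_index + 3]
        codon = "".join(seq[c] for c in cols)
        aa = translate_codon(codon)
        alts = [
            b
            for b in BASES
            if b != codon[2] and translate_codon(codon[:2] + b) == aa
        ]
        if not alts:
            return False
        seq[cols[2]] = alts[int(r.integers(0, len(alts)))]
        return True

    def diverge(divergence: float) -> list[str]:
        seq = list(ancestor)
        for c in noncoding_cols:
            if c in run_cols:
                continue
            if rng.random() < divergence:
                alts = [b for b in BASES if b != seq[c]]
                seq[c] = alts[int(rng.integers(0, 3))]
        p_codon = min(1.0, 3 * divergence)
        for ci in range(n_codons):
            if rng.random() < p_codon:
                synonymous_third_swap(ci, seq, rng)
        return seq

    parent_a = diverge(config.parental_divergence)
    parent_b = diverge(config.parental_divergence)
    outgroup = (
        diverge(config.outgroup_divergence) if config.include_outgroup else None
    )

    # --- hybrid mosaics ---------------------------------------------------
    ledger = TruthLedger(locus=config.locus)
    span_end = region_map.of_type("baseline")[0].start  # breakpoints stay in span
    allele_names = [
        f"{config.locus}_h{i + 1}" for i in range(config.n_hybrid_alleles)
    ]
    hybrid_seqs: dict[str, list[str]] = {}
    for i, name in enumerate(allele_names):
        if config.explicit_breakpoints and i in config.explicit_breakpoints:
            bps = sorted(config.explicit_breakpoints[i])
        elif config.breakpoints_per_allele > 0:
            lo, hi = 50, max(51, span_end - 50)
            bps = sorted(
                int(x)
                for x in rng.choice(
                    np.arange(lo, hi),
                    size=min(config.breakpoints_per_allele, hi - lo),
                    replace=False,
                )
            )
        else:
            bps = []
        first = "A" if i % 2 == 0 else "B"
        bounds = [0] + bps + [n_cols]
        origins = []
        seq: list[str] = []
        current = first
        for start, end in zip(bounds, bounds[1:]):
            src = parent_a if current == "A" else parent_b
            seq.extend(src[start:end])
            origins.append((start, end, current))
            current = "B" if current == "A" else "A"
        hybrid_seqs[name] = seq
        ledger.breakpoints[name] = bps
        ledger.origins[name] = origins

    # --- planted derived mutations ---------------------------------------
    used_cols: set[int] = set()
    used_codons: dict[str, set[int]] = {name: set() for name in allele_names}

    def plant_noncoding(name: str, region_type: str) -> None:
        cols = [
            c
            for r in region_map.of_type(region_type)
            for c in range(r.start, r.end)
            if c not in used_cols and c not in run_cols
        ]
        for _ in range(200):
            c = cols[int(rng.integers(0, len(cols)))]
            if c in used_cols:
                continue
            seq = hybrid_seqs[name]
            forbidden = {parent_a[c], parent_b[c]}
            alts = [b for b in BASES if b not in forbidden]
            alts = [alts[j] for j in rng.permutation(len(alts))]
            for alt in alts:
                if _creates_run(seq, c, alt):
                    continue
                seq[c] = alt
                used_cols.add(c)
                ledger.planted.append(
                    PlantedEvent(
                        column=c,
                        kind="substitution",
                        length=1,
                        region_type=region_type,
                        coding_effect=None,
                        derived_state=alt,
                        carrier_alleles=(name,),
                        carrier_haps=(),  # filled once members exist
                        status="derived",
                    )
                )
                return
        raise PreconditionError(f"could not place a {region_type} mutation")

    def plant_coding(name: str) -> None:
        want_nonsyn = rng.random() < config.fraction_nonsynonymous
        seq = hybrid_seqs[name]
        for _ in range(500):
            ci = int(rng.integers(0, n_codons))
            if ci in used_codons[name]:
                continue
            pos = int(rng.integers(0, 3))
            c = exon_cols[3 * ci + pos]
            if c in used_cols:
                continue
            codon_cols = exon_cols[3 * ci : 3 * ci + 3]
            codon = "".join(seq[x] for x in codon_cols)
            aa = translate_codon(codon)
            forbidden = {parent_a[c], parent_b[c]}
            for alt in [b for b in BASES if b not in forbidden]:
                mutant = "".join(
                    alt if k == pos else codon[k] for k in range(3)
                )
                alt_aa = translate_codon(mutant)
                if alt_aa == "*":
                    continue  # keep default configs free of nonsense alleles
                if (alt_aa != aa) != want_nonsyn:
                    continue
                seq[c] = alt
                used_cols.add(c)
                used_codons[name].add(ci)
                ledger.planted.append(
                    PlantedEvent(
                        column=c,
                        kind="substitution",
                        length=1,
                        region_type="exon",
                        coding_effect="nonsynonymous" if want_nonsyn else "synonymous",
                        derived_state=alt,
                        carrier_alleles=(name,),
                        carrier_haps=(),
                        status="derived",
                    )
                )
                return
        raise PreconditionError("could not place a coding mutation")

    def plant_deletion(name: str) -> None:
        seq = hybrid_seqs[name]
        intron_cols = [
            c
            for r in region_map.of_type("intron") + region_map.of_type("five_prime")
            for c in range(r.start + 1, r.end - 1)
        ]
        for _ in range(200):
            length = int(rng.integers(2, 5))
            c = intron_cols[int(rng.integers(0, len(intron_cols) - length))]
            cols = range(c, c + length)
            if any(
                x in used_cols
                or x in run_cols
                or region_map.region_type_at(x)
                != region_map.region_type_at(c)
                for x in cols
            ):
                continue
            # flanks must stay base-vs-base so the event stays one indel
            if seq[c - 1] == GAP or seq[c + length] == GAP:
                continue
            for x in cols:
                seq[x] = GAP
                used_cols.add(x)
            ledger.planted.append(
                PlantedEvent(
                    column=c,
                    kind="indel",
                    length=length,
                    region_type=region_map.region_type_at(c),
                    coding_effect=None,
                    derived_state=GAP * length,
                    carrier_alleles=(name,),
                    carrier_haps=(),
                    status="derived",
                )
            )
            return
        raise PreconditionError("could not place a deletion")

    # shared early 5' mutations: fixed in every allele after hybridization
    for _ in range(config.n_shared_five_prime):
        alt = None
        for _attempt in range(200):
            cols = [
                c
                for c in range(config.five_prime_len)
                if c not in used_cols and c not in run_cols
            ]
            c = cols[int(rng.integers(0, len(cols)))]
            forbidden = {parent_a[c], parent_b[c]}
            alts = [
                b
                for b in BASES
                if b not in forbidden
                and not any(_creates_run(hybrid_seqs[n], c, b) for n in allele_names)
            ]
            if alts:
                alt = alts[int(rng.integers(0, len(alts)))]
                break
        if alt is None:
            raise PreconditionError("could not place a shared 5' mutation")
        for name in allele_names:
            hybrid_seqs[name][c] = alt
        used_cols.add(c)
        ledger.planted.append(
            PlantedEvent(
                column=c,
                kind="substitution",
                length=1,
                region_type="five_prime",
                coding_effect=None,
                derived_state=alt,
                carrier_alleles=tuple(allele_names),
                carrier_haps=(),
                status="derived",
            )
        )

    for name in allele_names:
        for region_type, count in config.derived_per_region.items():
            for _ in range(count):
                if region_type == "exon":
                    plant_coding(name)
                else:
                    plant_noncoding(name, region_type)
        for _ in range(config.derived_deletions_per_allele):
            plant_deletion(name)

    # --- members, allelets, roles ----------------------------------------
    members: list[AlignedHaplotype] = []
    hap_ids_by_allele: dict[str, list[str]] = {}
    all_hybrid_ids: list[str] = []
    for i, name in enumerate(allele_names):
        subgroup = config.subgroups[i % len(config.subgroups)] if config.subgroups else None
        ids = []
        for m in range(config.members_per_allele):
            hap_id = f"{config.locus}.g{i + 1}.{m + 1}"
            members.append(
                AlignedHaplotype(
                    hap_id, "".join(hybrid_seqs[name]), "hybrid", subgroup
                )
            )
            ids.append(hap_id)
            all_hybrid_ids.append(hap_id)
        hap_ids_by_allele[name] = ids
        ledger.allele_members[name] = ids

    # planted events carried by an allele are carried by all its members
    ledger.planted = [
        dataclasses.replace(
            e,
            carrier_haps=tuple(
                hid
                for a in e.carrier_alleles
                for hid in hap_ids_by_allele.get(a, ())
            ),
        )
        for e in ledger.planted
    ]

    for i in range(config.n_allelets):
        name = allele_names[i]
        rep_seq = list(hybrid_seqs[name])
        slip_col = None
        for offset, base, length in _PLANTED_RUNS:
            c = offset + length - 1
            if rep_seq[c] == base:
                slip_col = c
                break
        if slip_col is None:
            raise PreconditionError("no homopolymer run available for a slip")
        rep_seq[slip_col] = GAP
        hap_id = f"{config.locus}.g{i + 1}.t"
        subgroup = config.subgroups[i % len(config.subgroups)] if config.subgroups else None
        members.append(
            AlignedHaplotype(hap_id, "".join(rep_seq), "hybrid", subgroup)
        )
        all_hybrid_ids.append(hap_id)
        ledger.allelets[hap_id] = name
        ledger.string_noise[hap_id] = slip_col
        ledger.planted.append(
            PlantedEvent(
                column=slip_col,
                kind="indel",
                length=1,
                region_type="five_prime",
                coding_effect=None,
                derived_state=GAP,
                carrier_alleles=(name,),
                carrier_haps=(hap_id,),
                status="slip",
            )
        )

    # --- polarization variants (conspecific low-frequency planting) -------
    seq_by_id = {m.id: list(m.sequence) for m in members}
    free_5p = [
        c
        for c in range(config.five_prime_len)
        if c not in used_cols
        and c not in run_cols
        and parent_a[c] == parent_b[c]
    ]
    free_5p = [free_5p[j] for j in rng.permutation(len(free_5p))]
    cursor = 0

    def plant_variant(status: str) -> None:
        nonlocal cursor
        while cursor < len(free_5p):
            c = free_5p[cursor]
            cursor += 1
            ancestral_state = parent_a[c]
            og_state = outgroup[c] if outgroup is not None else None
            n_carriers = int(rng.integers(1, config.recent_carrier_max + 1))
            if n_carriers / len(all_hybrid_ids) >= 0.30:
                n_carriers = 1
            carriers = [
                all_hybrid_ids[j]
                for j in rng.choice(
                    len(all_hybrid_ids), size=n_carriers, replace=False
                )
            ]
            if status == "recent":
                alts = [
                    b
                    for b in BASES
                    if b != ancestral_state and b != og_state
                ]
            else:
                alts = [b for b in BASES if b != ancestral_state]
            if not alts:
                continue
            alt = alts[int(rng.integers(0, len(alts)))]
            ok = all(seq_by_id[h][c] == ancestral_state for h in all_hybrid_ids)
            if not ok:
                continue
            for h in carriers:
                seq_by_id[h][c] = alt
            if status == "ancestral" and outgroup is not None:
                outgroup[c] = alt
            used_cols.add(c)
            ledger.planted.append(
                PlantedEvent(
                    column=c,
                    kind="substitution",
                    length=1,
                    region_type="five_prime",
                    coding_effect=None,
                    derived_state=alt,
                    carrier_alleles=(),
                    carrier_haps=tuple(carriers),
                    status=status,
                )
            )
            return
        raise PreconditionError("ran out of columns for polarization variants")

    for _ in range(config.n_recent_variants):
        plant_variant("recent")
    for _ in range(config.n_ancestral_variants):
        plant_variant("ancestral")

    final_members = [
        AlignedHaplotype(m.id, "".join(seq_by_id[m.id]), "hybrid", m.subgroup)
        for m in members
    ]
    final_members.append(
        AlignedHaplotype(f"{config.locus}.parentA", "".join(parent_a), "parent_a")
    )
    final_members.append(
        AlignedHaplotype(f"{config.locus}.parentB", "".join(parent_b), "parent_b")
    )
    if outgroup is not None:
        final_members.append(
            AlignedHaplotype(f"{config.locus}.outgroup", "".join(outgroup), "outgroup")
        )
    alignment = HaplotypeAlignment(final_members)
    ledger.self_check(alignment)
    return alignment, region_map, ledger


def _creates_run(seq: list[str], column: int, base: str, min_run: int = 4) -> bool:
    """Would substituting ``base`` at ``column`` create a homopolymer run of
    degapped length >= min_run around the column?"""
    left = column - 1
    count = 1
    while left >= 0:
        if seq[left] == GAP:
            left -= 1
            continue
        if seq[left] != base:
            break
        count += 1
        left -= 1
    right = column + 1
    while right < len(seq):
        if seq[right] == GAP:
            right += 1
            continue
        if seq[right] != base:
            break
        count += 1
        right += 1
    return count >= min_run


# ---------------------------------------------------------------------------
# canned deterministic fixtures
# ---------------------------------------------------------------------------

def _repeating(n: int, pattern: str = "ACGT") -> list[str]:
    return [pattern[i % len(pattern)] for i in range(n)]


def fixture_suite() -> dict[str, dict]:
    """Small hand-constructed scenarios with their expected outcomes.

    * ``chimera``            -- single-breakpoint 5'/coding recombinant
    * ``allelet_pair``       -- two haplotypes differing only by a string slip
    * ``frameshift``         -- 1 bp coding deletion truncating the protein
    * ``polarization_trap``  -- ancestral low-frequency variant that the
      outgroup exposes
    """
    fixtures: dict[str, dict] = {}

    # chimera: 5' of parent A, coding + 3' of parent B
    n = 72
    base = _repeating(n)
    pa = list(base)
    pb = list(base)
    for c in (5, 15, 25):  # 5' informative sites
        pb[c] = "A" if pa[c] != "A" else "G"
    for c, alt in ((35, "A"), (47, "C"), (56, "G")):  # synonymous third positions
        pb[c] = alt
    pb[65] = "A" if pa[65] != "A" else "G"  # 3' informative site
    hyb = pa[:30] + pb[30:]
    regions = [
        Region("five_prime", 0, 0, 30),
        Region("exon", 0, 30, 60),
        Region("three_prime", 0, 60, 72),
    ]
    fixtures["chimera"] = {
        "alignment": HaplotypeAlignment(
            [
                AlignedHaplotype("hyb1", "".join(hyb), "hybrid"),
                AlignedHaplotype("pa", "".join(pa), "parent_a"),
                AlignedHaplotype("pb", "".join(pb), "parent_b"),
            ]
        ),
        "region_map": GeneRegionMap("CHIM", regions, n_columns=n),
        "expected": {"n_breakpoints": 1, "breakpoint_interval": (25, 35)},
    }

    # allelet pair: A-string slip only
    n = 44
    base = _repeating(n)
    base[5:10] = list("AAAAA")
    base[4] = "G"
    base[10] = "G"
    h2 = list(base)
    h2[9] = GAP
    regions = [Region("five_prime", 0, 0, 20), Region("exon", 0, 20, 44)]
    fixtures["allelet_pair"] = {
        "alignment": HaplotypeAlignment(
            [
                AlignedHaplotype("v1", "".join(base), "hybrid"),
                AlignedHaplotype("v2", "".join(h2), "hybrid"),
            ]
        ),
        "region_map": GeneRegionMap("ALT", regions, n_columns=n),
        "expected": {"n_alleles": 1, "n_allelets": 1},
    }

    # frameshift: deleting one base exposes a premature stop
    ref_cds = "ATGCTAGCAACCGGG"
    hyb = list(ref_cds)
    hyb[3] = GAP  # degapped: ATG TAG ... -> stop at codon 2
    regions = [Region("exon", 0, 0, 15)]
    fixtures["frameshift"] = {
        "alignment": HaplotypeAlignment(
            [
                AlignedHaplotype("mut", "".join(hyb), "hybrid"),
                AlignedHaplotype("ref", ref_cds, "parent_a"),
            ]
        ),
        "region_map": GeneRegionMap("FSX", regions, n_columns=15),
        "expected": {"coding_effect": "frameshift", "truncated": True},
    }

    # polarization trap: outgroup shares the minor state of one variant
    n = 40
    base = "".join(_repeating(n))
    haps = [list(base) for _ in range(12)]
    og = list(base)
    haps[0][10] = "G" if base[10] != "G" else "T"  # recent, freq 1/12
    anc_state = "C" if base[20] != "C" else "T"
    haps[0][20] = anc_state  # ancestral, freq 2/12, shared with outgroup
    haps[1][20] = anc_state
    og[20] = anc_state
    for j in range(5):  # common polymorphism, freq 5/12: not tentative
        haps[j][30] = "T" if base[30] != "T" else "A"
    records = [
        AlignedHaplotype(f"e{j + 1}", "".join(h), "hybrid") for j, h in enumerate(haps)
    ]
    records.append(AlignedHaplotype("og", "".join(og), "outgroup"))
    fixtures["polarization_trap"] = {
        "alignment": HaplotypeAlignment(records),
        "region_map": GeneRegionMap(
            "POL", [Region("five_prime", 0, 0, n)], n_columns=n
        ),
        "expected": {
            "n_tentative": 2,
            "n_excluded": 1,
            "excluded_column": 20,
            "error_rate": 0.5,
        },
    }
    return fixtures
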