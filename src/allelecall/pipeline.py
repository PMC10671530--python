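"""End-to-end orchestration: call alleles, paint ancestry, catalogue
mutations, and run the selection tests, writing table-shaped reports.

All outputs are deterministic for fixed inputs and written atomically
(temp file + rename), so a crashed run never leaves a truncated report.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from allelecall.alignment_io import (
    GeneRegionMap,
    HaplotypeAlignment,
    _atomic_write,
    read_alignment,
    read_region_map,
    read_role_map,
)
from allelecall.alleles import AlleleSet, call_alleles
from allelecall.errors import AlleleCallError, PreconditionError
from allelecall.mutations import hybrid_mode_mutations, polarize_with_outgroup
from allelecall.painting import contribution_fractions, informative_sites, paint
from allelecall.selection import (
    baseline_test,
    dunn_sidak,
    ka_ks,
    mutation_density,
    per_allele_rates,
    round_half_up,
)


@dataclass
class RunConfig:
    """Options for one pipeline invocation."""

    alignment_path: str
    region_map_path: str
    out_dir: str
    role_map_path: str | None = None
    locus: str | None = None
    mode: str = "hybrid"  # hybrid | outgroup
    min_run: int = 4
    freq_threshold: float = 0.30
    strict_threshold: bool = True
    family_alpha: float = 0.05
    family_size: int | None = None
    tail: str = "auto"
    bias_threshold: float = 0.6
    three_prime_defining: bool = False
    name_by: str = "input_order"

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Load a config from YAML or JSON."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(path, lambda fh: df.to_csv(fh, sep="\t", index=False))


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage and write the report bundle.

    Returns the summary dictionary that is also written to
    ``<out_dir>/summary.json``.
    """
    role_map = (
        read_role_map(config.role_map_path) if config.role_map_path else None
    )
    alignment = read_alignment(config.alignment_path, role_map)
    maps = read_region_map(config.region_map_path, alignment)
    if config.locus:
        if config.locus not in maps:
            raise PreconditionError(f"locus {config.locus!r} not in region map")
        region_map = maps[config.locus]
    elif len(maps) == 1:
        region_map = next(iter(maps.values()))
    else:
        raise PreconditionError(
            f"region map describes several loci ({list(maps)}); pass locus"
        )
    if config.mode == "hybrid":
        if alignment.parent_a is None or alignment.parent_b is None:
            raise PreconditionError(
                "hybrid mode requires haplotypes with roles parent_a and "
                "parent_b (check the role map)"
            )
    elif config.mode == "outgroup":
        if alignment.outgroup is None:
            raise PreconditionError(
                "outgroup mode requires a haplotype with role outgroup"
            )
    else:
        raise PreconditionError(f"unknown mode {config.mode!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"locus": region_map.locus, "mode": config.mode}

    alleles = call_alleles(
        alignment,
        region_map,
        min_run=config.min_run,
        three_prime_defining=config.three_prime_defining,
        name_by=config.name_by,
    )
    _write_alleles(alleles, alignment, out)
    summary["n_alleles"] = alleles.n_alleles
    summary["n_allelets"] = alleles.n_allelets

    if config.mode == "hybrid":
        summary.update(_hybrid_stages(config, alignment, region_map, alleles, out))
    else:
        summary.update(_outgroup_stages(config, alignment, region_map, out))

    _atomic_write(out / "summary.json", lambda fh: json.dump(summary, fh, indent=2))
    return summary


def _write_alleles(alleles: AlleleSet, alignment, out: Path) -> None:
    rows = []
    for name, group in alleles.alleles.items():
        nearest = min(
            (len(d) for d in group.defining.values() if d), default=0
        )
        for hap in group.members:
            rows.append(
                {
                    "haplotype_id": hap,
                    "locus": alleles.locus,
                    "allele_name": name,
                    "status": "allele_member",
                    "n_defining_diffs_to_nearest_other_allele": nearest,
                }
            )
    for name, variants in alleles.allelets.items():
        for k, (hap, _) in enumerate(variants):
            rows.append(
                {
                    "haplotype_id": hap,
                    "locus": alleles.locus,
                    "allele_name": name + "′" * (k + 1),
                    "status": "allelet",
                    "n_defining_diffs_to_nearest_other_allele": 0,
                }
            )
    _write_tsv(pd.DataFrame(rows), out / "alleles.tsv")

    diff_rows = []
    seen = set()
    for name, group in alleles.alleles.items():
        for other, diffs in group.defining.items():
            key = tuple(sorted((name, other)))
            if key in seen:
                continue
            seen.add(key)
            for d in diffs:
                diff_rows.append(
                    {
                        "allele_1": key[0],
                        "allele_2": key[1],
                        "column_1based": d.column + 1,
                        "kind": d.kind,
                        "length": d.length,
                        "region_type": d.region_type,
                        "in_string": d.in_string,
                        "coding_effect": d.coding_effect or "",
                    }
                )
    _write_tsv(pd.DataFrame(diff_rows), out / "defining_diffs.tsv")


def _hybrid_stages(
    config: RunConfig,
    alignment: HaplotypeAlignment,
    region_map: GeneRegionMap,
    alleles: AlleleSet,
    out: Path,
) -> dict:
    pa, pb = alignment.parent_a, alignment.parent_b
    summary: dict = {}

    paint_rows, bp_rows, contrib_rows = [], [], []
    for name, group in alleles.alleles.items():
        rep = alignment[group.representative]
        sites = informative_sites(rep, pa, pb)
        painting = paint(sites, alignment.n_columns, rep.id)
        for start, end, origin in painting.segments:
            paint_rows.append(
                {
                    "allele": name,
                    "segment_start_1based": start + 1,
                    "segment_end_1based": end,
                    "origin": origin,
                }
            )
        for left, right in painting.breakpoints:
            bp_rows.append(
                {
                    "allele": name,
                    "left_1based": left + 1,
                    "right_1based": right + 1,
                    "midpoint": round_half_up((left + right) / 2 + 1, 1),
                }
            )
        for rtype, summary_ in contribution_fractions(
            painting, region_map, config.bias_threshold
        ).items():
            contrib_rows.append(
                {
                    "allele": name,
                    "region_type": rtype,
                    "frac_A": summary_.frac_a,
                    "frac_B": summary_.frac_b,
                    "n_sites": summary_.n_sites,
                    "bias": summary_.bias,
                }
            )
    _write_tsv(pd.DataFrame(paint_rows), out / "painting.tsv")
    _write_tsv(pd.DataFrame(bp_rows), out / "breakpoints.tsv")
    _write_tsv(pd.DataFrame(contrib_rows), out / "contributions.tsv")
    summary["n_breakpoints_total"] = len(bp_rows)

    catalog = hybrid_mode_mutations(alleles, alignment, region_map, config.min_run)
    cat_rows = [
        {
            "id": r.id,
            "locus": r.locus,
            "anchor_column_1based": r.anchor_column + 1,
            "kind": r.kind,
            "length": r.length,
            "region_type": r.region_type,
            "coding_effect": r.coding_effect,
            "derived_state": r.derived_state,
            "carrier_alleles": ",".join(sorted(r.carrier_alleles)),
            "sharing": r.sharing or "",
            "in_string": r.in_string,
        }
        for r in catalog
    ]
    _write_tsv(pd.DataFrame(cat_rows), out / "mutations.tsv")
    summary["n_mutations"] = len(catalog)

    # Table-1-shaped densities: unique events per region / aligned length
    density_rows = []
    per_region_counts: dict[str, int] = {}
    for rtype in ("five_prime", "exon", "intron", "three_prime", "baseline"):
        length = region_map.aligned_length(rtype)
        if length == 0:
            continue
        n_events = sum(1 for r in catalog if r.region_type == rtype)
        per_region_counts[rtype] = n_events
        d = mutation_density(n_events, length, region_map.locus, rtype)
        density_rows.append(
            {
                "locus": d.locus,
                "region_type": "coding" if rtype == "exon" else rtype,
                "aligned_length": d.aligned_length,
                "n_mutations": d.n_mutations,
                "mutation_density": d.density_report,
            }
        )
    _write_tsv(pd.DataFrame(density_rows), out / "density.tsv")
    summary["densities"] = {
        row["region_type"]: row["mutation_density"] for row in density_rows
    }

    # baseline selection tests (Table-2-shaped)
    sel_rows = []
    if region_map.aligned_length("baseline") > 0 and alleles.n_alleles >= 2:
        rates = {}
        for rtype in ("five_prime", "exon", "baseline"):
            length = region_map.aligned_length(rtype)
            if length:
                rates[rtype] = per_allele_rates(catalog, alleles, rtype, length)
        comparisons = []
        if "five_prime" in rates and "baseline" in rates:
            comparisons.append(("five_prime_vs_baseline", "five_prime", "baseline"))
        if "exon" in rates and "baseline" in rates:
            comparisons.append(("coding_vs_baseline", "exon", "baseline"))
        if "five_prime" in rates and "exon" in rates:
            comparisons.append(("five_prime_vs_coding", "five_prime", "exon"))
        k = config.family_size or len(comparisons)
        alpha_prime = dunn_sidak(config.family_alpha, k) if comparisons else None
        for comp, r1, r2 in comparisons:
            res = baseline_test(
                list(rates[r1][2].values()),
                list(rates[r2][2].values()),
                alternative=config.tail,
                alpha_prime=alpha_prime,
                locus=region_map.locus,
                comparison=comp,
            )
            sel_rows.append(
                {
                    "locus": res.locus,
                    "comparison": res.comparison,
                    "mean_rate_1": round_half_up(res.mean_rate_1, 5),
                    "se_1": round_half_up(res.se_1, 6) if res.se_1 is not None else "",
                    "mean_rate_2": round_half_up(res.mean_rate_2, 5),
                    "se_2": round_half_up(res.se_2, 6) if res.se_2 is not None else "",
                    "t": "" if math.isnan(res.t_stat) else round_half_up(res.t_stat, 3),
                    "df": round_half_up(res.df, 2),
                    "p_one_tailed": res.p_one_tailed,
                    "tail": res.tail,
                    "alpha_prime": round_half_up(alpha_prime, 4),
                    "significant": res.significant,
                    "direction": res.direction,
                }
            )
        summary["alpha_prime"] = alpha_prime
        summary["selection"] = {
            row["comparison"]: row["direction"] for row in sel_rows
        }
    _write_tsv(pd.DataFrame(sel_rows), out / "selection.tsv")

    # Ka/Ks per allele against the parent_a reading frame
    kaks_rows = []
    try:
        from allelecall.coding import CodingFrame

        frame = CodingFrame(region_map, pa)
        ref_cds = frame.cds
        for name, group in alleles.alleles.items():
            rep = alignment[group.representative]
            allele_cds = "".join(
                rep.sequence[c]
                for c in region_map.exon_columns()
                if pa.sequence[c] != "-"
            )
            if len(allele_cds) != len(ref_cds):
                continue
            try:
                res = ka_ks(allele_cds, ref_cds, allele=name)
            except AlleleCallError:
                continue
            kaks_rows.append(
                {
                    "allele": name,
                    "Ka": round_half_up(res.Ka, 4),
                    "Ks": round_half_up(res.Ks, 4),
                    "Ka_Ks": round_half_up(res.ratio, 4)
                    if res.ratio is not None
                    else "undefined",
                    "syn_sites": round_half_up(res.syn_sites, 2),
                    "nonsyn_sites": round_half_up(res.nonsyn_sites, 2),
                    "syn_changes": round_half_up(res.syn_changes, 2),
                    "nonsyn_changes": round_half_up(res.nonsyn_changes, 2),
                }
            )
    except AlleleCallError:
        pass
    _write_tsv(pd.DataFrame(kaks_rows), out / "kaks.tsv")
    return summary


def _outgroup_stages(
    config: RunConfig,
    alignment: HaplotypeAlignment,
    region_map: GeneRegionMap,
    out: Path,
) -> dict:
    result = polarize_with_outgroup(
        alignment,
        freq_threshold=config.freq_threshold,
        strict=config.strict_threshold,
        locus=region_map.locus,
        region_map=region_map,
    )
    verdict = {}
    for r in result.excluded:
        verdict[r.id] = "excluded_ancestral"
    for r in result.unresolved:
        verdict[r.id] = "unresolved"
    rows = [
        {
            "id": r.id,
            "column_1based": r.anchor_column + 1,
            "region_type": r.region_type or "",
            "minor_state": r.derived_state,
            "n_carriers": len(r.carrier_alleles),
            "verdict": verdict.get(r.id, "retained_recent"),
        }
        for r in result.tentative
    ]
    _write_tsv(pd.DataFrame(rows), out / "polarization.tsv")

    density_rows = []
    retained = [r for r in result.retained]
    for rtype in ("five_prime", "exon"):
        length = region_map.aligned_length(rtype)
        if not length:
            continue
        n_events = sum(1 for r in retained if r.region_type == rtype)
        d = mutation_density(n_events, length, region_map.locus, rtype)
        density_rows.append(
            {
                "locus": d.locus,
                "region_type": "coding" if rtype == "exon" else rtype,
                "aligned_length": d.aligned_length,
                "n_mutations": d.n_mutations,
                "mutation_density": d.density_report,
            }
        )
    _write_tsv(pd.DataFrame(density_rows), out / "density.tsv")

    return {
        "n_tentative": len(result.tentative),
        "n_excluded_ancestral": len(result.excluded),
        "n_unresolved": len(result.unresolved),
        "error_rate": result.error_rate,
        "error_rate_report": result.error_rate_report,
        "densities": {
            row["region_type"]: row["mutation_density"] for row in density_rows
        },
    }
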