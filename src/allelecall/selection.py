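"""Mutation densities, the baseline selection test, and Ka/Ks.

The *mutation density* of a locus region is the number of lineage-specific
mutation events per aligned nucleotide accumulated over the comparison
period.  The *baseline test* compares the per-allele mutation rate of a
genic region (5' or coding) with the rate of a nearby co-genomic neutral
sequence -- an intergenic stretch or a long (> 800 bp) intron -- in the same
genomes: a significantly elevated rate indicates positive selection on the
region, a significantly depressed rate negative selection.  Families of
baseline comparisons are corrected with the Dunn-Sidak adjustment
``alpha' = 1 - (1 - alpha)^(1/k)``.

Per-allele protein-level selection uses Nei-Gojobori-style Ka/Ks counting:
fractional synonymous/nonsynonymous site counts per reference codon, with
multiple-hit codons averaged over all substitution pathways at equal
weights.  Ka and Ks are reported as raw proportions (changes per site);
at the sub-2% divergences this pipeline targets, multiple-hit corrections
are negligible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from allelecall.coding import translate_codon
from allelecall.errors import PreconditionError

BASES = "ACGT"


def round_half_up(x: float, decimals: int = 4) -> float:
    """Round half away from zero to ``decimals`` places (table convention)."""
    if not math.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# mutation density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityResult:
    """Mutation events per aligned nucleotide for one locus region."""

    locus: str
    region_type: str
    n_mutations: int
    aligned_length: int
    density: float

    @property
    def density_report(self) -> float:
        """Density rounded half-up to 4 decimals, as printed in reports."""
        return round_half_up(self.density, 4)


def mutation_density(
    n_mutations: int,
    aligned_length: int,
    locus: str = "",
    region_type: str = "",
) -> DensityResult:
    """Number of mutation events per aligned nucleotide of one region."""
    if aligned_length <= 0:
        raise PreconditionError("aligned_length must be positive")
    if n_mutations < 0:
        raise PreconditionError("n_mutations must be non-negative")
    return DensityResult(
        locus=locus,
        region_type=region_type,
        n_mutations=n_mutations,
        aligned_length=aligned_length,
        density=n_mutations / aligned_length,
    )


def per_allele_rates(
    catalog: list,
    alleles,
    region_type: str,
    aligned_length: int,
) -> tuple[float, float | None, dict[str, float]]:
    """Per-allele mutation rate of one region: events carried by the allele
    divided by the aligned region length.

    Returns (mean, standard error across alleles, per-allele rates); the
    standard error is None with fewer than two alleles.
    """
    if aligned_length <= 0:
        raise PreconditionError("aligned_length must be positive")
    names = list(alleles.alleles) if hasattr(alleles, "alleles") else list(alleles)
    if not names:
        raise PreconditionError("no alleles")
    counts = {name: 0 for name in names}
    for record in catalog:
        if record.region_type != region_type:
            continue
        for carrier in record.carrier_alleles:
            if carrier in counts:
                counts[carrier] += 1
    rates = {name: counts[name] / aligned_length for name in names}
    vec = np.array(list(rates.values()), dtype=float)
    mean = float(vec.mean())
    se = (
        float(vec.std(ddof=1) / math.sqrt(len(vec))) if len(vec) >= 2 else None
    )
    return mean, se, rates


# ---------------------------------------------------------------------------
# baseline test
# ---------------------------------------------------------------------------

@dataclass
class SelectionTestResult:
    """One baseline comparison: region rates vs neutral-baseline rates."""

    locus: str
    comparison: str
    mean_rate_1: float
    se_1: float | None
    n_1: int
    mean_rate_2: float
    se_2: float | None
    n_2: int
    t_stat: float
    df: float
    p_one_tailed: float
    tail: str  # greater | less
    alpha_prime: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_one_tailed < self.alpha_prime

    @property
    def direction(self) -> str:
        """positive_selection / negative_selection / none.

        Positive when the genic-region rate is significantly above the
        baseline rate, negative when significantly below; meaningful for
        region-vs-baseline comparisons.
        """
        if not self.significant or self.degenerate:
            return "none"
        return (
            "positive_selection"
            if self.mean_rate_1 > self.mean_rate_2
            else "negative_selection"
        )


def baseline_test(
    region_rates,
    baseline_rates,
    alternative: str = "auto",
    alpha_prime: float = 0.05,
    paired: bool = False,
    locus: str = "",
    comparison: str = "",
) -> SelectionTestResult:
    """One-tailed t-test between per-allele region rates and baseline rates.

    Default is Welch's two-sample test (unequal variances); ``paired=True``
    pairs rates genome-by-genome instead.  ``alternative='auto'`` picks the
    tail from the observed mean ordering and reports the p-value for that
    tail.  When every value in both vectors is identical the statistic is
    undefined; p is reported as 0.5 with the degenerate flag set.
    """
    x = np.asarray(list(region_rates), dtype=float)
    y = np.asarray(list(baseline_rates), dtype=float)
    if x.size == 0 or y.size == 0:
        raise PreconditionError("both rate vectors must be non-empty")
    if paired and x.size != y.size:
        raise PreconditionError("paired test needs equal-length vectors")
    if alternative == "auto":
        alternative = "greater" if x.mean() >= y.mean() else "less"
    if alternative not in ("greater", "less"):
        raise PreconditionError(f"unknown alternative {alternative!r}")

    def se(v: np.ndarray) -> float | None:
        return (
            float(v.std(ddof=1) / math.sqrt(v.size)) if v.size >= 2 else None
        )

    degenerate = (
        np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]
    ) or (paired and np.all(x - y == (x - y)[0]) and (x - y)[0] == 0)
    if degenerate:
        t_stat, p, df = math.nan, 0.5, float(x.size + y.size - 2)
    elif paired:
        res = stats.ttest_rel(x, y, alternative=alternative)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        with warnings.catch_warnings():
            # constant per-allele rates are a legitimate degenerate input here
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        if math.isnan(t_stat):
            t_stat, p, df = math.nan, 0.5, float(x.size + y.size - 2)
            degenerate = True

    return SelectionTestResult(
        locus=locus,
        comparison=comparison,
        mean_rate_1=float(x.mean()),
        se_1=se(x),
        n_1=int(x.size),
        mean_rate_2=float(y.mean()),
        se_2=se(y),
        n_2=int(y.size),
        t_stat=t_stat,
        df=df,
        p_one_tailed=p,
        tail=alternative,
        alpha_prime=alpha_prime,
        degenerate=degenerate,
    )


def one_sample_baseline_test(
    rate: float,
    baseline_mean: float,
    baseline_se: float,
    df: int,
    alternative: str = "greater",
    alpha_prime: float = 0.05,
    locus: str = "",
    comparison: str = "",
) -> SelectionTestResult:
    """Baseline test for a single allele against a summarized background.

    Used when the background is supplied as (mean, standard error, df):
    ``t = (rate - mean) / se`` referred to a t-distribution with ``df``
    degrees of freedom, one-tailed.
    """
    if baseline_se <= 0:
        raise PreconditionError("baseline_se must be positive")
    if df < 1:
        raise PreconditionError("df must be >= 1")
    t_stat = (rate - baseline_mean) / baseline_se
    if alternative == "auto":
        alternative = "greater" if t_stat >= 0 else "less"
    if alternative == "greater":
        p = float(stats.t.sf(t_stat, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t_stat, df))
    else:
        raise PreconditionError(f"unknown alternative {alternative!r}")
    return SelectionTestResult(
        locus=locus,
        comparison=comparison,
        mean_rate_1=rate,
        se_1=None,
        n_1=1,
        mean_rate_2=baseline_mean,
        se_2=baseline_se,
        n_2=df + 1,
        t_stat=float(t_stat),
        df=float(df),
        p_one_tailed=p,
        tail=alternative,
        alpha_prime=alpha_prime,
    )


def dunn_sidak(alpha: float, k: int) -> float:
    """Per-comparison critical level keeping family error at ``alpha`` over
    ``k`` independent comparisons: ``1 - (1 - alpha)^(1/k)``."""
    if not 0 < alpha < 1:
        raise PreconditionError("alpha must be in (0, 1)")
    if k < 1:
        raise PreconditionError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


# ---------------------------------------------------------------------------
# Ka / Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    """Nei-Gojobori-style counts and rates for one allele vs a reference."""

    allele: str
    syn_sites: float
    nonsyn_sites: float
    syn_changes: float
    nonsyn_changes: float
    n_codons: int
    skipped_codons: int = 0

    @property
    def Ka(self) -> float:
        return self.nonsyn_changes / self.nonsyn_sites if self.nonsyn_sites else 0.0

    @property
    def Ks(self) -> float:
        return self.syn_changes / self.syn_sites if self.syn_sites else 0.0

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or None when Ks == 0 (undefined, never infinity)."""
        if self.Ks == 0:
            return None
        return self.Ka / self.Ks

    @property
    def ratio_defined(self) -> bool:
        return self.Ks > 0


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon: each position
    contributes its fraction of synonymous single-base changes."""
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if translate_codon(mutant) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _codon_change_counts(ref: str, alt: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) change counts between two codons,
    averaged over all substitution pathways with equal weights."""
    positions = [i for i in range(3) if ref[i] != alt[i]]
    if not positions:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        current = ref
        for pos in order:
            nxt = current[:pos] + alt[pos] + current[pos + 1 :]
            if translate_codon(nxt) == translate_codon(current):
                syn_total += 1
            else:
                nonsyn_total += 1
            current = nxt
        n_paths += 1
    return syn_total / n_paths, nonsyn_total / n_paths


def ka_ks(
    allele_cds: str, reference_cds: str, allele: str = ""
) -> KaKsResult:
    """Ka and Ks of a degapped coding sequence against a reference CDS.

    Both sequences must be equal length, a multiple of 3, with no internal
    stop codons in the reference; a terminal reference stop codon is
    excluded from the counts.  Codons containing N or a gap in either
    sequence are skipped entirely (both sites and changes).
    """
    allele_cds = allele_cds.upper()
    reference_cds = reference_cds.upper()
    if len(allele_cds) != len(reference_cds):
        raise PreconditionError("coding sequences differ in length")
    if len(reference_cds) % 3:
        raise PreconditionError("coding length is not a multiple of 3")
    n = len(reference_cds) // 3
    codons = [
        (reference_cds[3 * i : 3 * i + 3], allele_cds[3 * i : 3 * i + 3])
        for i in range(n)
    ]
    if codons and set(codons[-1][0]) <= set("ACGT") and translate_codon(codons[-1][0]) == "*":
        codons = codons[:-1]
    for i, (ref, _) in enumerate(codons):
        if set(ref) <= set("ACGT") and translate_codon(ref) == "*":
            raise PreconditionError(f"internal stop codon at codon {i} of reference")

    syn_sites = nonsyn_sites = syn_changes = nonsyn_changes = 0.0
    skipped = 0
    for ref, alt in codons:
        if set(ref + alt) - set("ACGT"):
            skipped += 1
            continue
        s, ns = _codon_site_fractions(ref)
        syn_sites += s
        nonsyn_sites += ns
        sd, nd = _codon_change_counts(ref, alt)
        syn_changes += sd
        nonsyn_changes += nd
    return KaKsResult(
        allele=allele,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_changes=syn_changes,
        nonsyn_changes=nonsyn_changes,
        n_codons=len(codons) - skipped,
        skipped_codons=skipped,
    )


def intensity_ratio(time_depth_1: float, time_depth_2: float) -> float:
    """Relative selection intensity of two lineages that accumulated similar
    mutation densities over different time depths: the ratio of the depths.

    A lineage reaching the same density in 1/f of the time experienced an
    f-fold higher per-year intensity.
    """
    if time_depth_1 <= 0 or time_depth_2 <= 0:
        raise PreconditionError("time depths must be positive")
    return time_depth_1 / time_depth_2
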