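"""SNP quality control and genomic strain-differentiation analyses.

Implements the call-level filters (Phred quality >= 20, local read depth >=
10, biallelic-only) and the persistence rule (a variant, once detected, must
be re-detected at every later time point while its species is present),
codon-level effect classification, pseudogene (premature-stop) detection and
strain assignment, Nei-Gojobori pN/pS, binomial category enrichment, coverage
anomaly flags, read-density species abundances, and molecular-clock
divergence times between strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .io import GeneTable, SnpRecord, SnpTrajectory, ValidationError, reverse_complement

__all__ = [
    "SnpFilterConfig",
    "DivergenceParams",
    "EffectCall",
    "PnpsResult",
    "filter_snps",
    "flag_anomalous_genes",
    "metagenome_species_abundance",
    "classify_snp_effect",
    "detect_pseudogenes",
    "assign_pseudogene_to_strain",
    "nei_gojobori_sites",
    "compute_pnps",
    "category_enrichment",
    "category_genome_fractions",
    "divergence_time",
]

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"


# ---------------------------------------------------------------------------
# Filtering


@dataclass(frozen=True)
class SnpFilterConfig:
    """Variant-call quality filters (defaults match the study's thresholds)."""

    min_qual: float = 20.0
    min_depth: int = 10
    require_biallelic: bool = True
    require_persistence: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def filter_snps(
    records: Iterable[SnpRecord],
    config: SnpFilterConfig | None = None,
    species_abundance: Mapping[str, Sequence[float]] | None = None,
) -> tuple[list[SnpTrajectory], pd.DataFrame]:
    """Apply the SNP filters and build major-allele frequency trajectories.

    ``records`` must cover every time point for each genome (a genome with a
    gap in its time coverage raises). ``species_abundance`` maps genome id to
    its relative abundance per time point; the persistence requirement is
    waived from the first time point at which the species' abundance is zero.

    A site is *detected* at time t if a record at t passes the quality and
    depth thresholds with at least one alternate observation. The major
    allele (ref or alt, whichever is more frequent) is fixed at the first
    detection and tracked thereafter. Returns the retained trajectories and a
    rejection log with one reason per discarded site (checked in the order
    indel, triallelic, qual, depth, persistence; the filters are
    order-independent for which sites survive).
    """
    cfg = config or SnpFilterConfig()
    by_site: dict[tuple[str, int, str], dict[int, SnpRecord]] = {}
    times_per_genome: dict[str, set[int]] = {}
    all_times: set[int] = set()
    for rec in records:
        key = (rec.genome_id, rec.position, rec.alt_allele)
        by_site.setdefault(key, {})[rec.time_index] = rec
        times_per_genome.setdefault(rec.genome_id, set()).add(rec.time_index)
        all_times.add(rec.time_index)
    if not by_site:
        return [], pd.DataFrame(columns=["genome_id", "position", "alt", "reason"])
    T = max(all_times) + 1
    full = set(range(T))
    gaps = {g: sorted(full - ts) for g, ts in times_per_genome.items() if full - ts}
    if gaps:
        raise ValidationError(f"genomes with missing time points: {gaps}")

    retained: list[SnpTrajectory] = []
    rejected: list[dict] = []

    def reject(key, reason):
        rejected.append(
            {"genome_id": key[0], "position": key[1], "alt": key[2], "reason": reason}
        )

    for key, timeline in sorted(by_site.items()):
        genome, pos, alt = key
        recs = [timeline.get(t) for t in range(T)]
        if any(r is not None and not r.is_snp for r in recs):
            reject(key, "indel")
            continue
        if cfg.require_biallelic and any(
            r is not None and r.n_alts_at_site > 1 for r in recs
        ):
            reject(key, "triallelic")
            continue
        detected = np.zeros(T, dtype=bool)
        qual_fail = depth_fail = False
        for t, r in enumerate(recs):
            if r is None or r.alt_count == 0:
                continue
            if r.qual < cfg.min_qual:
                qual_fail = True
                continue
            if r.depth < cfg.min_depth:
                depth_fail = True
                continue
            detected[t] = True
        if not detected.any():
            reject(key, "qual" if qual_fail else ("depth" if depth_fail else "never-detected"))
            continue
        first = int(np.argmax(detected))
        if cfg.require_persistence:
            if species_abundance is not None and genome in species_abundance:
                ab = np.asarray(species_abundance[genome], dtype=float)
                zero = np.flatnonzero(ab[first:] == 0)
                horizon = first + int(zero[0]) if zero.size else T
            else:
                horizon = T
            if not detected[first:horizon].all():
                # attribute the break to a sub-threshold call when one exists
                reason = "qual" if qual_fail else ("depth" if depth_fail else "persistence")
                reject(key, reason)
                continue
        freqs = np.full(T, np.nan)
        depths = np.zeros(T)
        for t, r in enumerate(recs):
            if r is None:
                continue
            tot = r.alt_count + r.ref_count
            if tot == 0:
                continue
            freqs[t] = r.alt_count / tot
            depths[t] = r.depth
        first_rec = recs[first]
        major_is_alt = first_rec.alt_count >= first_rec.ref_count
        if not major_is_alt:
            freqs = 1.0 - freqs
        retained.append(
            SnpTrajectory(
                snp_id=first_rec.record_id or f"{genome}:{pos}:{alt}",
                genome_id=genome,
                position=pos,
                ref_allele=first_rec.ref_allele,
                alt_allele=alt,
                freqs=freqs,
                depths=depths,
                major_is_alt=major_is_alt,
                first_detected=first,
            )
        )
    log = pd.DataFrame(rejected, columns=["genome_id", "position", "alt", "reason"])
    return retained, log


def flag_anomalous_genes(coverage: pd.DataFrame) -> pd.DataFrame:
    """Flag genes with anomalous read coverage (read-stealing mitigation).

    ``coverage`` is genes x samples. A gene is flagged *low* in a sample when
    its coverage is strictly below half that sample's median, and *high* when
    strictly above three times the median in any sample (both bounds
    exclusive, reading the rule literally). Returns a frame indexed like
    ``coverage`` with boolean columns ``low`` (any sample), ``high`` (any
    sample) and ``flagged``.
    """
    cov = coverage.to_numpy(dtype=float)
    if (cov < 0).any():
        raise ValidationError("coverage must be non-negative")
    medians = np.median(cov, axis=0)
    if (medians == 0).any():
        bad = [c for c, m in zip(coverage.columns, medians) if m == 0]
        raise ValidationError(f"samples with zero median coverage: {bad}")
    low = (cov < 0.5 * medians).any(axis=1)
    high = (cov > 3.0 * medians).any(axis=1)
    return pd.DataFrame(
        {"low": low, "high": high, "flagged": low | high}, index=coverage.index
    )


def metagenome_species_abundance(
    read_counts: Mapping[str, float], genome_lengths: Mapping[str, float]
) -> dict[str, float]:
    """Relative species abundance from mapped reads, normalized by genome length."""
    densities = {}
    for genome, n in read_counts.items():
        length = genome_lengths[genome]
        if length <= 0:
            raise ValidationError(f"genome length must be > 0 for {genome}")
        densities[genome] = n / length
    total = sum(densities.values())
    if total == 0:
        raise ValidationError("no mapped reads in any genome")
    return {g: d / total for g, d in densities.items()}


# ---------------------------------------------------------------------------
# Effect classification and pseudogenes


@dataclass(frozen=True)
class EffectCall:
    snp_id: str
    effect: str  # synonymous | nonsynonymous | nonsense | intergenic | unclassified
    gene_id: str | None = None
    codon_index: int | None = None  # 0-based within the gene
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None

    def __post_init__(self) -> None:
        if self.effect == "nonsense" and self.aa_after != "*":
            raise ValidationError("nonsense calls must produce a stop codon")


def classify_snp_effect(snp: SnpTrajectory, genes: GeneTable) -> EffectCall:
    """Codon-level consequence of a SNP, evaluated on the coding strand.

    Intergenic SNPs get effect 'intergenic'; SNPs inside a gene whose frame is
    incomplete get 'unclassified'. For minus-strand genes the substitution is
    reverse-complemented before the codon lookup.
    """
    table = genes.genes_for(snp.genome_id)
    hit = table[(table["start"] <= snp.position) & (snp.position <= table["end"])]
    if hit.empty:
        return EffectCall(snp.snp_id, "intergenic")
    gene = hit.iloc[0]
    if not bool(gene["complete"]):
        return EffectCall(snp.snp_id, "unclassified", gene_id=gene["gene_id"])
    cds = genes.coding_sequence(gene["gene_id"])
    if gene["strand"] == "+":
        offset = snp.position - gene["start"]
        ref_c, alt_c = snp.ref_allele, snp.alt_allele
    else:
        offset = gene["end"] - snp.position
        ref_c = reverse_complement(snp.ref_allele)
        alt_c = reverse_complement(snp.alt_allele)
    codon_idx, within = divmod(offset, 3)
    before = cds[3 * codon_idx : 3 * codon_idx + 3]
    if before[within] != ref_c:
        # reference mismatch: classify against what the sequence actually holds
        ref_c = before[within]
    after = before[:within] + alt_c + before[within + 1 :]
    aa_before = _CODON_TO_AA.get(before)
    aa_after = _CODON_TO_AA.get(after)
    if aa_after == "*" and aa_before != "*":
        effect = "nonsense"
    elif aa_before == aa_after:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return EffectCall(
        snp.snp_id,
        effect,
        gene_id=gene["gene_id"],
        codon_index=int(codon_idx),
        codon_before=before,
        codon_after=after,
        aa_before=aa_before,
        aa_after=aa_after,
    )


def detect_pseudogenes(
    effects: Sequence[EffectCall],
    trajectories: Mapping[str, SnpTrajectory],
    genes: GeneTable,
) -> pd.DataFrame:
    """Pseudogene calls: genes hit by a persistent premature stop codon.

    ``effects`` are calls for SNPs that already satisfied the persistence
    rule; a stop created in a gene's final codon is not premature and is
    excluded. Returns one row per (gene, causal SNP) with the first-detected
    time index.
    """
    rows = []
    for eff in effects:
        if eff.effect != "nonsense":
            continue
        gene = genes.table.loc[genes.table["gene_id"] == eff.gene_id].iloc[0]
        n_codons = (gene["end"] - gene["start"] + 1) // 3
        if eff.codon_index >= n_codons - 1:
            continue  # terminal codon: not premature
        traj = trajectories[eff.snp_id]
        rows.append(
            {
                "gene_id": eff.gene_id,
                "snp_id": eff.snp_id,
                "first_detected": int(traj.first_detected),
                "codon_index": int(eff.codon_index),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "first_detected", "codon_index"])


def assign_pseudogene_to_strain(
    snp: SnpTrajectory,
    strain_frequency: np.ndarray,
    n_strains: int,
    tol: float = 0.1,
) -> str:
    """Assign a loss-of-function SNP to the strain whose frequency it tracks.

    ``strain_frequency`` is strain 1's frequency trajectory f(t); strain 2 has
    1 - f(t). The SNP is assigned to the unique strain whose frequency matches
    its allele frequency within ``tol`` (the allele-frequency least count) at
    every time point where the SNP is detected; if it is consistent with both
    strains or with neither, it stays 'unassigned'.
    """
    if n_strains != 2:
        raise ValidationError("strain assignment requires a two-strain species")
    f = np.asarray(strain_frequency, dtype=float)
    obs = np.asarray(snp.freqs, dtype=float)
    mask = np.isfinite(obs)
    ok1 = bool(np.all(np.abs(obs[mask] - f[mask]) <= tol))
    ok2 = bool(np.all(np.abs(obs[mask] - (1.0 - f[mask])) <= tol))
    if ok1 and not ok2:
        return "strain_1"
    if ok2 and not ok1:
        return "strain_2"
    return "unassigned"


# ---------------------------------------------------------------------------
# pN/pS (Nei-Gojobori site counting)


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (N, S) site counts of one codon over its 9 single-nt changes."""
    aa = _CODON_TO_AA.get(codon)
    if aa is None:
        return (0.0, 0.0)
    n_sites = s_sites = 0.0
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if _CODON_TO_AA.get(mutant) == aa:
                syn += 1
        s_sites += syn / 3.0
        n_sites += (3 - syn) / 3.0
    return (n_sites, s_sites)


def nei_gojobori_sites(cds: str) -> tuple[float, float]:
    """Expected nonsynonymous and synonymous site counts of a coding sequence.

    Each codon contributes fractional N/S sites summing to 3 (stop codons in
    the reference frame contribute nothing and changes *to* a stop count as
    nonsynonymous).
    """
    n_tot = s_tot = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if _CODON_TO_AA.get(codon) == "*":
            continue
        n, s = _codon_site_counts(codon)
        n_tot += n
        s_tot += s
    return (n_tot, s_tot)


@dataclass(frozen=True)
class PnpsResult:
    gene_set_id: str
    n_sites: float
    s_sites: float
    n_observed: int
    s_observed: int
    pnps: float  # NaN when undefined
    undefined: bool

    @property
    def pn(self) -> float:
        return self.n_observed / self.n_sites if self.n_sites else math.nan

    @property
    def ps(self) -> float:
        return self.s_observed / self.s_sites if self.s_sites else math.nan


def compute_pnps(
    effects: Sequence[EffectCall],
    genes: GeneTable,
    gene_subset: Sequence[str] | None = None,
    gene_set_id: str = "all",
) -> PnpsResult:
    """pN/pS over a gene subset by Nei-Gojobori site counting.

    Observed nonsynonymous counts include nonsense changes (a premature stop
    is an amino-acid change); no multiple-hit correction is applied, i.e.
    this is the polymorphism ratio pN/pS, not dN/dS. Undefined (flagged, NaN)
    when no synonymous change was observed.
    """
    subset = set(gene_subset) if gene_subset is not None else set(genes.table["gene_id"])
    if not subset:
        raise ValidationError("empty gene subset")
    in_set = [e for e in effects if e.gene_id in subset and e.effect in ("synonymous", "nonsynonymous", "nonsense")]
    if not in_set:
        raise ValidationError("no classified SNPs in the gene subset")
    n_sites = s_sites = 0.0
    for gene_id in sorted(subset):
        n, s = nei_gojobori_sites(genes.coding_sequence(gene_id))
        n_sites += n
        s_sites += s
    n_obs = sum(1 for e in in_set if e.effect in ("nonsynonymous", "nonsense"))
    s_obs = sum(1 for e in in_set if e.effect == "synonymous")
    if s_obs == 0 or s_sites == 0:
        return PnpsResult(gene_set_id, n_sites, s_sites, n_obs, s_obs, math.nan, True)
    pnps = (n_obs / n_sites) / (s_obs / s_sites)
    return PnpsResult(gene_set_id, n_sites, s_sites, n_obs, s_obs, pnps, False)


# ---------------------------------------------------------------------------
# Category enrichment


def category_genome_fractions(genes: GeneTable) -> dict[str, float]:
    """Fraction of total annotated coding length in each category label."""
    t = genes.table
    lengths = (t["end"] - t["start"] + 1).groupby(t["category"]).sum()
    total = float(lengths.sum())
    return {cat: float(l) / total for cat, l in lengths.items()}


def category_enrichment(
    snp_counts: Mapping[str, int],
    category_fractions: Mapping[str, float],
    total_snps: int,
) -> pd.DataFrame:
    """Binomial enrichment of SNP counts per functional category.

    Under the null, the count in a category is Binomial(total_snps, fraction)
    where the fraction is the category's share of annotated coding length.
    p = P(X >= observed) (one-sided upper tail); enrichment score = 1/p.
    """
    rows = []
    for cat, obs in snp_counts.items():
        frac = category_fractions.get(cat, 0.0)
        if obs > total_snps:
            raise ValidationError(f"category {cat}: observed {obs} > total {total_snps}")
        if frac <= 0:
            if obs > 0:
                raise ValidationError(f"category {cat}: nonzero count with zero genome fraction")
            continue
        p = float(stats.binom.sf(obs - 1, total_snps, frac))  # P(X >= obs)
        rows.append(
            {
                "category": cat,
                "observed": int(obs),
                "expected": total_snps * frac,
                "p_value": p,
                "enrichment_score": 1.0 / p,
            }
        )
    return (
        pd.DataFrame(rows, columns=["category", "observed", "expected", "p_value", "enrichment_score"])
        .sort_values("p_value", kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Divergence time


@dataclass(frozen=True)
class DivergenceParams:
    """Molecular-clock parameters for soil bacteria.

    mu: mutations per nucleotide per generation (1e-8); L: genome size in bp
    (1e6); g: generations per year (~100 doublings/year in the wild). Under
    neutrality the divergence rate equals the per-individual mutation rate,
    so one SNP accumulates every 1/(mu*L) generations.
    """

    mu: float = 1e-8
    L: float = 1e6
    g: float = 100.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.L <= 0 or self.g <= 0:
            raise ValueError("all divergence parameters must be > 0")


def divergence_time(n_snps: float, params: DivergenceParams | None = None) -> tuple[float, float]:
    """(generations, years) for two strains to diverge by ``n_snps`` SNPs."""
    p = params or DivergenceParams()
    generations = n_snps / (p.mu * p.L)
    return generations, generations / p.g
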