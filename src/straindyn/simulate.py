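"""Synthetic communities with the statistical structure the analysis assumes.

The generator emulates the study design: 10 serially passaged communities,
~10 species each, two coexisting strains per species, metagenomes at 8 evenly
spaced time points. Species abundances fluctuate around their means with
gamma-distributed noise (the empirical law used by the interaction null
model); each species carries a cluster of linked SNPs differentiating its two
strains plus a cluster of shared, nearly fixed SNPs; observed allele
frequencies carry binomial read-depth sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, GeneTable, SnpTrajectory

__all__ = [
    "PassageSchedule",
    "DepthModel",
    "SpeciesTruth",
    "TruthCommunity",
    "TruthConfig",
    "generations_elapsed",
    "generate_truth",
    "observe_snps",
    "study_cohort",
    "generate_genes",
    "write_snp_vcf",
    "write_community_fixtures",
    "write_gene_fixtures",
]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

DEFAULT_CATEGORIES = (
    "two-component system",
    "carbon metabolism",
    "transcription factors",
    "transporters",
    "motility",
    "phage",
    "translation",
    "other",
)


@dataclass(frozen=True)
class PassageSchedule:
    """Serial-dilution schedule: ``n_transfers`` cycles at a fixed dilution.

    Each 1:D dilution-regrowth cycle corresponds to log2(D) doublings, so the
    default study regime (dilution 100) adds ~6.64 generations per transfer.
    """

    n_transfers: int
    dilution_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError(f"dilution factor must exceed 1, got {self.dilution_factor}")
        if self.n_transfers < 0:
            raise ValueError("n_transfers must be non-negative")

    @property
    def generations_per_transfer(self) -> float:
        return math.log2(self.dilution_factor)

    @property
    def total_generations(self) -> float:
        return self.n_transfers * self.generations_per_transfer


def generations_elapsed(schedule: PassageSchedule | Iterable[PassageSchedule]) -> float:
    """Total generations elapsed over one schedule or a sequence of regimes."""
    if isinstance(schedule, PassageSchedule):
        return schedule.total_generations
    return float(sum(s.total_generations for s in schedule))


@dataclass(frozen=True)
class DepthModel:
    """Poisson read-depth model around ``mean_depth`` (dispersion reserved)."""

    mean_depth: float = 50.0
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean depth must be >= 1")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        # zero-depth draws are bumped to 1 so every time point yields a call
        return np.maximum(1, rng.poisson(self.mean_depth, size=size))


@dataclass
class SpeciesTruth:
    species_id: str
    mean_abundance: float
    abundance_var: float
    abundance: np.ndarray          # true relative abundance per time point
    strain_frequency: np.ndarray   # true strain-1 frequency f(t) in [0,1]
    n_strains: int
    n_diff_snps: int
    n_shared_snps: int


@dataclass
class TruthCommunity:
    community_id: str
    species: list[SpeciesTruth]
    schedule: PassageSchedule
    times: np.ndarray  # generation coordinate of each sampled time point

    @property
    def abundance_table(self) -> AbundanceTable:
        values = pd.DataFrame(
            {t: [sp.abundance[i] for sp in self.species] for i, t in enumerate(self.times)},
            index=[sp.species_id for sp in self.species],
        )
        lineage = pd.DataFrame(
            {
                "family": [f"family_{sp.species_id.split('_')[-1]}" for sp in self.species],
                "genus": [f"genus_{sp.species_id.split('_')[-1]}" for sp in self.species],
                "species": [sp.species_id for sp in self.species],
                "strain": ["" for _ in self.species],
            },
            index=[sp.species_id for sp in self.species],
        )
        values.index.name = "taxon_id"
        return AbundanceTable(values, lineage, renormalize=True)


@dataclass(frozen=True)
class TruthConfig:
    """Study-scale defaults: 8 time points, gamma abundance noise, 2 strains.

    ``strain_process`` selects how the true strain-1 frequency f(t) moves:
    ``constant`` (flat at ``f0``), ``random-walk`` (Gaussian steps of sd
    ``walk_sd``, clipped), or ``driven`` (logistic sweep at ``sweep_rate`` per
    time point, emulating one strain displacing the other).
    """

    n_timepoints: int = 8
    mean_abundances: Sequence[float] | None = None  # default: geometric ranks
    abundance_cv: float = 0.31          # the study's median temporal CV
    strain_process: str = "random-walk"
    f0: float = 0.6
    walk_sd: float = 0.1
    sweep_rate: float = 1.0
    p_two_strains: float = 1.0
    diff_snp_range: tuple[int, int] = (30, 300)    # log-uniform draw
    shared_snp_range: tuple[int, int] = (20, 200)
    genome_length: int = 1_000_000
    fixed_allele_freq: float = 0.99
    schedule: PassageSchedule = field(default_factory=lambda: PassageSchedule(46, 100.0))

    def __post_init__(self) -> None:
        if self.abundance_cv < 0:
            raise ValueError("abundance_cv must be >= 0")
        if self.strain_process not in ("constant", "random-walk", "driven"):
            raise ValueError(f"unknown strain process {self.strain_process!r}")


def _strain_frequency_path(cfg: TruthConfig, rng: np.random.Generator) -> np.ndarray:
    T = cfg.n_timepoints
    if cfg.strain_process == "constant":
        return np.full(T, cfg.f0)
    if cfg.strain_process == "random-walk":
        steps = rng.normal(0.0, cfg.walk_sd, size=T - 1)
        f = np.empty(T)
        f[0] = cfg.f0
        for t in range(1, T):
            f[t] = min(1.0, max(0.0, f[t - 1] + steps[t - 1]))
        return f
    # driven: logistic sweep from f0 toward fixation of strain 1
    t = np.arange(T, dtype=float)
    x0 = math.log(cfg.f0 / (1 - cfg.f0)) if 0 < cfg.f0 < 1 else 0.0
    return 1.0 / (1.0 + np.exp(-(x0 + cfg.sweep_rate * t)))


def generate_truth(
    n_communities: int,
    n_species: int,
    seed: int,
    config: TruthConfig | None = None,
) -> list[TruthCommunity]:
    """Ground-truth communities: gamma-fluctuating species, two strains each.

    Per species the abundance at each time point is an independent gamma draw
    with the species' mean and variance (shape = mean^2/var), renormalized
    across species per time point; the strain-1 frequency follows the
    configured process, clipped to [0, 1]. Reproducible given ``seed``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)
    if cfg.mean_abundances is not None:
        means = np.asarray(cfg.mean_abundances, dtype=float)
        if means.size != n_species:
            raise ValueError("mean_abundances length must equal n_species")
    else:
        means = 0.6 ** np.arange(n_species)  # geometric rank-abundance
    means = means / means.sum()
    times = np.cumsum(
        np.full(cfg.n_timepoints, generations_elapsed(cfg.schedule) / cfg.n_timepoints)
    )
    communities = []
    for c in range(n_communities):
        species = []
        for s in range(n_species):
            mean = means[s]
            var = (cfg.abundance_cv * mean) ** 2
            if cfg.abundance_cv == 0:
                traj = np.full(cfg.n_timepoints, mean)
            else:
                if var <= 0:
                    raise ValueError("abundance variance must be > 0")
                shape = mean**2 / var
                scale = var / mean
                traj = rng.gamma(shape, scale, size=cfg.n_timepoints)
            two = rng.random() < cfg.p_two_strains
            lo, hi = cfg.diff_snp_range
            n_diff = int(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if two else 0
            lo_s, hi_s = cfg.shared_snp_range
            n_shared = int(np.exp(rng.uniform(np.log(lo_s), np.log(hi_s))))
            f = _strain_frequency_path(cfg, rng) if two else np.ones(cfg.n_timepoints)
            species.append(
                SpeciesTruth(
                    species_id=f"sp_{s:02d}",
                    mean_abundance=float(mean),
                    abundance_var=float(var),
                    abundance=traj,
                    strain_frequency=np.clip(f, 0.0, 1.0),
                    n_strains=2 if two else 1,
                    n_diff_snps=n_diff,
                    n_shared_snps=n_shared,
                )
            )
        total = np.sum([sp.abundance for sp in species], axis=0)
        for sp in species:
            sp.abundance = sp.abundance / total
        communities.append(
            TruthCommunity(
                community_id=f"M{c + 1:02d}",
                species=species,
                schedule=cfg.schedule,
                times=times,
            )
        )
    return communities


def observe_snps(
    truth: TruthCommunity,
    depth_model: DepthModel | None = None,
    seed: int = 0,
    genome_length: int = 1_000_000,
    fixed_allele_freq: float = 0.99,
) -> list[SnpTrajectory]:
    """Binomial read-sampling observation of every SNP in a truth community.

    Differentiating SNPs are observed at frequency Binomial(depth, f(t))/depth;
    shared SNPs at Binomial(depth, ~1)/depth. Positions are distinct uniform
    draws along each species' reference genome; true cluster membership is
    recorded in the snp_id (``<species>:diff:<k>`` / ``<species>:shared:<k>``).
    """
    dm = depth_model or DepthModel()
    rng = np.random.default_rng(seed)
    out: list[SnpTrajectory] = []
    T = len(truth.times)
    bases = np.array(list("ACGT"))
    for sp in truth.species:
        if sp.n_strains == 2 and sp.n_diff_snps < 1:
            raise ValueError(f"{sp.species_id}: two strains but no differentiating SNPs")
        n_total = sp.n_diff_snps + sp.n_shared_snps
        positions = rng.choice(genome_length, size=n_total, replace=False) + 1
        for k in range(n_total):
            is_diff = k < sp.n_diff_snps
            p = sp.strain_frequency if is_diff else np.full(T, fixed_allele_freq)
            depths = dm.sample(rng, T)
            freqs = rng.binomial(depths, np.clip(p, 0, 1)) / depths
            ref = bases[rng.integers(4)]
            alt = bases[(np.flatnonzero(bases == ref)[0] + rng.integers(1, 4)) % 4]
            label = "diff" if is_diff else "shared"
            idx = k if is_diff else k - sp.n_diff_snps
            out.append(
                SnpTrajectory(
                    snp_id=f"{sp.species_id}:{label}:{idx}",
                    genome_id=sp.species_id,
                    position=int(positions[k]),
                    ref_allele=str(ref),
                    alt_allele=str(alt),
                    freqs=freqs,
                    depths=depths.astype(float),
                )
            )
    return out


def study_cohort(
    seed: int = 2027,
    n_communities: int = 10,
    n_species: int = 10,
    mean_depth: float = 100.0,
    config: TruthConfig | None = None,
) -> tuple[list[TruthCommunity], dict[str, list[SnpTrajectory]]]:
    """The default study-scale cohort: 10 communities, 8 time points, ~10
    species each with two strains, plus binomially observed SNPs per
    community. Returns (communities, {community_id: trajectories})."""
    cfg = config or TruthConfig()
    communities = generate_truth(n_communities, n_species, seed=seed, config=cfg)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_communities)
    observations = {
        com.community_id: observe_snps(
            com, DepthModel(mean_depth), seed=int(child_seeds[i] % 2**31)
        )
        for i, com in enumerate(communities)
    }
    return communities, observations


# ---------------------------------------------------------------------------
# Gene fixtures


def generate_genes(
    n_genes: int,
    length_codons: int,
    seed: int = 0,
    genome_id: str = "sp_00",
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    spacer: int = 50,
    minus_strand_fraction: float = 0.3,
) -> GeneTable:
    """Synthetic genome of complete ORFs (ATG ... stop) with category labels.

    Genes are laid head-to-tail on one contig separated by random intergenic
    spacers; a fraction is placed on the minus strand (the stored genome
    carries the reverse complement there). Category labels cycle through the
    supplied palette.
    """
    if length_codons < 2:
        raise ValueError("length_codons must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    chunks: list[str] = []
    pos = 1
    for g in range(n_genes):
        gap = "".join(rng.choice(list("ACGT"), size=spacer + int(rng.integers(0, spacer))))
        chunks.append(gap)
        pos += len(gap)
        body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=length_codons - 2)]
        cds = "ATG" + "".join(body) + _STOPS[rng.integers(0, 3)]
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        start, end = pos, pos + len(cds) - 1
        from .io import reverse_complement

        chunks.append(reverse_complement(cds) if strand == "-" else cds)
        pos = end + 1
        rows.append(
            {
                "gene_id": f"{genome_id}:gene_{g:04d}",
                "genome_id": genome_id,
                "start": start,
                "end": end,
                "strand": strand,
                "frame": 0,
                "category": categories[g % len(categories)],
                "complete": True,
            }
        )
    tail = "".join(rng.choice(list("ACGT"), size=spacer))
    chunks.append(tail)
    return GeneTable(pd.DataFrame(rows), {genome_id: "".join(chunks)})


# ---------------------------------------------------------------------------
# Fixture writers (plain-text VCF / TSV / FASTA)

def write_snp_vcf(
    trajectories: Sequence[SnpTrajectory],
    time_index: int,
    path: str | Path,
    qual: float = 60.0,
    genome_length: int = 1_000_000,
) -> None:
    """Write one time point of SNP observations as a FreeBayes-dialect VCF."""
    by_genome: dict[str, list[SnpTrajectory]] = {}
    for tr in trajectories:
        by_genome.setdefault(tr.genome_id, []).append(tr)
    lines = []
    contigs = "".join(
        f"##contig=<ID={g},length={genome_length}>\n" for g in sorted(by_genome)
    )
    header = (
        "##fileformat=VCFv4.2\n##source=straindyn-synthetic\n"
        + contigs
        + '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n'
        + '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">\n'
        + '##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observations">\n'
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    for genome in sorted(by_genome):
        for tr in sorted(by_genome[genome], key=lambda t: t.position):
            depth = int(tr.depths[time_index])
            freq = tr.freqs[time_index]
            if not np.isfinite(freq):
                continue
            ao = int(round(freq * depth))
            ro = depth - ao
            if ao == 0:
                continue  # alt allele not observed at this time point
            lines.append(
                f"{genome}\t{tr.position}\t{tr.snp_id}\t{tr.ref_allele}\t"
                f"{tr.alt_allele}\t{qual:.1f}\t.\tDP={depth};AO={ao};RO={ro}\n"
            )
    with open(path, "w") as fh:
        fh.write(header)
        fh.writelines(lines)


def write_community_fixtures(
    truth: TruthCommunity,
    trajectories: Sequence[SnpTrajectory],
    out_dir: str | Path,
    genome_length: int = 1_000_000,
) -> dict:
    """Write VCFs (one per time point) and the abundance TSV for a community."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcfs = []
    for t in range(len(truth.times)):
        vcf_path = out_dir / f"{truth.community_id}_t{t}.vcf"
        write_snp_vcf(trajectories, t, vcf_path, genome_length=genome_length)
        vcfs.append(str(vcf_path))
    ab_path = out_dir / f"{truth.community_id}_abundance.tsv"
    from .io import write_abundance_table

    write_abundance_table(truth.abundance_table, ab_path)
    return {"vcfs": vcfs, "abundance": str(ab_path)}


def write_gene_fixtures(genes: GeneTable, out_dir: str | Path, stem: str = "genes") -> dict:
    """Write the gene table (TSV) and genome sequences (FASTA)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / f"{stem}.tsv"
    fasta_path = out_dir / f"{stem}.fasta"
    genes.table.to_csv(table_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for genome_id, seq in genes.sequences.items():
            fh.write(f">{genome_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return {"table": str(table_path), "fasta": str(fasta_path)}
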