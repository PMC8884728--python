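"""Readers, writers and validated domain containers for the pipeline's formats.

VCF (FreeBayes dialect) carries per-time-point SNP calls; TSV carries taxa x
time relative-abundance tables with a taxonomic lineage per taxon; TSV + FASTA
carry gene coordinates and sequences. Coordinates are 1-based inclusive
(VCF/GFF convention); the time axis is a 0-based index mapped to generation
coordinates by the passage schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "FormatError",
    "ValidationError",
    "SnpRecord",
    "SnpTrajectory",
    "AbundanceTable",
    "GeneTable",
    "read_snp_vcf",
    "read_abundance_table",
    "write_abundance_table",
    "read_gene_table",
    "write_results",
]

LINEAGE_LEVELS = ("family", "genus", "species", "strain")

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing fields)."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True)
class SnpRecord:
    """One (site, alternate allele) observation at one time point.

    ``n_alts_at_site`` counts the alternate alleles seen at the site, so
    biallelic sites have ``n_alts_at_site == 1``. Indels are parsed and kept
    (``is_snp=False``) but routed out of the SNP pipeline downstream.
    """

    genome_id: str
    position: int  # 1-based bp
    ref_allele: str
    alt_allele: str
    time_index: int
    qual: float
    depth: int
    alt_count: int
    ref_count: int
    n_alts_at_site: int = 1
    is_snp: bool = True
    record_id: str | None = None  # VCF ID column, when present

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.qual < 0:
            raise ValidationError(f"qual must be >= 0, got {self.qual}")
        if self.alt_count + self.ref_count > self.depth:
            raise ValidationError(
                f"allele observations ({self.alt_count}+{self.ref_count}) exceed "
                f"depth {self.depth} at {self.genome_id}:{self.position}"
            )

    @property
    def site(self) -> tuple[str, int]:
        return (self.genome_id, self.position)

    @property
    def alt_frequency(self) -> float:
        tot = self.alt_count + self.ref_count
        return self.alt_count / tot if tot else np.nan


@dataclass
class SnpTrajectory:
    """Major-allele frequency and read depth of one biallelic SNP across time.

    ``freqs[t]`` is NaN where the SNP's species had no qualifying call. The
    major allele is fixed at first detection and tracked consistently.
    """

    snp_id: str
    genome_id: str
    position: int
    ref_allele: str
    alt_allele: str
    freqs: np.ndarray
    depths: np.ndarray
    major_is_alt: bool = True
    gene_id: str | None = None
    first_detected: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.freqs.shape != self.depths.shape:
            raise ValidationError("freqs and depths must have the same length")
        ok = self.freqs[np.isfinite(self.freqs)]
        if ok.size and (ok.min() < -1e-9 or ok.max() > 1 + 1e-9):
            raise ValidationError("frequencies must lie in [0, 1]")

    @property
    def n_times(self) -> int:
        return self.freqs.size


class AbundanceTable:
    """Taxa x time relative abundances with a taxonomy lineage per taxon.

    ``values`` is a DataFrame indexed by taxon id with one float column per
    generation coordinate; every column sums to 1. ``lineage`` is indexed the
    same way with columns family/genus/species/strain (strain may be empty).
    """

    def __init__(self, values: pd.DataFrame, lineage: pd.DataFrame, *, renormalize: bool = False):
        values = values.astype(float).copy()
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative abundance encountered")
        sums = values.sum(axis=0).to_numpy()
        if renormalize:
            bad = np.abs(sums - 1.0) > 1e-3
            if bad.any():
                raise ValidationError(
                    f"column sums {sums[bad]} deviate from 1 by more than 1e-3"
                )
            nz = sums > 0
            values.loc[:, nz] = values.loc[:, nz] / sums[nz]
        else:
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValidationError(f"columns must sum to 1 (+-1e-6), got {sums}")
        lineage = lineage.reindex(values.index)
        if lineage.isna().all(axis=1).any():
            missing = lineage.index[lineage.isna().all(axis=1)].tolist()
            raise ValidationError(f"taxa without lineage: {missing}")
        self.values = values
        self.lineage = lineage

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.values.columns])

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def trajectory(self, taxon: str) -> np.ndarray:
        return self.values.loc[taxon].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.values.equals(other.values) and self.lineage.equals(other.lineage)

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready frame: taxon_id, lineage columns, one column per time."""
        out = self.lineage.copy()
        for col in self.values.columns:
            out[str(col)] = self.values[col]
        out.insert(0, "taxon_id", out.index)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, renormalize: bool = True) -> "AbundanceTable":
        frame = frame.set_index("taxon_id")
        lineage_cols = [c for c in LINEAGE_LEVELS if c in frame.columns]
        time_cols = [c for c in frame.columns if c not in lineage_cols]
        values = frame[time_cols]
        values.columns = [float(c) for c in time_cols]
        return cls(values, frame[lineage_cols], renormalize=renormalize)


@dataclass
class GeneTable:
    """Gene coordinates, strand, frame and category labels for one or more genomes.

    ``table`` columns: gene_id, genome_id, start, end (1-based inclusive),
    strand (+/-), frame, category, complete (bool). ``sequences`` maps
    genome_id to its nucleotide sequence (str, 1-based addressing via pos-1).
    """

    table: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "genome_id", "start", "end", "strand", "frame", "category", "complete"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"gene table missing columns: {sorted(missing)}")
        if (t["start"] > t["end"]).any():
            raise ValidationError("gene start must be <= end")
        coding = t[t["complete"].astype(bool)]
        bad = coding[(coding["end"] - coding["start"] + 1) % 3 != 0]
        if len(bad):
            raise ValidationError(
                f"complete coding genes with length not divisible by 3: {bad['gene_id'].tolist()}"
            )

    def genes_for(self, genome_id: str) -> pd.DataFrame:
        return self.table[self.table["genome_id"] == genome_id]

    def coding_sequence(self, gene_id: str) -> str:
        """Coding-strand sequence of a gene (reverse-complemented for '-')."""
        row = self.table.loc[self.table["gene_id"] == gene_id].iloc[0]
        seq = self.sequences[row["genome_id"]][row["start"] - 1 : row["end"]]
        if row["strand"] == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# VCF reading


def _info_or_none(variant, key):
    try:
        return variant.INFO[key]
    except KeyError:
        return None


def _as_tuple(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, (tuple, list, np.ndarray)):
        return tuple(np.atleast_1d(value).tolist())
    return (value,)


def read_snp_vcf(path: str | Path, time_index: int) -> list[SnpRecord]:
    """Read one VCF (one time point) into SnpRecords, one per (site, alt).

    FreeBayes dialect first: INFO DP (total depth), AO (alt observations, one
    per alt), RO (reference observations). Falls back to the first sample's
    FORMAT AD when AO/RO are absent. Indels are parsed with ``is_snp=False``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    records: list[SnpRecord] = []
    for variant in vcf:
        alts = [a for a in variant.ALT if a != "<*>"]
        if not alts:
            continue
        dp = _info_or_none(variant, "DP")
        ao = _as_tuple(_info_or_none(variant, "AO"))
        ro = _info_or_none(variant, "RO")
        if not ao or ro is None:
            # FORMAT AD fallback: [ref, alt1, alt2, ...] for the first sample
            try:
                ad = np.atleast_2d(variant.format("AD"))[0]
            except (KeyError, TypeError) as exc:
                raise FormatError(
                    f"{path.name} {variant.CHROM}:{variant.POS}: no INFO AO/RO "
                    "and no FORMAT AD field to recover allele counts"
                ) from exc
            ro = int(ad[0])
            ao = tuple(int(x) for x in ad[1 : 1 + len(alts)])
        if dp is None:
            dp = int(ro) + int(sum(ao))
            if dp == 0:
                raise FormatError(
                    f"{path.name} {variant.CHROM}:{variant.POS}: missing DP field"
                )
        for alt, alt_obs in zip(alts, ao):
            is_snp = (
                len(variant.REF) == 1
                and len(alt) == 1
                and variant.REF.upper() in _NUCLEOTIDES
                and alt.upper() in _NUCLEOTIDES
            )
            records.append(
                SnpRecord(
                    genome_id=variant.CHROM,
                    position=variant.POS,
                    ref_allele=variant.REF,
                    alt_allele=alt,
                    time_index=time_index,
                    qual=float(variant.QUAL) if variant.QUAL is not None else 0.0,
                    depth=int(dp),
                    alt_count=int(alt_obs),
                    ref_count=int(ro),
                    n_alts_at_site=len(alts),
                    is_snp=is_snp,
                    record_id=variant.ID,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Abundance tables


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a taxa x time TSV (taxon_id, lineage columns, one column per time).

    Column sums within 1e-3 of 1 are renormalized to exactly 1; larger
    deviations raise :class:`ValidationError`.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    if "taxon_id" not in frame.columns:
        raise FormatError(f"{path}: expected a 'taxon_id' column")
    for col in frame.columns:
        if col not in ("taxon_id",) + LINEAGE_LEVELS:
            try:
                float(col)
            except ValueError:
                raise FormatError(f"{path}: column {col!r} is neither lineage nor a time") from None
    return AbundanceTable.from_frame(frame.fillna({"strain": ""}))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_table(table_path: str | Path, fasta_path: str | Path) -> GeneTable:
    from Bio import SeqIO

    table = pd.read_csv(table_path, sep="\t")
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    return GeneTable(table, sequences)


# ---------------------------------------------------------------------------
# Results writing


def write_results(
    tables: Mapping[str, pd.DataFrame | AbundanceTable] | Iterable[tuple[str, pd.DataFrame | AbundanceTable]],
    out_dir: str | Path,
    *,
    overwrite: bool = False,
) -> list[dict]:
    """Write result tables as TSV under ``out_dir``; return a manifest.

    Column order is preserved as stored (deterministic); floats are written at
    full precision so a round-trip read reproduces values to 1e-9. Name
    collisions (within the call or with existing files) raise unless
    ``overwrite`` is set.
    """
    items = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate result table names: {dupes}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for name, table in items:
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
        frame = table.to_frame() if isinstance(table, AbundanceTable) else table
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
        manifest.append({"name": name, "file": path.name, "rows": int(len(frame))})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
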