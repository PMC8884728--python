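"""Dynamical-correlation statistics and their null models.

At equilibrium, ecological interactions between community members induce
temporal correlations between their abundance trajectories, while purely
stochastic (neutral) fluctuations do not. This module measures those
correlations at the strain and species level and calibrates them against
three explicit nulls: (i) independent gamma-distributed abundance
fluctuations (renormalized to the simplex) for interaction detection, (ii) a
strain-label permutation that splits conspecific strains across mock species,
and (iii) trajectory shuffles for eco-evolutionary influence and
co-occurrence variability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "CouplingConfig",
    "GammaNullSpec",
    "NullDistribution",
    "InteractionNetwork",
    "correlation_magnitude",
    "strain_coupling",
    "interspecies_correlations",
    "gamma_null_correlations",
    "detect_interactions",
    "strain_label_permutation_test",
    "cooccurrence_variability",
    "ecoevo_influence",
    "coupling_distance_curve",
]


@dataclass(frozen=True)
class CouplingConfig:
    """Coupling threshold (inflection point of the empirical distribution)."""

    threshold: float = 0.4
    kind: str = "pearson"  # or "spearman"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.kind not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation kind {self.kind!r}")


def _corr(a: np.ndarray, b: np.ndarray, kind: str = "pearson") -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        return np.nan
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    if kind == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    return float(np.corrcoef(a, b)[0, 1])


def correlation_magnitude(a, b, kind: str = "pearson") -> float:
    """|r| between two trajectories; NaN when undefined (constant series)."""
    return abs(_corr(a, b, kind))


def strain_coupling(
    strain_a: np.ndarray,
    strain_b: np.ndarray,
    config: CouplingConfig | None = None,
) -> tuple[float, str]:
    """Coupling of two conspecific strains: |Pearson r| of their abundances.

    Only the magnitude is used — two strains whose abundances move in exact
    opposition (r = -1) are maximally coupled. Returns (coupling, label)
    where label is 'decoupled' below the threshold, 'coupled' at or above it,
    and 'undefined' when either trajectory is constant.
    """
    cfg = config or CouplingConfig()
    c = correlation_magnitude(strain_a, strain_b, cfg.kind)
    if not np.isfinite(c):
        return np.nan, "undefined"
    return c, ("decoupled" if c < cfg.threshold else "coupled")


def interspecies_correlations(
    species_a: np.ndarray,
    species_b: np.ndarray,
    strains_a: Sequence[np.ndarray],
    strains_b: Sequence[np.ndarray],
    kind: str = "pearson",
) -> tuple[float, float, bool]:
    """Species-level |r| vs the strongest interspecific strain pair.

    Strain pairs are enumerated only across species (at most 4 when both
    species carry two strains). Returns (species |r|, max strain |r|,
    strain_exceeds flag). Undefined strain correlations are skipped; if all
    are undefined the strain |r| falls back to the species |r|.
    """
    if len(strains_a) == 0 or len(strains_b) == 0:
        raise ValidationError("both species need at least one strain trajectory")
    species_r = correlation_magnitude(species_a, species_b, kind)
    strain_rs = [
        correlation_magnitude(sa, sb, kind)
        for sa, sb in itertools.product(strains_a, strains_b)
    ]
    finite = [r for r in strain_rs if np.isfinite(r)]
    strain_r = max(finite) if finite else species_r
    exceeds = bool(np.isfinite(species_r) and np.isfinite(strain_r) and strain_r > species_r)
    return species_r, strain_r, exceeds


# ---------------------------------------------------------------------------
# Gamma null for interaction detection


@dataclass(frozen=True)
class GammaNullSpec:
    """Independent gamma abundance fluctuations: P_i(x) with the observed mean
    and variance of each member, shape beta_i = mean_i^2 / var_i."""

    means: tuple[float, ...]
    variances: tuple[float, ...]
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.means) != len(self.variances):
            raise ValueError("means and variances must align")
        if any(m <= 0 for m in self.means) or any(v <= 0 for v in self.variances):
            raise ValueError("means and variances must be > 0")

    @property
    def shapes(self) -> np.ndarray:
        m = np.asarray(self.means)
        v = np.asarray(self.variances)
        return m * m / v

    @property
    def scales(self) -> np.ndarray:
        return np.asarray(self.variances) / np.asarray(self.means)


@dataclass
class NullDistribution:
    """Samples from a stated null with smoothed empirical p-value lookup."""

    samples: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.samples = self.samples[np.isfinite(self.samples)]
        if self.samples.size == 0:
            raise ValidationError("null distribution is empty")

    def p_value(self, observed: float) -> float:
        """P(null >= observed) with (k+1)/(n+1) smoothing (never exactly 0)."""
        k = int((self.samples >= observed).sum())
        return (k + 1) / (self.samples.size + 1)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))


def gamma_null_correlations(
    spec: GammaNullSpec, n_times: int = 8
) -> NullDistribution:
    """Expected |r| distribution between non-interacting community members.

    Each of ``n_sims`` synthetic communities draws every member's abundance
    independently from its gamma distribution at each time point,
    renormalizes per time point to relative abundances, and pools all
    pairwise correlation magnitudes. Because the null pools every pair, the
    resulting p-values already account for multiple comparisons.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.means)
    shapes = spec.shapes
    scales = spec.scales
    pooled: list[np.ndarray] = []
    for _ in range(spec.n_sims):
        draws = rng.gamma(shapes[:, None], scales[:, None], size=(n, n_times))
        rel = draws / draws.sum(axis=0, keepdims=True)
        corr = np.corrcoef(rel)
        iu = np.triu_indices(n, k=1)
        pooled.append(np.abs(corr[iu]))
    return NullDistribution(np.concatenate(pooled), "gamma-sampling null |r|")


@dataclass
class InteractionNetwork:
    """Significant pairwise correlations at one taxonomic level.

    ``density`` is interactions per node (how many partners a member has on
    average), not edges per possible edge.
    """

    level: str
    nodes: list[str]
    edges: pd.DataFrame  # columns a, b, r, p

    def __post_init__(self) -> None:
        if self.level == "strain":
            conspecific = [
                (a, b)
                for a, b in zip(self.edges["a"], self.edges["b"])
                if str(a).split(".")[0] == str(b).split(".")[0]
            ]
            if conspecific:
                raise ValidationError(
                    f"strain-level edges must not connect conspecifics: {conspecific[:3]}"
                )

    @property
    def density(self) -> float:
        return len(self.edges) / len(self.nodes) if self.nodes else 0.0


def detect_interactions(
    observed: Mapping[tuple[str, str], float],
    null: NullDistribution,
    alpha: float = 0.05,
    level: str = "species",
    nodes: Sequence[str] | None = None,
) -> InteractionNetwork:
    """Call interactions where the observed |r| beats the gamma null.

    p = (1 + #null >= |r|) / (1 + n_null); an edge is present when p < alpha.
    No additional multiple-testing correction is applied: the pooled null
    already reflects the number of comparisons.
    """
    rows = []
    seen: set[str] = set()
    for (a, b), r in observed.items():
        seen.update((a, b))
        if not np.isfinite(r):
            continue
        p = null.p_value(r)
        if p < alpha:
            rows.append({"a": a, "b": b, "r": r, "p": p})
    node_list = list(nodes) if nodes is not None else sorted(seen)
    edges = pd.DataFrame(rows, columns=["a", "b", "r", "p"])
    return InteractionNetwork(level, node_list, edges)


# ---------------------------------------------------------------------------
# Strain-label permutation null


def _fraction_strain_dominant(
    strain_pairs: Mapping[str, tuple[np.ndarray, np.ndarray]],
    kind: str = "pearson",
    groups: Mapping[str, str] | None = None,
) -> float:
    """Fraction of species pairs whose best interspecific strain |r| exceeds
    the species |r|; species trajectories are the sums of their strains.
    With ``groups`` (species id -> community), only pairs co-occurring in the
    same community are compared."""
    names = sorted(strain_pairs)
    flags = []
    for a, b in itertools.combinations(names, 2):
        if groups is not None and groups[a] != groups[b]:
            continue
        sa = strain_pairs[a]
        sb = strain_pairs[b]
        _, _, exceeds = interspecies_correlations(
            np.sum(sa, axis=0), np.sum(sb, axis=0), sa, sb, kind
        )
        flags.append(exceeds)
    if not flags:
        raise ValidationError("need at least two comparable species")
    return float(np.mean(flags))


def strain_label_permutation_test(
    strain_pairs: Mapping[str, tuple[np.ndarray, np.ndarray]],
    n_perm: int = 1000,
    seed: int = 0,
    kind: str = "pearson",
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Null controlling for phylogenetic association between strains/species.

    ``strain_pairs`` maps species id to its two strain abundance
    trajectories. The observed statistic F is the fraction of species pairs
    where the best interspecific strain |r| exceeds the species |r|. Each
    permutation shuffles strain labels across species (re-pairing strains
    into mock species of two, each trajectory used exactly once) and
    recomputes F. With ``groups`` (species id -> community), shuffling and
    pair enumeration both stay within each community, matching the study's
    per-community relabelling. Returns F_obs, the null mean/sd, and the
    smoothed p-value.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    species = sorted(strain_pairs)
    if len(species) < 2:
        raise ValidationError("need at least 2 two-strain species to permute")
    f_obs = _fraction_strain_dominant(strain_pairs, kind, groups)
    by_group: dict[str, list[str]] = {}
    for sp in species:
        by_group.setdefault(groups[sp] if groups else "all", []).append(sp)
    rng = np.random.default_rng(seed)
    null_f = np.empty(n_perm)
    for i in range(n_perm):
        mock: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        mock_groups: dict[str, str] = {}
        for g, members in by_group.items():
            pool = [t for sp in members for t in strain_pairs[sp]]
            order = rng.permutation(len(pool))
            for j in range(len(pool) // 2):
                key = f"{g}:mock_{j}"
                mock[key] = (pool[order[2 * j]], pool[order[2 * j + 1]])
                mock_groups[key] = g
        null_f[i] = _fraction_strain_dominant(
            mock, kind, mock_groups if groups else None
        )
    p = (1 + int((null_f >= f_obs).sum())) / (n_perm + 1)
    return {
        "F_obs": f_obs,
        "null_mean": float(null_f.mean()),
        "null_sd": float(null_f.std(ddof=1)) if n_perm > 1 else 0.0,
        "p_value": p,
        "null_samples": null_f,
    }


# ---------------------------------------------------------------------------
# Compositional variability across communities


def cooccurrence_variability(
    membership: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Normalized probability that two members of a taxonomic group co-occur.

    ``membership`` is communities x members (boolean presence); ``groups``
    maps a parent taxon to its member ids (members differ at the focal level
    but share the parent one level above). Observed statistic: over all
    within-group member pairs, the fraction co-occurring in at least one
    community. The null shuffles member labels across groups, preserving the
    number of groups and their sizes; the result is observed / null mean.
    """
    sizes = [len(m) for m in groups.values() if len(m) >= 2]
    if not sizes:
        raise ValidationError("no groups of size >= 2 at this level")
    present = membership.astype(bool)

    def statistic(groups_: Mapping[str, Sequence[str]]) -> float:
        pairs = []
        for members in groups_.values():
            for a, b in itertools.combinations(members, 2):
                pairs.append(bool((present[a] & present[b]).any()))
        return float(np.mean(pairs)) if pairs else np.nan

    observed = statistic(groups)
    all_members = [m for members in groups.values() for m in members]
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = list(rng.permutation(all_members))
        mock: dict[str, list[str]] = {}
        pos = 0
        for g, members in groups.items():
            mock[g] = shuffled[pos : pos + len(members)]
            pos += len(members)
        null[i] = statistic(mock)
    null_mean = float(np.nanmean(null))
    return {
        "observed": observed,
        "null_mean": null_mean,
        "normalized": observed / null_mean if null_mean else np.nan,
    }


# ---------------------------------------------------------------------------
# Eco-evolutionary influence


def ecoevo_influence(
    species_trajs: Mapping[str, np.ndarray],
    major_strain_freqs: Mapping[str, np.ndarray],
    n_shuffles: int = 1000,
    seed: int = 0,
    use_magnitude: bool = False,
) -> pd.DataFrame:
    """Correlation between each species' abundance and its major-strain frequency.

    The null shuffles the pairing between species trajectories and
    major-strain frequency trajectories across the whole population; a
    species is flagged *influential* when its statistic exceeds the null's
    95th percentile. Signed r by default (``use_magnitude`` switches to |r|).
    Constant strain frequencies give an undefined statistic and are never
    flagged.
    """
    names = sorted(set(species_trajs) & set(major_strain_freqs))
    if len(names) < 2:
        raise ValidationError("need at least two species for the shuffle null")
    stat = lambda a, b: (
        correlation_magnitude(a, b) if use_magnitude else _corr(a, b)
    )
    rng = np.random.default_rng(seed)
    ab = [np.asarray(species_trajs[n], dtype=float) for n in names]
    fr = [np.asarray(major_strain_freqs[n], dtype=float) for n in names]
    null = []
    for _ in range(n_shuffles):
        i = rng.integers(len(names))
        j = rng.integers(len(names))
        while j == i:
            j = rng.integers(len(names))
        v = stat(ab[i], fr[j])
        if np.isfinite(v):
            null.append(v)
    cut = float(np.percentile(null, 95))
    rows = []
    for n, a, f in zip(names, ab, fr):
        r = stat(a, f)
        rows.append(
            {
                "species": n,
                "r": r,
                "influential": bool(np.isfinite(r) and r > cut),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["null_95th"] = cut
    out.attrs["fraction_influential"] = float(out["influential"].mean())
    return out


# ---------------------------------------------------------------------------
# Coupling vs genetic distance


def coupling_distance_curve(
    distances: Sequence[float],
    couplings: Sequence[float],
    n_bins: int = 8,
) -> pd.DataFrame:
    """Binned moving average of coupling over log-spaced genetic distances.

    Replaces the figure's LOESS smoothing with per-bin means; empty bins are
    omitted. Returns columns bin_low, bin_high, distance (geometric mid),
    mean_coupling, n.
    """
    d = np.asarray(distances, dtype=float)
    c = np.asarray(couplings, dtype=float)
    mask = np.isfinite(d) & np.isfinite(c) & (d > 0)
    d, c = d[mask], c[mask]
    if d.size == 0:
        raise ValidationError("no valid (distance, coupling) pairs")
    lo, hi = d.min(), d.max()
    if lo == hi:
        return pd.DataFrame(
            [{"bin_low": lo, "bin_high": hi, "distance": lo, "mean_coupling": c.mean(), "n": d.size}]
        )
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[-1] *= 1 + 1e-12
    rows = []
    idx = np.digitize(d, edges) - 1
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "distance": float(np.sqrt(edges[b] * edges[b + 1])),
                "mean_coupling": float(c[sel].mean()),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
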