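"""Minimal consumer-resource models of strain vs species interactions.

Two batch-culture models discriminate the hypotheses about where ecological
interactions live. Growth follows dN_a/dt = N_a * sum_i C_ai R_i and
dR_i/dt = -R_i * sum_a C_ai N_a (unit yield, so biomass + resources are
conserved within a cycle); communities are serially diluted 1:100 into fresh
medium. Under *strain_specific* interactions each conspecific strain pair's
consumption vectors sit a competitive distance D apart on the unit simplex
(D drawn from the study's discrete mixture); under *species_identical*
interactions conspecific strains share one consumption vector (D = 0) and
their within-species frequency moves only by neutral random-walk drift.
Fluctuations around equilibrium come from small transfer-to-transfer noise in
the supplied resource proportions. The discriminating statistic is the
fraction of surviving species pairs whose best interspecific strain
correlation exceeds the species-level correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import interspecies_correlations, strain_coupling
from .io import ValidationError

__all__ = [
    "DriftSpec",
    "CrmScenario",
    "CommunityResult",
    "sample_simplex",
    "conspecific_at_distance",
    "integrate_cycle",
    "apply_drift",
    "serial_passage",
    "fraction_strain_exceeds_species",
    "conspecific_couplings",
    "evaluate_hypotheses",
]


@dataclass(frozen=True)
class DriftSpec:
    """Neutral random walk of within-species strain frequency.

    Per generation the frequency receives a Gaussian increment of mean zero
    and variance v/N (``v_over_N``, population-genetic drift scaling, the
    default) or v*N (``v_times_N``, the literal stated form), where N is the
    species' relative abundance; frequencies are clipped to [0, 1] with
    absorbing boundaries. The default v makes the neutral fixation timescale
    (~0.25 N/v generations from an even strain split) comparable to the
    experiment's ~900 generations at a typical surviving-species abundance of
    ~1/30, so part of the strain pool fixes over the run — the regime the
    neutral model is meant to represent.
    """

    v: float = 8e-6
    mode: str = "v_over_N"

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("drift coefficient v must be >= 0")
        if self.mode not in ("v_over_N", "v_times_N"):
            raise ValueError(f"unknown drift mode {self.mode!r}")

    def step_variance(self, species_abundance: float) -> float:
        if self.v == 0:
            return 0.0
        if self.mode == "v_times_N":
            return self.v * species_abundance
        return self.v / max(species_abundance, 1e-12)


@dataclass(frozen=True)
class CrmScenario:
    """Study-scale scenario: 10 communities of 50 species x 2 strains on 30
    resources, dilution 1:100, supply-noise variance 0.05, stated D mixture."""

    n_species: int = 50
    n_resources: int = 30
    dilution: float = 100.0
    supply_noise_var: float = 0.05
    supply_noise_mode: str = "relative"  # or "absolute"
    hypothesis: str = "strain_specific"  # or "species_identical"
    d_values: tuple[float, ...] = (0.01, 0.1, 0.3, 1.0)
    d_probs: tuple[float, ...] = (0.15, 0.20, 0.50, 0.15)
    drift: DriftSpec = field(default_factory=DriftSpec)
    n_communities: int = 10
    seed: int = 0
    n_record: int = 8
    record_every: int = 6
    eq_tol: float = 1e-3
    eq_consecutive: int = 5
    max_assembly_cycles: int = 250
    extinction_threshold: float = 1e-12
    depletion_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.hypothesis not in ("strain_specific", "species_identical"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if abs(sum(self.d_probs) - 1.0) > 1e-9:
            raise ValueError("D mixture probabilities must sum to 1")
        if any(d < 0 for d in self.d_values):
            raise ValueError("competitive distances must be >= 0")
        if self.dilution <= 1:
            raise ValueError("dilution factor must exceed 1")

    @property
    def generations_per_cycle(self) -> float:
        return math.log2(self.dilution)


# ---------------------------------------------------------------------------
# Consumption vectors on the simplex


def sample_simplex(dim: int, rng: np.random.Generator | int = 0) -> np.ndarray:
    """A point uniform on the unit simplex (flat Dirichlet)."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return rng.dirichlet(np.ones(dim))


def conspecific_at_distance(
    c: np.ndarray,
    D: float,
    rng: np.random.Generator | int = 0,
    max_retries: int = 1000,
) -> np.ndarray:
    """A second consumption vector at Euclidean distance D from ``c``.

    The displacement direction is drawn isotropically within the simplex's
    tangent space (zero-sum directions) and resampled whenever the result
    leaves the simplex; an infeasible D raises after ``max_retries``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-9:
        raise ValueError("c must lie on the unit simplex")
    if D == 0:
        return c.copy()
    # Walk distance D along the segment from c toward a random simplex point z;
    # convexity keeps the result on the simplex whenever ||z - c|| >= D. Large
    # D needs sparse (near-vertex) targets, so the Dirichlet concentration is
    # lowered progressively until a feasible direction appears.
    tries_per_alpha = max(1, max_retries // 4)
    for alpha in (1.0, 0.5, 0.2, 0.1):
        for _ in range(tries_per_alpha):
            z = rng.dirichlet(np.full(c.size, alpha))
            if not np.all(np.isfinite(z)):
                continue  # tiny-alpha draws can underflow
            delta = z - c
            norm = np.linalg.norm(delta)
            if norm < D or norm == 0:
                continue
            candidate = c + D * delta / norm
            if np.all(candidate >= 0):
                return candidate / candidate.sum()  # guard rounding; sum is 1
    # the extreme points: if any target is far enough for D, a vertex is
    for k in rng.permutation(c.size):
        z = np.zeros(c.size)
        z[k] = 1.0
        delta = z - c
        norm = np.linalg.norm(delta)
        if norm < D:
            continue
        candidate = c + D * delta / norm
        if np.all(candidate >= 0):
            return candidate / candidate.sum()
    raise ValueError(
        f"could not place a conspecific at distance {D} from c after "
        f"{max_retries} tries; try a smaller D"
    )


# ---------------------------------------------------------------------------
# Within-cycle dynamics


def integrate_cycle(
    N0: np.ndarray,
    R0: np.ndarray,
    C: np.ndarray,
    eps: float = 1e-6,
    t_max: float = 1e5,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one batch cycle until the resources are depleted.

    Solves dN_a/dt = N_a (C R)_a, dR_i/dt = -R_i (C^T N)_i until
    sum_i R_i < eps (terminal event) or ``t_max``. Total biomass plus
    resources is conserved to within the integrator tolerance (checked, 1e-6
    relative).
    """
    N0 = np.asarray(N0, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    nN = N0.size
    CT = np.ascontiguousarray(C.T)

    def rhs(_t, y):
        N = y[:nN]
        R = y[nN:]
        growth = C @ R
        return np.concatenate((N * growth, -R * (CT @ N)))

    def depleted(_t, y):
        return y[nN:].sum() - eps

    depleted.terminal = True
    depleted.direction = -1

    total0 = N0.sum() + R0.sum()
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        np.concatenate((N0, R0)),
        method="LSODA",
        events=depleted,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}; state {sol.y[:, -1]}")
    y_end = sol.y[:, -1]
    N_end = np.maximum(y_end[:nN], 0.0)
    R_end = np.maximum(y_end[nN:], 0.0)
    total_end = N_end.sum() + R_end.sum()
    if abs(total_end - total0) > 1e-6 * total0:
        raise RuntimeError(
            f"mass conservation violated: {total0} -> {total_end} "
            f"(relative error {abs(total_end - total0) / total0:.2e})"
        )
    return N_end, R_end


def apply_drift(
    frequencies: np.ndarray,
    species_abundances: np.ndarray,
    spec: DriftSpec,
    n_generations: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Neutral random walk of strain frequencies over ``n_generations``.

    Integer generations step one Gaussian increment each (clipping to [0, 1]
    after every step); a fractional remainder contributes one further
    increment with proportionally scaled variance. The boundaries are
    absorbing: a frequency that reaches exactly 0 or 1 stays there — a
    lineage with no individuals left cannot reappear.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    f = np.clip(np.asarray(frequencies, dtype=float).copy(), 0.0, 1.0)
    N = np.asarray(species_abundances, dtype=float)
    if spec.v == 0 or n_generations == 0:
        return f
    var = np.array([spec.step_variance(x) for x in N])
    sd = np.sqrt(var)
    whole, frac = int(n_generations), n_generations - int(n_generations)

    def step(scale: float) -> None:
        nonlocal f
        live = (f > 0.0) & (f < 1.0)
        if not live.any():
            return
        f[live] = np.clip(
            f[live] + rng.normal(0.0, 1.0, size=int(live.sum())) * sd[live] * scale,
            0.0,
            1.0,
        )

    for _ in range(whole):
        step(1.0)
    if frac > 0:
        step(math.sqrt(frac))
    return f


# ---------------------------------------------------------------------------
# Serial passage


@dataclass
class CommunityResult:
    """Recorded post-equilibrium trajectories of one simulated community.

    ``strain_abundance`` is strains x samples (relative abundance within the
    whole community); ``species_of`` maps strain index to species index;
    ``d_of_species`` holds each species' conspecific competitive distance.
    """

    strain_abundance: np.ndarray
    species_of: np.ndarray
    d_of_species: np.ndarray
    equilibrium_reached: bool
    n_assembly_cycles: int

    @property
    def n_species(self) -> int:
        return int(self.species_of.max()) + 1

    @property
    def species_abundance(self) -> np.ndarray:
        out = np.zeros((self.n_species, self.strain_abundance.shape[1]))
        for a, s in enumerate(self.species_of):
            out[s] += self.strain_abundance[a]
        return out

    def surviving_strains(self, species: int) -> list[int]:
        idx = np.flatnonzero(self.species_of == species)
        return [int(a) for a in idx if np.all(self.strain_abundance[a] > 0)]


def _supply(scenario: CrmScenario, rng: np.random.Generator | None) -> np.ndarray:
    """Resource supply for one transfer: equal proportions on average, total 1.

    Transfer-to-transfer variability is Gaussian relative noise of variance
    ``supply_noise_var`` on each resource's proportion, clipped at zero and
    renormalized (``rng=None`` gives the noise-free balanced medium).
    """
    m = scenario.n_resources
    base = np.full(m, 1.0 / m)
    if rng is None or scenario.supply_noise_var == 0:
        return base
    eta = rng.normal(0.0, math.sqrt(scenario.supply_noise_var), size=m)
    if scenario.supply_noise_mode == "relative":
        noisy = base * (1.0 + eta)
    else:  # absolute noise on the proportions themselves
        noisy = base + eta
    noisy = np.maximum(noisy, 0.0)
    total = noisy.sum()
    if total == 0:
        return base
    return noisy / total


def serial_passage(scenario: CrmScenario) -> list[CommunityResult]:
    """Simulate the scenario's communities through assembly and sampling.

    Each community assembles under the balanced (noise-free) medium until its
    end-of-cycle composition changes by less than ``eq_tol`` (L1) for
    ``eq_consecutive`` consecutive cycles, then runs ``n_record *
    record_every`` further cycles with supply noise, recording every
    ``record_every``-th end-of-cycle composition (the metagenomic sampling
    cadence). Under ``species_identical`` the two conspecific strains share
    one consumption vector, so species dynamics are integrated directly and
    strain frequencies evolve only by drift (log2(dilution) generations per
    cycle).
    """
    rng = np.random.default_rng(scenario.seed)
    results = []
    for _ in range(scenario.n_communities):
        results.append(_one_community(scenario, np.random.default_rng(rng.integers(2**31))))
    return results


def _one_community(scenario: CrmScenario, rng: np.random.Generator) -> CommunityResult:
    S = scenario.n_species
    strain_specific = scenario.hypothesis == "strain_specific"

    d_of_species = rng.choice(scenario.d_values, size=S, p=scenario.d_probs)
    if not strain_specific:
        d_of_species = np.zeros(S)

    C_species = np.vstack([sample_simplex(scenario.n_resources, rng) for _ in range(S)])
    if strain_specific:
        C = np.empty((2 * S, scenario.n_resources))
        for s in range(S):
            C[2 * s] = C_species[s]
            C[2 * s + 1] = conspecific_at_distance(C_species[s], d_of_species[s], rng)
        n_units = 2 * S  # integrate individual strains
    else:
        C = C_species
        n_units = S      # conspecifics are identical: integrate species

    species_of_unit = np.repeat(np.arange(S), 2) if strain_specific else np.arange(S)
    N = np.full(n_units, 1.0 / (scenario.dilution * n_units))
    freqs = np.full(S, 0.5)  # within-species strain-1 frequency (hypothesis 2)

    def one_cycle(noisy_rng):
        nonlocal N, freqs
        supply = _supply(scenario, noisy_rng)
        alive = N > 0
        N_end = np.zeros_like(N)
        N_alive, _ = integrate_cycle(
            N[alive], supply, C[alive], eps=scenario.depletion_eps
        )
        N_end[alive] = N_alive
        N_end[N_end < scenario.extinction_threshold] = 0.0
        N = N_end / scenario.dilution
        if not strain_specific and scenario.drift.v > 0:
            # demographic drift acts every cycle, assembly included
            rel = N / N.sum()
            freqs = apply_drift(
                freqs, rel, scenario.drift, scenario.generations_per_cycle, rng
            )

    def composition():
        if strain_specific:
            strains = N
        else:
            strains = np.empty(2 * S)
            strains[0::2] = N * freqs
            strains[1::2] = N * (1.0 - freqs)
        total = strains.sum()
        return strains / total if total > 0 else strains

    def eq_composition():
        # under hypothesis 2 the strain split moves by drift every cycle, so
        # equilibrium is judged on the (deterministic) species composition
        if strain_specific:
            return composition()
        total = N.sum()
        return N / total if total > 0 else N

    # --- assembly in the balanced medium
    prev = eq_composition()
    streak = 0
    cycles = 0
    reached = False
    while cycles < scenario.max_assembly_cycles:
        one_cycle(None)
        cycles += 1
        comp = eq_composition()
        streak = streak + 1 if np.abs(comp - prev).sum() < scenario.eq_tol else 0
        prev = comp
        if streak >= scenario.eq_consecutive:
            reached = True
            break
    if not reached:
        warnings.warn(
            f"community did not equilibrate within {scenario.max_assembly_cycles} "
            "cycles; proceeding with the final state"
        )

    # --- recorded phase with supply noise (and drift under hypothesis 2)
    recorded = []
    for cycle in range(scenario.n_record * scenario.record_every):
        one_cycle(rng)
        if (cycle + 1) % scenario.record_every == 0:
            recorded.append(composition())
    strain_abundance = np.column_stack(recorded)

    return CommunityResult(
        strain_abundance=strain_abundance,
        species_of=np.repeat(np.arange(S), 2),
        d_of_species=np.asarray(d_of_species, dtype=float),
        equilibrium_reached=reached,
        n_assembly_cycles=cycles,
    )


# ---------------------------------------------------------------------------
# Summary statistics


def fraction_strain_exceeds_species(
    results: Sequence[CommunityResult],
) -> tuple[float, int]:
    """Fraction of surviving species pairs where the best interspecific
    strain |r| beats the species |r| (pooled over communities).

    A strain survives when its recorded abundance is positive at every
    sample; a species survives when at least one of its strains does.
    Species pairs where both members kept a single strain contribute a
    non-exceeding comparison (strain |r| equals species |r| there).
    """
    flags = []
    for res in results:
        species_ab = res.species_abundance
        alive_species = [
            s for s in range(res.n_species) if res.surviving_strains(s)
        ]
        for i, a in enumerate(alive_species):
            for b in alive_species[i + 1 :]:
                strains_a = [res.strain_abundance[k] for k in res.surviving_strains(a)]
                strains_b = [res.strain_abundance[k] for k in res.surviving_strains(b)]
                _, _, exceeds = interspecies_correlations(
                    species_ab[a], species_ab[b], strains_a, strains_b
                )
                flags.append(exceeds)
    if not flags:
        raise ValidationError("fewer than two surviving species in every community")
    return float(np.mean(flags)), len(flags)


def evaluate_hypotheses(
    base_seed: int = 1,
    n_seeds: int = 5,
    hypotheses: Sequence[str] = ("strain_specific", "species_identical"),
    **scenario_overrides,
) -> dict:
    """Run both models over ``n_seeds`` replicate seeds and summarise.

    Returns, per hypothesis, the per-seed discrimination fractions (strain |r|
    exceeding species |r| over surviving species pairs), their mean, and the
    total number of pairs compared.
    """
    out: dict = {}
    for hyp in hypotheses:
        fractions = []
        n_pairs = 0
        for i in range(n_seeds):
            scenario = CrmScenario(
                hypothesis=hyp, seed=int(base_seed) + i, **scenario_overrides
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = serial_passage(scenario)
            f, n = fraction_strain_exceeds_species(results)
            fractions.append(f)
            n_pairs += n
        out[hyp] = {
            "fractions": fractions,
            "mean": float(np.mean(fractions)),
            "n_pairs": n_pairs,
        }
    return out


def conspecific_couplings(
    results: Sequence[CommunityResult],
) -> tuple[np.ndarray, np.ndarray]:
    """(D, coupling) for every conspecific pair with both strains surviving."""
    ds, cs = [], []
    for res in results:
        for s in range(res.n_species):
            alive = res.surviving_strains(s)
            if len(alive) != 2:
                continue
            c, label = strain_coupling(
                res.strain_abundance[alive[0]], res.strain_abundance[alive[1]]
            )
            if label != "undefined":
                ds.append(res.d_of_species[s])
                cs.append(c)
    return np.asarray(ds), np.asarray(cs)
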