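"""Force-dependent stochastic unfolding of proximal IG domains.

Unfolding is a two-state reaction with a Bell-model rate
``k(f) = k0 * exp(f * width_i / kB T)``; refolding is identically zero
(the sarcomere is never allowed back to a relaxed state).  The weak
hierarchy of unfolding forces is encoded by barrier widths that shrink
with domain index, so later domains need higher force to unfold at the
same rate.  High calcium multiplies all widths by a factor < 1, raising
unfolding forces.

The module also provides the Monte-Carlo ensemble of titin strands used by
the protocol engine: 500 independent strands per um^2 of cross-section,
each with its own unfolding count and actin-binding state, evaluated
quasi-statically against precomputed force-extension tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kbt
from .polymer import ewlc_extension, wlc_extension
from .titin import TitinIsoform, TitinStrandState, apply_calcium

__all__ = [
    "UnfoldingParams",
    "EnsembleConfig",
    "unfolding_rate",
    "mc_step",
    "TitinEnsemble",
    "EnsembleTrace",
    "ensemble_trace",
]

def default_barrier_widths(n_domains: int = 50) -> tuple:
    """Linearly spaced barrier widths, 0.25 nm (first) to 0.15 nm (last)."""
    return tuple(np.linspace(0.25, 0.15, n_domains))


@dataclass(frozen=True)
class UnfoldingParams:
    """Bell-model unfolding kinetics with a hierarchical barrier structure.

    ``base_rate`` is deliberately small: with the default chain elasticity
    it puts significant unfolding above ~150 pN per strand, below which
    protocol-scale stretches leave the domains folded.
    """

    base_rate: float = 1e-5
    barrier_widths: tuple = field(default_factory=default_barrier_widths)
    calcium_width_multiplier: float = 0.87

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        w = np.asarray(self.barrier_widths, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("barrier_widths must be a non-empty 1-d sequence")
        if np.any(w <= 0):
            raise ValueError("barrier_widths must be > 0")
        if np.any(np.diff(w) > 1e-12):
            raise ValueError(
                "barrier_widths must be non-increasing with domain index "
                "(weak hierarchy: later domains need higher force)"
            )
        if not 0 < self.calcium_width_multiplier <= 1:
            raise ValueError("calcium_width_multiplier must be in (0, 1]")

    def widths(self, calcium: bool = False) -> np.ndarray:
        w = np.asarray(self.barrier_widths, dtype=float)
        return w * self.calcium_width_multiplier if calcium else w


@dataclass(frozen=True)
class EnsembleConfig:
    """Monte-Carlo ensemble size, seeding and clock."""

    n_strands: int = 500
    rng_seed: int = 0
    time_step: float = 1e-3
    strands_per_um2: float = 500.0

    def __post_init__(self) -> None:
        if self.n_strands < 1:
            raise ValueError("n_strands must be >= 1")
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.strands_per_um2 <= 0:
            raise ValueError("strands_per_um2 must be > 0")


def unfolding_rate(
    force: float,
    domain_index: int,
    params: UnfoldingParams,
    *,
    calcium: bool = False,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Bell-model unfolding rate (1/s) of one domain at ``force`` (pN)."""
    if force < 0:
        raise ValueError("force must be >= 0")
    widths = params.widths(calcium)
    if not 0 <= domain_index < widths.size:
        raise IndexError(
            f"domain_index {domain_index} out of range [0, {widths.size})"
        )
    return params.base_rate * float(
        np.exp(force * widths[domain_index] / kbt(temperature))
    )


def _unfold_counts(
    n_unfolded: np.ndarray,
    forces: np.ndarray,
    dt: float,
    params: UnfoldingParams,
    rng: np.random.Generator,
    *,
    calcium: bool,
    temperature: float,
) -> np.ndarray:
    """Number of newly unfolded domains per strand over ``dt`` (vectorised).

    Each still-folded domain unfolds independently with probability
    1 - exp(-k_i dt).  At fixed force each domain is a one-way two-state
    process, so this single Bernoulli draw per domain is exact for any dt
    (no substepping error); within a step the newly unfolded domains are
    counted in hierarchy order (the folded set of a strand is always the
    index suffix [n_unfolded, N)).
    """
    widths = params.widths(calcium)
    n_dom = widths.size
    beta = 1.0 / kbt(temperature)
    fmax = float(np.max(forces)) if forces.size else 0.0
    with np.errstate(over="ignore"):
        kmax = params.base_rate * np.exp(fmax * widths[0] * beta)
    if kmax * dt < 1e-12:
        return np.zeros_like(n_unfolded)
    with np.errstate(over="ignore"):
        rates = params.base_rate * np.exp(np.outer(forces, widths) * beta)
        p = -np.expm1(-rates * dt)
    folded = np.arange(n_dom)[None, :] >= n_unfolded[:, None]
    events = (rng.random(p.shape) < p) & folded
    return events.sum(axis=1)


def mc_step(
    state: TitinStrandState,
    force: float,
    dt: float,
    rng: np.random.Generator,
    params: Optional[UnfoldingParams] = None,
    *,
    temperature: float = DEFAULT_TEMPERATURE,
) -> TitinStrandState:
    """Advance one strand's unfolding state by ``dt`` seconds.

    ``n_unfolded`` never decreases (no refolding).  Bound strands are
    shielded: the actin bridge shunts the stretch force past the frozen
    proximal compartment, so no further proximal unfolding occurs.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if params is None:
        params = UnfoldingParams()
    if state.actin_bound:
        return state
    inc = _unfold_counts(
        np.array([state.n_unfolded]),
        np.array([force]),
        dt,
        params,
        rng,
        calcium=state.calcium_bound,
        temperature=temperature,
    )[0]
    if inc == 0:
        return state
    return replace(state, n_unfolded=state.n_unfolded + int(inc))


# -- force-extension tables --------------------------------------------------


class _ForceTable:
    """Tabulated force-extension inverses for one isoform.

    Rows are built lazily per unfolding count.  ``solve`` inverts
    extension(force) by linear interpolation on a dense log-spaced force
    grid; exact solves (titin.chain_force) are used wherever tolerances
    matter, the tables only drive the Monte-Carlo ensemble.
    """

    N_GRID = 2600
    F_MAX = 1e5

    def __init__(self, isoform: TitinIsoform):
        self.isoform = isoform
        self.f_grid = np.concatenate(
            [[0.0], np.geomspace(1e-8, self.F_MAX, self.N_GRID)]
        )
        self._rows: dict = {}
        iso = isoform
        self._x_pevk_aband = (
            ewlc_extension(self.f_grid, iso.pevk) + self.f_grid / iso.a_band_stiffness
        )
        self._x_folded_one = wlc_extension(self.f_grid, iso.folded_ig)
        self._x_unfolded_one = wlc_extension(self.f_grid, iso.unfolded_ig)

    def _row(self, n_unfolded: int) -> np.ndarray:
        row = self._rows.get(n_unfolded)
        if row is None:
            n_folded = self.isoform.n_proximal_ig - n_unfolded
            row = (
                self._x_pevk_aband
                + n_folded * self._x_folded_one
                + n_unfolded * self._x_unfolded_one
            )
            self._rows[n_unfolded] = row
        return row

    def solve_unbound(self, compliant_target, n_unfolded) -> np.ndarray:
        """Force for unbound strands: target = HSL - rigid offset."""
        target = np.atleast_1d(np.asarray(compliant_target, dtype=float))
        n_u = np.atleast_1d(np.asarray(n_unfolded))
        out = np.zeros_like(target)
        for k in np.unique(n_u):
            m = n_u == k
            out[m] = np.interp(target[m], self._row(int(k)), self.f_grid)
        return out

    def solve_bound(self, free_target) -> np.ndarray:
        """Force for bound strands: target = HSL - rigid - frozen proximal."""
        target = np.asarray(free_target, dtype=float)
        return np.interp(target, self._x_pevk_aband, self.f_grid)


_TABLE_CACHE: dict = {}


def _table_for(isoform: TitinIsoform) -> _ForceTable:
    tab = _TABLE_CACHE.get(isoform)
    if tab is None:
        tab = _ForceTable(isoform)
        _TABLE_CACHE[isoform] = tab
    return tab


# -- ensemble ----------------------------------------------------------------


class TitinEnsemble:
    """Vectorised ensemble of independent titin strands.

    Holds per-strand unfolding counts, actin-binding flags and frozen
    proximal lengths; switches between the low- and high-calcium isoforms
    as a whole (calcium is a bath property, not a per-strand one).
    """

    def __init__(
        self,
        isoform: TitinIsoform,
        params: UnfoldingParams,
        config: EnsembleConfig,
        rng: Optional[np.random.Generator] = None,
    ):
        if isoform.calcium:
            raise ValueError("ensemble must be constructed from the low-calcium isoform")
        if len(params.barrier_widths) != isoform.n_proximal_ig:
            raise ValueError(
                "barrier_widths must have one entry per proximal IG domain "
                f"({isoform.n_proximal_ig}), got {len(params.barrier_widths)}"
            )
        self.isoform_low = isoform
        self._isoform_high: Optional[TitinIsoform] = None
        self.params = params
        self.config = config
        self.calcium = False
        self.temperature = isoform.pevk.temperature
        n = config.n_strands
        self.n_unfolded = np.zeros(n, dtype=np.int64)
        self.bound = np.zeros(n, dtype=bool)
        self.frozen = np.zeros(n, dtype=float)
        self.rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    # -- calcium ----------------------------------------------------------

    @property
    def isoform(self) -> TitinIsoform:
        if not self.calcium:
            return self.isoform_low
        if self._isoform_high is None:
            self._isoform_high = apply_calcium(self.isoform_low)
        return self._isoform_high

    def set_calcium(self, on: bool) -> None:
        self.calcium = bool(on)

    # -- mechanics --------------------------------------------------------

    def forces(self, hsl: float) -> np.ndarray:
        """Per-strand common force (pN) at half-sarcomere length ``hsl`` (nm)."""
        iso = self.isoform
        tab = _table_for(iso)
        out = np.zeros(self.config.n_strands)
        unbound = ~self.bound
        if np.any(unbound):
            target = hsl - iso.rigid_offset
            out[unbound] = tab.solve_unbound(
                np.full(unbound.sum(), target), self.n_unfolded[unbound]
            )
        if np.any(self.bound):
            target = hsl - iso.rigid_offset - self.frozen[self.bound]
            out[self.bound] = tab.solve_bound(target)
        return out

    def proximal_lengths(self, hsl: float) -> np.ndarray:
        """Summed end-to-end length of the proximal IG compartment per strand."""
        iso = self.isoform
        f = self.forces(hsl)
        n_fold = iso.n_proximal_ig - self.n_unfolded
        x = n_fold * wlc_extension(f, iso.folded_ig) + self.n_unfolded * wlc_extension(
            f, iso.unfolded_ig
        )
        x = np.asarray(x, dtype=float)
        x[self.bound] = self.frozen[self.bound]
        return x

    def bind(self, hsl: float) -> int:
        """Bind all unbound strands at their current proximal lengths."""
        unbound = ~self.bound
        n_new = int(unbound.sum())
        if n_new:
            prox = self.proximal_lengths(hsl)
            self.frozen[unbound] = prox[unbound]
            self.bound[unbound] = True
        return n_new

    def unbind(self) -> int:
        n = int(self.bound.sum())
        self.bound[:] = False
        self.frozen[:] = 0.0
        return n

    def step_unfolding(self, forces: np.ndarray, dt: float) -> None:
        """Advance unfolding by ``dt``; bound strands are shielded."""
        unbound = ~self.bound
        if not np.any(unbound):
            return
        inc = _unfold_counts(
            self.n_unfolded[unbound],
            forces[unbound],
            dt,
            self.params,
            self.rng,
            calcium=self.calcium,
            temperature=self.temperature,
        )
        if np.any(inc):
            self.n_unfolded[unbound] = self.n_unfolded[unbound] + inc

    def stress(self, forces: np.ndarray) -> float:
        """Ensemble stress in nN/um^2 for per-strand forces in pN."""
        return float(np.mean(forces)) * self.config.strands_per_um2 * 1e-3


@dataclass(frozen=True)
class EnsembleTrace:
    """Passive ensemble force trace: mean +- sd stress per time point."""

    time_s: np.ndarray
    hsl_nm: np.ndarray
    stress_mean: np.ndarray
    stress_sd: np.ndarray
    mean_unfolded: np.ndarray


def ensemble_trace(
    protocol,
    isoform: TitinIsoform,
    params: UnfoldingParams,
    config: EnsembleConfig,
) -> EnsembleTrace:
    """Average passive chain force over an ensemble of strand histories.

    The protocol's length schedule is followed passively (activation
    phases, if any, are ignored); stress is the per-strand force averaged
    over the ensemble and normalised by the configured strand density.
    Reproducible given ``config.rng_seed``.
    """
    from .protocols import compile_length_schedule  # deferred: avoids cycle

    times, hsl = compile_length_schedule(protocol, config.time_step)
    ens = TitinEnsemble(isoform, params, config)
    spu = config.strands_per_um2 * 1e-3
    n_t = times.size
    mean = np.empty(n_t)
    sd = np.empty(n_t)
    nu = np.empty(n_t)
    dt = config.time_step
    for i in range(n_t):
        f = ens.forces(hsl[i])
        mean[i] = np.mean(f) * spu
        sd[i] = np.std(f) * spu
        nu[i] = np.mean(ens.n_unfolded)
        if i < n_t - 1:
            ens.step_unfolding(f, dt)
    return EnsembleTrace(times, hsl, mean, sd, nu)
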