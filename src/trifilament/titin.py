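"""Serial-compartment model of a single titin strand in a half sarcomere.

A strand is a chain of compartments in series: folded proximal IG domains
(aggregated into one WLC), unfolded proximal IG domains (likewise), the
extensible PEVK segment, the non-compliant distal end-filament, and the
half A-band modelled as a very stiff linear spring.  Because the
compartments are in series they all carry the same force, and the
half-sarcomere length (HSL) is the sum of their end-to-end lengths:

    HSL = Nu*lu + (N - Nu)*lf + l_PEVK + l_dist + d

Activation-triggered actin binding freezes the proximal IG compartment at
its current length (titin binds to the nearest actin site at the most
proximal PEVK residue), leaving PEVK + distal as the free spring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE
from .polymer import (
    ExtensibleWLCParams,
    WLCParams,
    ewlc_extension,
    wlc_extension,
)

__all__ = [
    "TitinIsoform",
    "TitinStrandState",
    "ChainSolution",
    "default_isoform",
    "slack_length",
    "chain_force",
    "chain_force_vec",
    "apply_calcium",
    "bind_to_actin",
    "actin_extension",
    "CALCIUM_FORCE_RATIO",
    "CALCIUM_REFERENCE_HSL",
]

#: Contour-length gain of one IG domain upon unfolding (nm).
IG_UNFOLDING_GAIN = 26.0
#: Contour length of one folded IG domain (nm).
FOLDED_IG_CONTOUR = 4.5
#: Contour length per PEVK residue (nm).
PEVK_RESIDUE_CONTOUR = 0.36

#: Passive-force ratio the high-calcium parameter set is calibrated to.
CALCIUM_FORCE_RATIO = 1.25
#: Reference half-sarcomere length (nm) for that calibration (3.4 um sarcomere).
CALCIUM_REFERENCE_HSL = 1700.0

#: Force used to define compartment rest lengths below slack (pN).
SLACK_EPSILON_FORCE = 1e-6


@dataclass(frozen=True)
class TitinIsoform:
    """Structural composition and elasticity of one titin strand.

    Defaults describe the 3,400-kD rabbit psoas isoform: 50 proximal and
    26 distal IG domains and 800 PEVK residues; per-domain contour lengths
    4.5 nm (folded) and 30.5 nm (unfolded, a 26 nm gain), and a PEVK
    contour of 0.36 nm per residue.
    """

    n_proximal_ig: int = 50
    n_distal_ig: int = 26
    n_pevk_residues: int = 800
    folded_ig: WLCParams = WLCParams(10.0, FOLDED_IG_CONTOUR)
    unfolded_ig: WLCParams = WLCParams(0.8, FOLDED_IG_CONTOUR + IG_UNFOLDING_GAIN)
    pevk: ExtensibleWLCParams = ExtensibleWLCParams(
        1.4, PEVK_RESIDUE_CONTOUR * 800, elastic_modulus=75.0
    )
    distal_end_filament_length: float = 117.0
    half_a_band_length: float = 800.0
    a_band_stiffness: float = 1e4
    calcium: bool = False

    def __post_init__(self) -> None:
        for name in ("n_proximal_ig", "n_distal_ig", "n_pevk_residues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        gain = self.unfolded_ig.contour_length - self.folded_ig.contour_length
        if abs(gain - IG_UNFOLDING_GAIN) > 1e-9:
            raise ValueError(
                "unfolded minus folded IG contour length must equal "
                f"{IG_UNFOLDING_GAIN} nm, got {gain}"
            )
        expected_pevk = PEVK_RESIDUE_CONTOUR * self.n_pevk_residues
        if abs(self.pevk.contour_length - expected_pevk) > 1e-9:
            raise ValueError(
                f"PEVK contour length must be {PEVK_RESIDUE_CONTOUR} nm x "
                f"{self.n_pevk_residues} residues = {expected_pevk} nm, "
                f"got {self.pevk.contour_length}"
            )
        if self.distal_end_filament_length < 0:
            raise ValueError("distal_end_filament_length must be >= 0")
        if self.half_a_band_length <= 0:
            raise ValueError("half_a_band_length must be > 0")
        if self.a_band_stiffness <= 0:
            raise ValueError("a_band_stiffness must be > 0")

    @property
    def rigid_offset(self) -> float:
        """Summed length of the force-independent compartments (nm)."""
        return self.half_a_band_length + self.distal_end_filament_length


def default_isoform(temperature: float = DEFAULT_TEMPERATURE, **overrides) -> TitinIsoform:
    """Construct the default isoform at the given temperature."""
    iso = TitinIsoform(
        folded_ig=WLCParams(10.0, FOLDED_IG_CONTOUR, temperature),
        unfolded_ig=WLCParams(0.8, FOLDED_IG_CONTOUR + IG_UNFOLDING_GAIN, temperature),
        pevk=ExtensibleWLCParams(
            1.4, PEVK_RESIDUE_CONTOUR * 800, temperature, elastic_modulus=75.0
        ),
    )
    if overrides:
        iso = replace(iso, **overrides)
    return iso


@dataclass(frozen=True)
class TitinStrandState:
    """Per-strand unfolding and binding state.

    ``n_unfolded`` never decreases within one simulation (no refolding).
    ``frozen_proximal_length`` is present iff the strand is actin-bound and
    records the summed end-to-end length of all proximal IG domains at the
    moment of binding.
    """

    n_unfolded: int = 0
    calcium_bound: bool = False
    actin_bound: bool = False
    frozen_proximal_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_unfolded < 0:
            raise ValueError("n_unfolded must be >= 0")
        if self.actin_bound:
            if self.frozen_proximal_length is None:
                raise ValueError("actin-bound state requires frozen_proximal_length")
            if self.frozen_proximal_length < 0:
                raise ValueError("frozen_proximal_length must be >= 0")
        elif self.frozen_proximal_length is not None:
            raise ValueError("frozen_proximal_length only valid when actin_bound")


@dataclass(frozen=True)
class ChainSolution:
    """Equal-force equilibrium of one strand at a given half-sarcomere length.

    Compartment lengths sum to the input HSL; every compliant compartment
    carries ``common_force``.  When the strand is actin-bound the proximal
    compartment is frozen and per-domain splits are unavailable (None).
    """

    common_force: float
    folded_ig_each: Optional[float]
    unfolded_ig_each: Optional[float]
    proximal_total: float
    pevk_length: float
    distal_length: float
    a_band_length: float

    @property
    def total_length(self) -> float:
        return (
            self.proximal_total
            + self.pevk_length
            + self.distal_length
            + self.a_band_length
        )


def _check_state(isoform: TitinIsoform, state: TitinStrandState) -> None:
    if state.n_unfolded > isoform.n_proximal_ig:
        raise ValueError(
            f"n_unfolded ({state.n_unfolded}) exceeds number of proximal IG "
            f"domains ({isoform.n_proximal_ig})"
        )


def _compliant_extension(force, isoform: TitinIsoform, n_unfolded: int, bound: bool):
    """Summed extension of the force-dependent compartments at ``force``.

    Aggregated WLCs: identical domains in series at equal force compose
    exactly into one WLC whose contour is the summed per-domain contour.
    """
    f = np.asarray(force, dtype=float)
    n_folded = isoform.n_proximal_ig - n_unfolded
    x = ewlc_extension(f, isoform.pevk) + f / isoform.a_band_stiffness
    if not bound:
        if n_folded > 0:
            x = x + n_folded * wlc_extension(f, isoform.folded_ig)
        if n_unfolded > 0:
            x = x + n_unfolded * wlc_extension(f, isoform.unfolded_ig)
    return x


def _proximal_split(force: float, isoform: TitinIsoform, n_unfolded: int):
    """Per-domain folded/unfolded lengths at ``force`` for an unbound strand."""
    folded_each = (
        float(wlc_extension(force, isoform.folded_ig))
        if isoform.n_proximal_ig - n_unfolded > 0
        else 0.0
    )
    unfolded_each = (
        float(wlc_extension(force, isoform.unfolded_ig)) if n_unfolded > 0 else 0.0
    )
    return folded_each, unfolded_each


def slack_length(isoform: TitinIsoform, state: TitinStrandState) -> float:
    """Half-sarcomere length (nm) at which chain force first exceeds zero.

    Below this length the physics leaves compartment lengths undefined; the
    package adopts the convention that at slack every compartment sits at
    the length it would have under an infinitesimal force (1e-6 pN), which
    makes force traces continuous across the slack crossing.
    """
    _check_state(isoform, state)
    frozen = state.frozen_proximal_length if state.actin_bound else 0.0
    x = _compliant_extension(
        SLACK_EPSILON_FORCE, isoform, state.n_unfolded, state.actin_bound
    )
    return float(x) + (frozen or 0.0) + isoform.rigid_offset


def _solve_common_force(
    hsl: float, isoform: TitinIsoform, n_unfolded: int, bound: bool, frozen: float
) -> float:
    """Root of X(f) = HSL for the equal-force constraint (exact, scalar)."""
    target = hsl - isoform.rigid_offset - (frozen if bound else 0.0)

    def g(f):
        return float(_compliant_extension(f, isoform, n_unfolded, bound)) - target

    f_hi = 1.0
    for _ in range(80):
        if g(f_hi) > 0:
            break
        f_hi *= 2.0
    else:
        raise ArithmeticError(
            "no finite force satisfies the chain length constraint "
            f"(HSL={hsl} nm; degenerate, effectively inextensible configuration)"
        )
    return brentq(g, 0.0, f_hi, xtol=1e-14, rtol=1e-15, maxiter=200)


def chain_force(
    hsl: float, isoform: TitinIsoform, state: TitinStrandState
) -> ChainSolution:
    """Equal-force solution of the serial chain at half-sarcomere length ``hsl``.

    At or below the slack length the force is zero and the compliant
    compartments are placed at their infinitesimal-force rest lengths,
    scaled proportionally so that compartment lengths always sum to ``hsl``.
    """
    if hsl <= 0:
        raise ValueError("half_sarcomere_length must be > 0")
    _check_state(isoform, state)
    bound = state.actin_bound
    frozen = state.frozen_proximal_length if bound else 0.0
    slack = slack_length(isoform, state)

    if hsl <= slack:
        rigid = isoform.rigid_offset + (frozen or 0.0)
        if hsl < rigid:
            raise ValueError(
                f"HSL = {hsl} nm is shorter than the rigid compartments "
                f"({rigid} nm); outside the modelled regime"
            )
        # scale the epsilon-force configuration of the compliant compartments
        rest_compliant = slack - rigid
        scale = (hsl - rigid) / rest_compliant if rest_compliant > 0 else 0.0
        f_eps = SLACK_EPSILON_FORCE
        pevk = float(ewlc_extension(f_eps, isoform.pevk)) * scale
        aband = isoform.half_a_band_length + (f_eps / isoform.a_band_stiffness) * scale
        if bound:
            return ChainSolution(
                0.0, None, None, float(frozen), pevk,
                isoform.distal_end_filament_length, aband,
            )
        fe, ue = _proximal_split(f_eps, isoform, state.n_unfolded)
        n_folded = isoform.n_proximal_ig - state.n_unfolded
        return ChainSolution(
            0.0,
            fe * scale,
            ue * scale,
            (n_folded * fe + state.n_unfolded * ue) * scale,
            pevk,
            isoform.distal_end_filament_length,
            aband,
        )

    f = _solve_common_force(hsl, isoform, state.n_unfolded, bound, frozen or 0.0)
    pevk = float(ewlc_extension(f, isoform.pevk))
    aband = isoform.half_a_band_length + f / isoform.a_band_stiffness
    if bound:
        return ChainSolution(
            f, None, None, float(frozen), pevk,
            isoform.distal_end_filament_length, aband,
        )
    fe, ue = _proximal_split(f, isoform, state.n_unfolded)
    n_folded = isoform.n_proximal_ig - state.n_unfolded
    return ChainSolution(
        f,
        fe,
        ue,
        n_folded * fe + state.n_unfolded * ue,
        pevk,
        isoform.distal_end_filament_length,
        aband,
    )


def _compliant_extension_and_slope(f, isoform: TitinIsoform, n_unfolded: int):
    """X(f) and dX/df of an unbound strand's compliant compartments.

    X is increasing and concave in f (each term is the inverse of a convex
    force law plus linear enthalpic/spring terms), which the vectorised
    Newton solver below exploits.
    """
    from .polymer import _wlc_shape_inverse, _wlc_shape_prime

    f = np.asarray(f, dtype=float)
    x = f / isoform.a_band_stiffness
    slope = np.full_like(f, 1.0 / isoform.a_band_stiffness)
    n_folded = isoform.n_proximal_ig - n_unfolded
    for params, count in (
        (isoform.folded_ig, n_folded),
        (isoform.unfolded_ig, n_unfolded),
    ):
        if count > 0:
            fs = params.force_scale
            u = _wlc_shape_inverse(f / fs)
            cl = count * params.contour_length
            x = x + cl * u
            slope = slope + cl / (fs * _wlc_shape_prime(u))
    pevk = isoform.pevk
    fs = pevk.force_scale
    u = _wlc_shape_inverse(f / fs)
    cl = pevk.contour_length
    x = x + cl * (u + f / pevk.elastic_modulus)
    slope = slope + cl * (1.0 / (fs * _wlc_shape_prime(u)) + 1.0 / pevk.elastic_modulus)
    return x, slope


def chain_force_vec(hsl, isoform: TitinIsoform, n_unfolded: int = 0) -> np.ndarray:
    """Vectorised common force (pN) for an unbound strand at many lengths.

    Newton iteration on the concave extension sum with its analytic slope,
    started from below (monotone convergence); used by the calibration
    fits where the chain model is evaluated on a grid.
    """
    hsl = np.atleast_1d(np.asarray(hsl, dtype=float))
    target = hsl - isoform.rigid_offset
    slack_x = float(
        _compliant_extension(SLACK_EPSILON_FORCE, isoform, n_unfolded, False)
    )
    below = target <= slack_x
    f = np.full_like(target, SLACK_EPSILON_FORCE)
    for _ in range(200):
        x, slope = _compliant_extension_and_slope(f, isoform, n_unfolded)
        df = (target - x) / slope
        f = np.maximum(f + df, 0.0)
        if np.max(np.abs(df) / np.maximum(f, 1.0)) < 1e-13:
            break
    return np.where(below, 0.0, f)


# -- calcium parameter set ---------------------------------------------------

_CALCIUM_CACHE: dict = {}


def _calcium_scale(isoform: TitinIsoform) -> float:
    """Persistence-length multiplier of the high-calcium parameter set.

    Calibrated so that the passive force of a strand with no unfolded
    domains at the reference length (HSL 1700 nm, sarcomere 3.4 um) is
    exactly 25% above the low-calcium value.
    """
    key = (
        isoform.n_proximal_ig,
        isoform.folded_ig,
        isoform.unfolded_ig,
        isoform.pevk,
        isoform.distal_end_filament_length,
        isoform.half_a_band_length,
        isoform.a_band_stiffness,
    )
    if key in _CALCIUM_CACHE:
        return _CALCIUM_CACHE[key]
    state = TitinStrandState()
    f_low = chain_force(CALCIUM_REFERENCE_HSL, isoform, state).common_force
    if f_low <= 0:
        raise ValueError(
            "reference length is below slack for this isoform; cannot "
            "calibrate the calcium parameter set"
        )

    def ratio_error(lam: float) -> float:
        iso = _scaled_isoform(isoform, lam)
        f_high = chain_force(CALCIUM_REFERENCE_HSL, iso, state).common_force
        return f_high / f_low - CALCIUM_FORCE_RATIO

    lam = brentq(ratio_error, 1e-4, 1.0 - 1e-9, xtol=1e-12, rtol=1e-12)
    _CALCIUM_CACHE[key] = lam
    return lam


def _scaled_isoform(isoform: TitinIsoform, lam: float) -> TitinIsoform:
    return replace(
        isoform,
        folded_ig=replace(
            isoform.folded_ig,
            persistence_length=isoform.folded_ig.persistence_length * lam,
        ),
        unfolded_ig=replace(
            isoform.unfolded_ig,
            persistence_length=isoform.unfolded_ig.persistence_length * lam,
        ),
        pevk=replace(
            isoform.pevk,
            persistence_length=isoform.pevk.persistence_length * lam,
        ),
        calcium=True,
    )


def apply_calcium(isoform: TitinIsoform) -> TitinIsoform:
    """Return the high-calcium parameter set (idempotent).

    Scales the persistence lengths of the IG and PEVK segments so that the
    passive force at the 3.4 um reference sarcomere length rises by 25%.
    """
    if isoform.calcium:
        return isoform
    return _scaled_isoform(isoform, _calcium_scale(isoform))


def bind_to_actin(
    state: TitinStrandState,
    solution: ChainSolution,
    *,
    crossbridges_active: bool = True,
    site_spacing: float = 0.0,
) -> TitinStrandState:
    """Bind titin to actin at the most proximal PEVK residue.

    The proximal IG compartment is frozen at its current summed end-to-end
    length (nearest-binding-site convention: compartment lengths are
    unchanged by the binding event, so the chain force is continuous).
    An optional discrete actin ``site_spacing`` (nm) rounds the frozen
    length down to the nearest site.
    """
    if state.actin_bound:
        raise ValueError("strand is already actin-bound")
    if not crossbridges_active:
        raise ValueError(
            "actin-titin binding is only enabled when myofibrils are "
            "activated (cross-bridge interaction inhibited)"
        )
    frozen = solution.proximal_total
    if site_spacing > 0:
        frozen = np.floor(frozen / site_spacing) * site_spacing
    return replace(state, actin_bound=True, frozen_proximal_length=float(frozen))


def unbind_from_actin(state: TitinStrandState) -> TitinStrandState:
    """Release the actin bond (deactivation, immediate-unbind scenario)."""
    if not state.actin_bound:
        return state
    return replace(state, actin_bound=False, frozen_proximal_length=None)


def actin_extension(filament_length_um: float, stress_increase: float) -> float:
    """Actin compliance arithmetic documenting the rigid-actin assumption.

    Returns the actin stretch in picometres: 20 pm per um of filament
    length per nN/um^2 of force increase.
    """
    if filament_length_um < 0 or stress_increase < 0:
        raise ValueError("inputs must be non-negative")
    return 20.0 * filament_length_um * stress_increase
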