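"""Protocol engine coupling the cross-bridge and titin sub-models.

A protocol is an ordered list of phases (set length, activate, ramp, hold,
deactivate) executed on a shared clock.  The cross-bridge distribution is
advanced every PDE step; the titin ensemble is solved quasi-statically on a
coarser titin clock (chain equilibrium is instantaneous relative to
protocol timescales).  Actin-titin binding and the calcium parameter switch
are applied at activation according to the scenario flags:

* ``instantaneous-calcium`` (default): the calcium parameter set is applied
  at activation; binding becomes effective at the onset of the first
  externally imposed ramp after activation.
* ``instantaneous-binding``: titin binds at activation (at its low-calcium
  compartment lengths) and the calcium parameters are applied once bound.

At deactivation the calcium parameters are reverted instantly and titin
unbinds (or not) according to the deactivation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from . import crossbridge as cb
from .crossbridge import CrossBridgeParams, CrossBridgeState, OverlapFunction
from .titin import TitinIsoform, default_isoform
from .unfolding import EnsembleConfig, TitinEnsemble, UnfoldingParams

__all__ = [
    "SetLength",
    "Activate",
    "Ramp",
    "Hold",
    "Deactivate",
    "Protocol",
    "ScenarioFlags",
    "ModelConfig",
    "ForceTrace",
    "SteadyStateError",
    "run_protocol",
    "steady_state_stress",
    "residual_force_enhancement",
    "force_depression",
    "passive_force_enhancement",
    "canonical_protocols",
    "get_protocol",
    "make_stretch_protocol",
    "isometric_reference",
    "compile_length_schedule",
]


# -- protocol phases ---------------------------------------------------------


@dataclass(frozen=True)
class SetLength:
    """Instantaneously set the sarcomere length (um); a setup phase."""

    sarcomere_um: float

    def __post_init__(self):
        if self.sarcomere_um <= 0:
            raise ValueError("sarcomere length must be > 0")


@dataclass(frozen=True)
class Activate:
    """Switch on activation: cross-bridge cycling and/or calcium."""

    crossbridges: bool = True
    calcium: str = "high"

    def __post_init__(self):
        if self.calcium not in ("high", "low"):
            raise ValueError("calcium must be 'high' or 'low'")


@dataclass(frozen=True)
class Ramp:
    """Constant-speed length ramp to a target sarcomere length.

    ``speed_nm_per_s`` is per sarcomere length: each sarcomere lengthens or
    shortens at this many nm/s, so the half sarcomere sees half of it.
    """

    target_um: float
    speed_nm_per_s: float = 100.0

    def __post_init__(self):
        if self.target_um <= 0:
            raise ValueError("target length must be > 0")
        if self.speed_nm_per_s <= 0:
            raise ValueError("ramp speed must be > 0")


@dataclass(frozen=True)
class Hold:
    duration_s: float

    def __post_init__(self):
        if self.duration_s < 0:
            raise ValueError("hold duration must be >= 0")


@dataclass(frozen=True)
class Deactivate:
    """Switch activation off, then hold for ``hold_s`` seconds."""

    hold_s: float = 5.0

    def __post_init__(self):
        if self.hold_s < 0:
            raise ValueError("hold duration must be >= 0")


Phase = Union[SetLength, Activate, Ramp, Hold, Deactivate]


@dataclass(frozen=True)
class Protocol:
    name: str
    phases: tuple
    titin_actin_binding: bool = True

    def __post_init__(self):
        if not self.phases:
            raise ValueError("protocol must contain at least one phase")
        for p in self.phases:
            if not isinstance(p, (SetLength, Activate, Ramp, Hold, Deactivate)):
                raise TypeError(f"unknown phase type: {p!r}")

    @property
    def final_length_um(self) -> Optional[float]:
        length = None
        for p in self.phases:
            if isinstance(p, SetLength):
                length = p.sarcomere_um
            elif isinstance(p, Ramp):
                length = p.target_um
        return length

    @property
    def has_activation(self) -> bool:
        return any(isinstance(p, Activate) for p in self.phases)


@dataclass(frozen=True)
class ScenarioFlags:
    """Ordering of calcium vs binding at activation, and unbinding at
    deactivation; the two extremes considered for each."""

    calcium_ordering: str = "instantaneous-calcium"
    deactivation_unbinding: str = "keep-bound"

    def __post_init__(self):
        if self.calcium_ordering not in (
            "instantaneous-calcium",
            "instantaneous-binding",
        ):
            raise ValueError(f"unknown calcium_ordering: {self.calcium_ordering}")
        if self.deactivation_unbinding not in ("keep-bound", "immediate-unbind"):
            raise ValueError(
                f"unknown deactivation_unbinding: {self.deactivation_unbinding}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Everything a run needs besides the protocol, scenario and seed."""

    isoform: TitinIsoform = field(default_factory=default_isoform)
    unfolding: UnfoldingParams = field(default_factory=UnfoldingParams)
    crossbridge: CrossBridgeParams = field(default_factory=CrossBridgeParams)
    overlap: OverlapFunction = field(default_factory=OverlapFunction)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    pde_dt: float = 1e-4
    titin_every: int = 10
    output_every: int = 10
    rupture_force: float = 600.0
    binding_site_spacing: float = 0.0

    def __post_init__(self):
        if self.pde_dt <= 0:
            raise ValueError("pde_dt must be > 0")
        if self.titin_every < 1 or self.output_every < 1:
            raise ValueError("clock dividers must be >= 1")
        if self.rupture_force <= 0:
            raise ValueError("rupture_force must be > 0")


@dataclass
class ForceTrace:
    """Sampled time series of one run; stresses in nN/um^2.

    ``total`` equals ``active + titin`` at every sample by construction.
    ``events`` is the per-phase event log; ``truncated`` flags a rupture
    stop before the protocol completed.
    """

    time_s: np.ndarray
    sarcomere_um: np.ndarray
    active_stress: np.ndarray
    titin_stress: np.ndarray
    total_stress: np.ndarray
    mean_unfolded: np.ndarray
    events: list = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return self.time_s.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "sarcomere_um": self.sarcomere_um,
                "active_nN_um2": self.active_stress,
                "titin_nN_um2": self.titin_stress,
                "total_nN_um2": self.total_stress,
                "mean_unfolded": self.mean_unfolded,
            }
        )


class SteadyStateError(RuntimeError):
    pass


# -- length schedule compilation --------------------------------------------


def compile_length_schedule(protocol: Protocol, dt: float):
    """Times and half-sarcomere lengths (nm) of a protocol's length history.

    Activation/deactivation phases contribute their hold durations; the
    mechanical schedule is what a passive run of the protocol would see.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sl = None
    t = [0.0]
    lengths = []
    segs = []  # (duration, v_sl nm/s)
    for p in protocol.phases:
        if isinstance(p, SetLength):
            sl = p.sarcomere_um
        elif isinstance(p, Ramp):
            if sl is None:
                raise ValueError("ramp before any set_length phase")
            dur = abs(p.target_um - sl) * 1000.0 / p.speed_nm_per_s
            v = np.sign(p.target_um - sl) * p.speed_nm_per_s
            segs.append((sl, dur, v))
            sl = p.target_um
        elif isinstance(p, Hold):
            segs.append((sl, p.duration_s, 0.0))
        elif isinstance(p, Deactivate):
            segs.append((sl, p.hold_s, 0.0))
    if sl is None:
        raise ValueError("protocol never sets a length")
    times = [0.0]
    hsl = []
    start_sl = segs[0][0] if segs else sl
    hsl = [start_sl * 500.0]
    t_now = 0.0
    for seg_sl, dur, v in segs:
        n = max(1, int(round(dur / dt)))
        for i in range(1, n + 1):
            t_now += dt
            times.append(t_now)
            hsl.append((seg_sl + v * min(i * dt, dur) / 1000.0) * 500.0)
        sl_end = seg_sl + v * dur / 1000.0
        hsl[-1] = sl_end * 500.0
    return np.asarray(times), np.asarray(hsl)


# -- the engine --------------------------------------------------------------


def _zero_attachment(x):
    return np.zeros_like(np.asarray(x, dtype=float))


def run_protocol(
    protocol: Protocol,
    scenario: ScenarioFlags,
    model: ModelConfig,
    seed: int = 0,
) -> ForceTrace:
    """Integrate both sub-models through the protocol's phases.

    Returns the sampled :class:`ForceTrace`.  Reproducible given ``seed``:
    all Monte-Carlo randomness flows from one root seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ens = TitinEnsemble(model.isoform, model.unfolding, model.ensemble, rng=rng)
    dt = model.pde_dt
    titin_dt = dt * model.titin_every

    cb_params = model.crossbridge
    detach_params = replace(cb_params, attachment=_zero_attachment, scale=1.0)
    if protocol.has_activation:
        cb.calibrated_scale(cb_params)  # resolve S once up front

    sl_um: Optional[float] = None
    cb_state: Optional[CrossBridgeState] = None
    cb_cycling = False  # attachment enabled
    pending_bind = False
    events: list = []
    truncated = False

    times: list = []
    sls: list = []
    f_active: list = []
    f_titin: list = []
    n_unf: list = []

    t_now = 0.0
    titin_stress = 0.0
    mean_nu = 0.0

    def log(kind: str, **detail):
        events.append({"time_s": round(t_now, 9), "event": kind, **detail})

    def titin_update() -> bool:
        """Quasi-static titin solve + unfolding step; True if rupture."""
        nonlocal titin_stress, mean_nu
        forces = ens.forces(sl_um * 500.0)
        titin_stress = ens.stress(forces)
        mean_nu = float(np.mean(ens.n_unfolded))
        fmax = float(np.max(forces))
        if fmax > model.rupture_force:
            log("rupture-stop", max_strand_force_pN=fmax)
            return True
        ens.step_unfolding(forces, titin_dt)
        return False

    def record():
        times.append(t_now)
        sls.append(sl_um)
        act = (
            cb.active_force(cb_state, sl_um, cb_params, model.overlap)
            if cb_state is not None
            else 0.0
        )
        f_active.append(act)
        f_titin.append(titin_stress)
        n_unf.append(mean_nu)

    def do_bind():
        nonlocal pending_bind
        n = ens.bind(sl_um * 500.0)
        pending_bind = False
        log("actin-titin-binding", strands=n)

    def run_segment(duration: float, v_sl: float) -> bool:
        """Advance time; returns True if the run must stop (rupture)."""
        nonlocal t_now, sl_um, cb_state
        n_steps = max(1, int(round(duration / dt)))
        v_hsl = v_sl * 0.5  # nm/s at the half-sarcomere
        for i in range(n_steps):
            if i % model.titin_every == 0:
                if titin_update():
                    record()
                    return True
            if i % model.output_every == 0:
                record()
            if cb_state is not None:
                params = cb_params if cb_cycling else detach_params
                cb_state = cb.step_pde(cb_state, v_hsl, dt, params)
            t_now += dt
            sl_um += v_sl * dt / 1000.0
        return False

    for phase in protocol.phases:
        if truncated:
            break
        if isinstance(phase, SetLength):
            sl_um = phase.sarcomere_um
            log("set-length", sarcomere_um=sl_um)
        elif isinstance(phase, Activate):
            if sl_um is None:
                raise ValueError("activate before any set_length phase")
            log(
                "activation",
                crossbridges=phase.crossbridges,
                calcium=phase.calcium,
            )
            if phase.crossbridges:
                cb_state = CrossBridgeState(
                    np.zeros(cb_params.n_x), np.zeros(cb_params.n_x), 1.0
                )
                cb_cycling = True
            want_binding = protocol.titin_actin_binding
            if want_binding and not phase.crossbridges:
                log("binding-suppressed", reason="cross-bridge interaction inhibited")
                want_binding = False
            if scenario.calcium_ordering == "instantaneous-binding":
                if want_binding:
                    do_bind()
                if phase.calcium == "high":
                    ens.set_calcium(True)
                    log("calcium-applied")
            else:  # instantaneous-calcium
                if phase.calcium == "high":
                    ens.set_calcium(True)
                    log("calcium-applied")
                pending_bind = want_binding
        elif isinstance(phase, Ramp):
            if sl_um is None:
                raise ValueError("ramp before any set_length phase")
            if pending_bind:
                do_bind()
            dur = abs(phase.target_um - sl_um) * 1000.0 / phase.speed_nm_per_s
            v_sl = np.sign(phase.target_um - sl_um) * phase.speed_nm_per_s
            log("ramp", target_um=phase.target_um, speed_nm_per_s=phase.speed_nm_per_s)
            truncated = run_segment(dur, float(v_sl))
            if not truncated:
                sl_um = phase.target_um
        elif isinstance(phase, Hold):
            if sl_um is None:
                raise ValueError("hold before any set_length phase")
            truncated = run_segment(phase.duration_s, 0.0)
        elif isinstance(phase, Deactivate):
            log("deactivation")
            cb_cycling = False
            ens.set_calcium(False)
            if scenario.deactivation_unbinding == "immediate-unbind":
                n = ens.unbind()
                log("actin-titin-unbinding", strands=n)
            truncated = run_segment(phase.hold_s, 0.0)

    if not truncated:
        titin_update()
    record()

    times_a = np.asarray(times)
    active_a = np.asarray(f_active)
    titin_a = np.asarray(f_titin)
    return ForceTrace(
        time_s=times_a,
        sarcomere_um=np.asarray(sls),
        active_stress=active_a,
        titin_stress=titin_a,
        total_stress=active_a + titin_a,
        mean_unfolded=np.asarray(n_unf),
        events=events,
        truncated=truncated,
    )


# -- history-dependence metrics ---------------------------------------------


def steady_state_stress(
    trace: ForceTrace,
    window_s: float = 1.0,
    drift_tol: float = 1e-3,
) -> float:
    """Mean total stress over the trailing window, after a drift check.

    Drift is the fitted linear change over the window relative to the
    window mean; above ``drift_tol`` (default 0.1%) the trace is not
    steady and an error with the drift diagnostic is raised.
    """
    t = trace.time_s
    mask = t >= t[-1] - window_s
    if mask.sum() < 4:
        raise SteadyStateError("trace too short for the steady-state window")
    tw = t[mask]
    fw = trace.total_stress[mask]
    mean = float(np.mean(fw))
    slope = float(np.polyfit(tw, fw, 1)[0])
    drift = abs(slope) * window_s / abs(mean) if mean != 0 else abs(slope)
    if drift > drift_tol:
        raise SteadyStateError(
            f"no steady state: relative drift {drift:.3e} over the trailing "
            f"{window_s} s window exceeds {drift_tol:.1e} "
            f"(mean {mean:.3f} nN/um^2, slope {slope:.3e} nN/um^2/s)"
        )
    return mean


def residual_force_enhancement(
    stretch_trace: ForceTrace, isometric_trace: ForceTrace, **kw
) -> float:
    """Percent excess of post-stretch steady force over the isometric
    reference at the final length."""
    f_stretch = steady_state_stress(stretch_trace, **kw)
    f_iso = steady_state_stress(isometric_trace, **kw)
    return 100.0 * (f_stretch / f_iso - 1.0)


def force_depression(
    shorten_trace: ForceTrace, isometric_trace: ForceTrace, **kw
) -> float:
    """Percent change of post-shortening steady force vs the isometric
    reference (negative when force is depressed)."""
    return residual_force_enhancement(shorten_trace, isometric_trace, **kw)


def passive_force_enhancement(
    protocol: Protocol,
    model: ModelConfig,
    seed: int = 0,
    scenarios=("keep-bound", "immediate-unbind"),
    window_s: float = 1.0,
) -> dict:
    """Post-deactivation passive force excess over the purely passive run.

    Runs the protocol (which must end with a deactivation phase) once per
    deactivation scenario plus a never-activated passive control with the
    same length history, and reports 100 * (deactivated / passive - 1)
    per scenario.
    """
    if not isinstance(protocol.phases[-1], Deactivate):
        raise ValueError("protocol must end with a deactivate phase")
    passive = _passive_variant(protocol)
    ref = run_protocol(passive, ScenarioFlags(), model, seed)
    f_ref = _trailing_mean(ref, window_s)
    out = {}
    for s in scenarios:
        flags = ScenarioFlags(deactivation_unbinding=s)
        tr = run_protocol(protocol, flags, model, seed)
        out[s] = 100.0 * (_trailing_mean(tr, window_s) / f_ref - 1.0)
    return out


def _trailing_mean(trace: ForceTrace, window_s: float) -> float:
    mask = trace.time_s >= trace.time_s[-1] - window_s
    return float(np.mean(trace.total_stress[mask]))


# -- canonical protocol registry --------------------------------------------


def _passive_variant(protocol: Protocol) -> Protocol:
    phases = tuple(
        Hold(p.hold_s) if isinstance(p, Deactivate) else p
        for p in protocol.phases
        if not isinstance(p, Activate)
    )
    return Protocol(protocol.name + "/passive", phases, titin_actin_binding=False)


def _calcium_only_variant(protocol: Protocol) -> Protocol:
    phases = tuple(
        Activate(crossbridges=False, calcium=p.calcium)
        if isinstance(p, Activate)
        else p
        for p in protocol.phases
    )
    return Protocol(protocol.name + "/calcium-only", phases)


def _no_binding_variant(protocol: Protocol) -> Protocol:
    return Protocol(
        protocol.name + "/no-binding", protocol.phases, titin_actin_binding=False
    )


def make_stretch_protocol(
    name: str,
    start_um: float,
    end_um: float,
    speed_nm_per_s: float = 100.0,
    activation_hold_s: float = 2.0,
    final_hold_s: float = 12.0,
    passive_start_um: Optional[float] = None,
) -> Protocol:
    """Activate at ``start_um`` (after an optional passive pre-ramp from
    ``passive_start_um``) and ramp to ``end_um``."""
    phases: list = []
    if passive_start_um is not None and passive_start_um != start_um:
        phases += [SetLength(passive_start_um), Ramp(start_um, speed_nm_per_s)]
    else:
        phases.append(SetLength(start_um))
    phases += [
        Activate(),
        Hold(activation_hold_s),
        Ramp(end_um, speed_nm_per_s),
    ]
    if final_hold_s > 0:
        phases.append(Hold(final_hold_s))
    return Protocol(name, tuple(phases))


def isometric_reference(protocol: Protocol) -> Protocol:
    """Fresh isometric run activated at the protocol's final length.

    Used as the "corresponding isometric force" reference for the
    enhancement/depression metrics; shares the scenario flags of the run it
    is compared against.
    """
    final = protocol.final_length_um
    activates = [p for p in protocol.phases if isinstance(p, Activate)]
    act = activates[0] if activates else Activate()
    # match the total activated duration: activation hold + ramps + holds
    total = 0.0
    sl = None
    seen_activate = False
    for p in protocol.phases:
        if isinstance(p, SetLength):
            sl = p.sarcomere_um
        elif isinstance(p, Activate):
            seen_activate = True
        elif isinstance(p, Ramp):
            if seen_activate and sl is not None:
                total += abs(p.target_um - sl) * 1000.0 / p.speed_nm_per_s
            sl = p.target_um
        elif isinstance(p, Hold):
            if seen_activate:
                total += p.duration_s
    return Protocol(
        protocol.name + "/isometric-reference",
        (SetLength(final), act, Hold(max(total, 4.0))),
        titin_actin_binding=protocol.titin_actin_binding,
    )


def canonical_protocols() -> dict:
    """Named registry of the simulated experiments.

    Each base protocol is exposed in four condition variants:
    the full three-filament model (base name), ``/passive`` (never
    activated), ``/calcium-only`` (calcium effects, cross-bridges
    inhibited, hence no binding) and ``/no-binding`` (cross-bridges +
    calcium but actin-titin binding disabled, i.e. the regular
    cross-bridge model plus passive titin).
    """
    base = {}
    base["beyond-overlap-2.4"] = Protocol(
        "beyond-overlap-2.4",
        (SetLength(2.4), Activate(), Hold(2.0), Ramp(6.0, 100.0), Hold(1.0)),
    )
    base["beyond-overlap-3.4"] = Protocol(
        "beyond-overlap-3.4",
        (
            SetLength(2.4),
            Ramp(3.4, 100.0),
            Activate(),
            Hold(2.0),
            Ramp(6.0, 100.0),
            Hold(1.0),
        ),
    )
    base["rfe"] = make_stretch_protocol("rfe", 2.4, 3.0)
    base["fd"] = Protocol(
        "fd",
        (
            SetLength(2.4),
            Ramp(2.6, 100.0),
            Activate(),
            Hold(2.0),
            Ramp(2.4, 100.0),
            Hold(12.0),
        ),
    )
    base["pfe"] = Protocol(
        "pfe",
        (
            SetLength(2.4),
            Activate(),
            Hold(2.0),
            Ramp(3.0, 100.0),
            Hold(10.0),
            Deactivate(5.0),
        ),
    )
    registry = {}
    for name, proto in base.items():
        registry[name] = proto
        registry[name + "/passive"] = _passive_variant(proto)
        registry[name + "/calcium-only"] = _calcium_only_variant(proto)
        registry[name + "/no-binding"] = _no_binding_variant(proto)
    return registry


def get_protocol(name: str) -> Protocol:
    registry = canonical_protocols()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; known: {sorted(registry)}"
        ) from None
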