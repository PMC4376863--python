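"""Parameter estimation from passive stretch-shorten hysteresis loops.

A passive loop is classified into four parts: (1) the stretch limb below
the inflection point, where no significant IG-domain unfolding occurs;
(2) the stretch limb above it, where domains unfold; (3) early shortening,
an indefinite state (excluded from all fits); and (4) late shortening,
which follows a single fixed-composition chain curve.

Region 1 fixes the folded-IG persistence length and the PEVK persistence
length and elastic modulus; region 4 then fixes the number of unfolded
domains (exhaustive integer scan) and the unfolded-IG persistence length.
A synthetic loop generator provides ground-truth datasets for parameter
recovery, standing in for experimental data that exist only graphically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .titin import TitinIsoform, chain_force_vec, default_isoform
from .unfolding import EnsembleConfig, UnfoldingParams, ensemble_trace

__all__ = [
    "HysteresisDataset",
    "CalibrationResult",
    "CalibrationError",
    "classify_regions",
    "fit_region1",
    "fit_region4",
    "synthesize_hysteresis",
    "SynthesisTruth",
]

REGION_UNASSIGNED = 0


class CalibrationError(RuntimeError):
    pass


@dataclass
class HysteresisDataset:
    """Ordered (sarcomere length, stress) samples of one passive loop."""

    sarcomere_um: np.ndarray
    stress: np.ndarray
    phase: np.ndarray  # "stretch" | "shorten"
    region: np.ndarray = field(default=None)
    strands_per_um2: float = 500.0

    def __post_init__(self):
        self.sarcomere_um = np.asarray(self.sarcomere_um, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.region is None:
            self.region = np.zeros(self.sarcomere_um.size, dtype=int)
        else:
            self.region = np.asarray(self.region, dtype=int)
        n = self.sarcomere_um.size
        if not (self.stress.size == self.phase.size == self.region.size == n):
            raise ValueError("all columns must have equal length")
        if np.any(self.sarcomere_um <= 0):
            raise ValueError("sarcomere lengths must be positive")
        bad = set(self.phase) - {"stretch", "shorten"}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        is_shorten = self.phase == "shorten"
        if np.any(is_shorten[:-1] & ~is_shorten[1:]):
            raise ValueError("stretch phase must precede the shorten phase")

    @property
    def stretch_idx(self) -> np.ndarray:
        return np.flatnonzero(self.phase == "stretch")

    @property
    def shorten_idx(self) -> np.ndarray:
        return np.flatnonzero(self.phase == "shorten")

    def samples(self, region: int):
        m = self.region == region
        return self.sarcomere_um[m], self.stress[m]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sarcomere_um": self.sarcomere_um,
                "stress_nN_um2": self.stress,
                "phase": self.phase,
                "region": self.region,
            }
        )


@dataclass
class CalibrationResult:
    """Fitted WLC parameters with approximate standard errors."""

    folded_pl: float = np.nan
    pevk_pl: float = np.nan
    pevk_k0: float = np.nan
    n_unfolded: Optional[int] = None
    unfolded_pl: float = np.nan
    standard_errors: dict = field(default_factory=dict)
    residual_norms: dict = field(default_factory=dict)
    region4_scan: Optional[np.ndarray] = None

    def apply_to(self, isoform: TitinIsoform) -> TitinIsoform:
        """Return the isoform with all fitted parameters substituted."""
        iso = replace(
            isoform,
            folded_ig=replace(isoform.folded_ig, persistence_length=self.folded_pl),
            pevk=replace(
                isoform.pevk,
                persistence_length=self.pevk_pl,
                elastic_modulus=self.pevk_k0,
            ),
        )
        if np.isfinite(self.unfolded_pl):
            iso = replace(
                iso,
                unfolded_ig=replace(
                    iso.unfolded_ig, persistence_length=self.unfolded_pl
                ),
            )
        return iso


# -- classification ----------------------------------------------------------


def classify_regions(
    dataset: HysteresisDataset,
    *,
    window: int = 11,
    polyorder: int = 3,
    fallback_breakpoint_um: Optional[float] = None,
    region4_tol: float = 0.04,
    isoform: Optional[TitinIsoform] = None,
) -> HysteresisDataset:
    """Label every sample with its hysteresis region (in place; returned).

    The region-1/region-2 breakpoint is the inflection of the stretch limb:
    the point of steepest stress rise (maximum of the Savitzky-Golay
    smoothed first derivative, i.e. the sign change of the second
    derivative).  If the slope keeps growing to the end of the limb there
    is no detectable unfolding onset and the whole limb is region 1 (or it
    is split at ``fallback_breakpoint_um`` when supplied).  On the shorten
    limb, region 4 is the largest trailing portion that a single
    fixed-composition chain fits to within ``region4_tol`` relative rms
    (using a quick internal region-1 prefit for the fixed parameters); the
    remainder (the indefinite early-shortening state) is region 3.
    """
    iso = isoform if isoform is not None else default_isoform()
    si = dataset.stretch_idx
    hi = dataset.shorten_idx
    if si.size == 0:
        raise CalibrationError("dataset has no stretch samples")
    dataset.region[:] = REGION_UNASSIGNED

    # stretch limb: regions 1 and 2
    n1 = _stretch_breakpoint(
        dataset.sarcomere_um[si],
        dataset.stress[si],
        window,
        polyorder,
        fallback_breakpoint_um,
    )
    dataset.region[si[: n1 + 1]] = 1
    dataset.region[si[n1 + 1:]] = 2

    # shorten limb: regions 3 and 4
    if hi.size:
        try:
            pre = fit_region1(dataset, isoform=iso, n_starts=1)
            iso_cls = pre.apply_to(iso)
        except CalibrationError:
            iso_cls = iso
        n4 = _region4_extent(dataset, hi, iso_cls, region4_tol)
        dataset.region[hi[: hi.size - n4]] = 3
        if n4:
            dataset.region[hi[hi.size - n4:]] = 4
    return dataset


def _stretch_breakpoint(sl, f, window, polyorder, fallback_um) -> int:
    """Index (into the stretch limb) of the last region-1 sample."""
    n = sl.size
    if n < max(window, polyorder + 2):
        return n - 1
    win = min(window, n if n % 2 else n - 1)
    delta = float(np.mean(np.diff(sl)))
    d1 = savgol_filter(f, win, polyorder, deriv=1, delta=delta)
    half = win // 2
    interior = np.arange(half, n - half)
    if interior.size == 0:
        return n - 1
    i0 = int(interior[np.argmax(d1[interior])])
    if i0 >= n - half - 1:
        # slope still growing at the end: no detectable inflection
        if fallback_um is not None:
            import warnings

            warnings.warn(
                "no inflection detectable; using the user-supplied breakpoint",
                stacklevel=3,
            )
            return int(np.searchsorted(sl, fallback_um, side="right") - 1)
        return n - 1
    # refine within the smoothing window: the raw forward difference peaks
    # at the last interval before the slope collapses
    lo = max(i0 - half, 0)
    hi = min(i0 + half + 1, n - 1)
    raw = np.diff(f[lo : hi + 1]) / np.diff(sl[lo : hi + 1])
    return lo + int(np.argmax(raw))


def _region4_extent(dataset, hi, iso, tol) -> int:
    """Number of trailing shorten-limb samples that one chain curve fits.

    Tries the whole limb first (the common no-further-unfolding case) and
    otherwise bisects for the largest suffix below the residual tolerance.
    """
    sl = dataset.sarcomere_um[hi]
    y = dataset.stress[hi]
    n = sl.size
    k_min = min(4, n)

    def ok(k: int) -> bool:
        res = _fit_free_chain(sl[-k:], y[-k:], iso, dataset.strands_per_um2)
        return res <= tol

    if ok(n):
        return n
    lo, hi_k = k_min, n  # ok(lo) assumed; ok(hi_k) False
    if not ok(k_min):
        return k_min
    while hi_k - lo > 1:
        mid = (lo + hi_k) // 2
        if ok(mid):
            lo = mid
        else:
            hi_k = mid
    return lo


def _fit_free_chain(sl, y, iso, spu) -> float:
    """Relative rms of the best 2-parameter chain fit (composition +
    unfolded persistence length relaxed to continuous) to (sl, y)."""
    scale = np.maximum(np.abs(y), 1e-9 * np.max(np.abs(y)) + 1e-300)

    def resid(theta):
        nu, log_pl = theta
        nu = float(np.clip(nu, 0.0, iso.n_proximal_ig))
        model = _model_stress(sl, iso, nu, np.exp(log_pl), spu)
        return (model - y) / scale

    out = least_squares(
        resid,
        x0=np.array([iso.n_proximal_ig / 4, np.log(0.8)]),
        method="trf",
        bounds=([0.0, np.log(1e-3)], [iso.n_proximal_ig, np.log(1e3)]),
        xtol=1e-12,
        ftol=1e-12,
    )
    return float(np.sqrt(np.mean(out.fun**2)))


def _model_stress(sl_um, iso, n_unfolded, unfolded_pl, spu):
    """Ensemble stress (nN/um^2) of the chain model on a length grid.

    ``n_unfolded`` may be fractional here (classification relaxation); the
    chain is evaluated with fractional contour via interpolation between
    the neighbouring integer compositions.
    """
    iso = replace(
        iso, unfolded_ig=replace(iso.unfolded_ig, persistence_length=unfolded_pl)
    )
    hsl = np.asarray(sl_um, dtype=float) * 500.0
    lo = int(np.floor(n_unfolded))
    hi = min(lo + 1, iso.n_proximal_ig)
    f_lo = chain_force_vec(hsl, iso, lo)
    if hi == lo or n_unfolded == lo:
        f = f_lo
    else:
        f_hi = chain_force_vec(hsl, iso, hi)
        w = n_unfolded - lo
        f = (1 - w) * f_lo + w * f_hi
    return f * spu * 1e-3


# -- fitting -----------------------------------------------------------------


def fit_region1(
    dataset: HysteresisDataset,
    *,
    isoform: Optional[TitinIsoform] = None,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-10,
) -> CalibrationResult:
    """Levenberg-Marquardt fit of the no-unfolding chain to region 1.

    Free parameters: folded-IG persistence length, PEVK persistence length
    and PEVK elastic modulus (all fitted in log space to stay positive).
    Multi-start (jittered initial guesses) guards against local minima.
    """
    iso = isoform if isoform is not None else default_isoform()
    sl, y = dataset.samples(1)
    keep = y > 0
    sl, y = sl[keep], y[keep]
    if sl.size < 9:
        raise CalibrationError(
            f"region 1 has {sl.size} usable samples; need >= 9 (3x the "
            "number of free parameters)"
        )
    spu = dataset.strands_per_um2

    def resid(theta):
        pl_f, pl_p, k0 = np.exp(theta)
        trial = replace(
            iso,
            folded_ig=replace(iso.folded_ig, persistence_length=pl_f),
            pevk=replace(
                iso.pevk, persistence_length=pl_p, elastic_modulus=k0
            ),
        )
        model = chain_force_vec(sl * 500.0, trial, 0) * spu * 1e-3
        return (model - y) / y

    x0 = np.log(
        [
            iso.folded_ig.persistence_length,
            iso.pevk.persistence_length,
            iso.pevk.elastic_modulus,
        ]
    )
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        start = x0 if k == 0 else x0 + rng.normal(0, 0.3, size=3)
        out = least_squares(
            resid, start, method="lm", gtol=gtol, xtol=1e-14, ftol=1e-14
        )
        if best is None or out.cost < best.cost:
            best = out
    if best is None or not best.success:
        raise CalibrationError(
            f"region-1 fit did not converge: {getattr(best, 'message', 'no fit')}"
        )
    pl_f, pl_p, k0 = np.exp(best.x)
    ses = _standard_errors(best)
    return CalibrationResult(
        folded_pl=float(pl_f),
        pevk_pl=float(pl_p),
        pevk_k0=float(k0),
        standard_errors={
            "folded_pl_rel": ses[0],
            "pevk_pl_rel": ses[1],
            "pevk_k0_rel": ses[2],
        },
        residual_norms={"region1_rms_rel": float(np.sqrt(np.mean(best.fun**2)))},
    )


def fit_region4(
    dataset: HysteresisDataset,
    region1_result: CalibrationResult,
    *,
    isoform: Optional[TitinIsoform] = None,
) -> CalibrationResult:
    """Exhaustive integer scan for the unfolded-domain count.

    For every candidate count in [0, N_prox] the unfolded-IG persistence
    length is fitted by inner least squares on the region-4 samples (with
    the region-1 parameters held fixed); the candidate with the globally
    smallest residual wins.
    """
    iso = isoform if isoform is not None else default_isoform()
    iso = region1_result.apply_to(iso)
    sl, y = dataset.samples(4)
    keep = y > 0
    sl, y = sl[keep], y[keep]
    if sl.size < 3:
        raise CalibrationError("region 4 has too few samples to fit")
    spu = dataset.strands_per_um2
    n_max = iso.n_proximal_ig

    scan = np.full(n_max + 1, np.inf)
    pls = np.full(n_max + 1, np.nan)
    for k in range(n_max + 1):
        if k == 0:
            model = chain_force_vec(sl * 500.0, iso, 0) * spu * 1e-3
            scan[0] = float(np.sum(((model - y) / y) ** 2))
            continue

        def resid(theta, k=k):
            trial = replace(
                iso,
                unfolded_ig=replace(
                    iso.unfolded_ig, persistence_length=float(np.exp(theta[0]))
                ),
            )
            model = chain_force_vec(sl * 500.0, trial, k) * spu * 1e-3
            return (model - y) / y

        out = least_squares(
            resid,
            np.array([np.log(iso.unfolded_ig.persistence_length)]),
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
        )
        scan[k] = float(np.sum(out.fun**2))
        pls[k] = float(np.exp(out.x[0]))

    k_best = int(np.argmin(scan))
    result = dataclasses.replace(
        region1_result,
        n_unfolded=k_best,
        unfolded_pl=float(pls[k_best]) if k_best > 0 else np.nan,
        region4_scan=scan,
    )
    result.residual_norms = dict(region1_result.residual_norms)
    result.residual_norms["region4_sse_rel"] = float(scan[k_best])
    return result


def _standard_errors(out) -> list:
    """Relative standard errors from the Jacobian at the optimum."""
    try:
        jtj = out.jac.T @ out.jac
        dof = max(out.fun.size - out.x.size, 1)
        sigma2 = 2 * out.cost / dof
        cov = sigma2 * np.linalg.inv(jtj)
        return [float(np.sqrt(v)) for v in np.diag(cov)]
    except np.linalg.LinAlgError:
        return [np.nan] * out.x.size


# -- synthetic data ----------------------------------------------------------


@dataclass(frozen=True)
class SynthesisTruth:
    """Ground truth of a synthetic loop, for recovery testing."""

    isoform: TitinIsoform
    n_unfolded_final: int
    breakpoint_index: int  # last stretch sample with no unfolding
    onset_force: float


def synthesize_hysteresis(
    isoform: Optional[TitinIsoform] = None,
    *,
    sl_start: float = 2.4,
    sl_max: float = 5.0,
    n_samples: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    mode: str = "deterministic",
    n_unfold_final: Optional[int] = None,
    onset_force: float = 150.0,
    force_increment: float = 2.0,
    unfolding: Optional[UnfoldingParams] = None,
    ensemble: Optional[EnsembleConfig] = None,
    speed_nm_per_s: float = 100.0,
):
    """Generate a passive stretch-shorten loop with known ground truth.

    ``deterministic`` mode unfolds domain i when the chain force first
    exceeds ``onset_force + i * force_increment`` (optionally capped at
    ``n_unfold_final`` domains), which makes region boundaries and the
    final composition exact; ``mc`` mode runs the full Monte-Carlo
    ensemble via :func:`~trifilament.unfolding.ensemble_trace` and takes
    the ensemble-mean stress.  Multiplicative Gaussian noise of relative
    width ``noise_sd`` is applied; deterministic given ``seed``.

    Returns ``(HysteresisDataset, SynthesisTruth)``.
    """
    iso = isoform if isoform is not None else default_isoform()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5E1F)))
    spu = (ensemble.strands_per_um2 if ensemble is not None else 500.0) * 1e-3
    n_up = n_samples // 2
    n_down = n_samples - n_up
    sl_up = np.linspace(sl_start, sl_max, n_up)
    sl_down = np.linspace(sl_max, sl_start, n_down)

    if mode == "deterministic":
        cap = n_unfold_final if n_unfold_final is not None else iso.n_proximal_ig
        thresholds = onset_force + force_increment * np.arange(iso.n_proximal_ig)
        n_u = 0
        stress_up = np.empty(n_up)
        breakpoint_index = 0
        for i, sl in enumerate(sl_up):
            f = float(chain_force_vec(sl * 500.0, iso, n_u)[0])
            while n_u < cap and f > thresholds[n_u]:
                n_u += 1
                f = float(chain_force_vec(sl * 500.0, iso, n_u)[0])
            if n_u == 0:
                breakpoint_index = i
            stress_up[i] = f * spu
        f_down = chain_force_vec(sl_down * 500.0, iso, n_u)
        stress_down = np.asarray(f_down) * spu
        final_nu = n_u
    elif mode == "mc":
        from .protocols import Protocol, Ramp, SetLength

        params = unfolding if unfolding is not None else UnfoldingParams()
        config = ensemble if ensemble is not None else EnsembleConfig(rng_seed=seed)
        proto = Protocol(
            "synth-loop",
            (
                SetLength(sl_start),
                Ramp(sl_max, speed_nm_per_s),
                Ramp(sl_start, speed_nm_per_s),
            ),
            titin_actin_binding=False,
        )
        trace = ensemble_trace(proto, iso, params, config)
        i_top = int(np.argmax(trace.hsl_nm))
        up = np.linspace(0, i_top, n_up).round().astype(int)
        down = np.linspace(i_top, trace.hsl_nm.size - 1, n_down).round().astype(int)
        sl_up = trace.hsl_nm[up] / 500.0
        sl_down = trace.hsl_nm[down] / 500.0
        stress_up = trace.stress_mean[up]
        stress_down = trace.stress_mean[down]
        final_nu = int(round(trace.mean_unfolded[-1]))
        nz = np.flatnonzero(trace.mean_unfolded[up] > 0.01)
        breakpoint_index = int(nz[0] - 1) if nz.size else n_up - 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    stress = np.concatenate([stress_up, stress_down])
    if noise_sd > 0:
        stress = stress * (1.0 + noise_sd * rng.standard_normal(stress.size))
    dataset = HysteresisDataset(
        sarcomere_um=np.concatenate([sl_up, sl_down]),
        stress=stress,
        phase=np.array(["stretch"] * n_up + ["shorten"] * n_down, dtype=object),
        strands_per_um2=spu * 1e3,
    )
    truth = SynthesisTruth(
        isoform=iso,
        n_unfolded_final=final_nu,
        breakpoint_index=int(breakpoint_index),
        onset_force=onset_force,
    )
    return dataset, truth
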