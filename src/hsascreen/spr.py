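"""Two-site ("heterogeneous ligand") SPR kinetics for HSA binding to
surface-immobilized amyloid-beta(1-40).

In SPR nomenclature the immobilized Abeta40 is the *ligand* and flowing HSA
the *analyte*. The chip surface carries two independent classes of Abeta40
sites; each binds HSA with its own association rate ``ka_i`` (M^-1 s^-1)
and dissociation rate ``kd_i`` (s^-1), giving equilibrium dissociation
constants ``KD_i = kd_i / ka_i``. Under constant analyte concentration C
(pseudo-first-order conditions) each class follows

    dR_i/dt = ka_i * C * (Rmax_i - R_i) - kd_i * R_i,

with the closed-form solution used throughout:

    association (0 <= t <= t_assoc):
        R_i(t) = Rmax_i * ka_i*C / (ka_i*C + kd_i) * (1 - exp(-(ka_i*C + kd_i)*t))
    dissociation (t > t_assoc):
        R_i(t) = R_i(t_assoc) * exp(-kd_i * (t - t_assoc))

and total response R(t) = R_1(t) + R_2(t) in resonance units (RU).

Fitting follows the per-concentration protocol: each sensorgram is fitted
separately by bounded nonlinear least squares over
(ka1, kd1, ka2, kd2, Rmax1, Rmax2), multi-started from a log-spaced grid of
initial rates; the per-concentration estimates are then averaged
arithmetically with standard deviations over concentrations. KD_i is
computed per fit and then averaged, so the averaged KD generally differs
from the ratio of the averaged rates.

Free energies use the water-standard-state convention
dG_i = -R*T*ln(55.3 / KD_i) with 55.3 M the molarity of water; fold
changes and delta-delta-G compare a ligand-treated condition with its
solvent-matched baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "Sensorgram",
    "FreeEnergyResult",
    "FitError",
    "GAS_CONSTANT_KJ",
    "WATER_MOLARITY",
    "DEFAULT_TEMPERATURE",
    "simulate_sensorgram",
    "fit_heterogeneous",
    "equilibrium_kd",
    "free_energy",
    "delta_delta_g",
    "fold_change",
    "round_fold",
    "baseline_correct",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
]

#: Gas constant, kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.314e-3
#: Molar concentration of water (standard state for the dG convention), M.
WATER_MOLARITY = 55.3
#: Assay temperature, K (25 degrees C).
DEFAULT_TEMPERATURE = 298.15


class FitError(RuntimeError):
    """No multi-start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-site model; site 1 is the higher-affinity
    class (KD1 <= KD2) under the canonical labelling.

    ``KD1``/``KD2`` default to kd_i/ka_i; fitted-and-averaged parameter sets
    carry explicitly averaged KD values instead (average of per-concentration
    ratios, which is not the ratio of averages). ``sd`` holds per-parameter
    standard deviations over concentrations, when available.
    """

    ka1: float
    kd1: float
    ka2: float
    kd2: float
    KD1: float | None = None
    KD2: float | None = None
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ka1", "kd1", "ka2", "kd2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.KD1 is None:
            object.__setattr__(self, "KD1", self.kd1 / self.ka1)
        if self.KD2 is None:
            object.__setattr__(self, "KD2", self.kd2 / self.ka2)

    def canonical(self) -> "KineticParams":
        """Relabel so that site 1 has the lower KD."""
        if self.KD1 <= self.KD2:
            return self
        swapped_sd = {
            {"1": k[:-1] + "2", "2": k[:-1] + "1"}.get(k[-1], k): v
            for k, v in self.sd.items()
        }
        return KineticParams(
            ka1=self.ka2, kd1=self.kd2, ka2=self.ka1, kd2=self.kd1,
            KD1=self.KD2, KD2=self.KD1, sd=swapped_sd,
        )

    def to_dict(self) -> dict:
        return {
            "ka1": self.ka1, "kd1": self.kd1, "KD1": self.KD1,
            "ka2": self.ka2, "kd2": self.kd2, "KD2": self.KD2,
            "sd": dict(self.sd),
        }


@dataclass
class Sensorgram:
    """One SPR trace: response (RU) vs time, with the analyte concentration
    and the association/dissociation phase boundary."""

    times: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    analyte_conc: float  # M
    t_assoc: float  # s; association on [0, t_assoc]
    rmax1: float | None = None  # RU, simulation input / fitted capacity
    rmax2: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-D array of >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.response.shape != self.times.shape:
            raise ValueError("response and times must have equal length")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response contains non-finite values")
        if not (self.times[0] <= self.t_assoc <= self.times[-1]):
            raise ValueError("t_assoc outside the time range")
        if self.analyte_conc < 0:
            raise ValueError("analyte concentration must be >= 0")


def _two_site_response(
    times: np.ndarray,
    ka1: float, kd1: float, ka2: float, kd2: float,
    rmax1: float, rmax2: float,
    conc: float, t_assoc: float,
) -> np.ndarray:
    total = np.zeros_like(times, dtype=float)
    assoc = times <= t_assoc
    for ka, kd, rmax in ((ka1, kd1, rmax1), (ka2, kd2, rmax2)):
        kobs = ka * conc + kd
        if kobs == 0.0:
            continue
        req = rmax * ka * conc / kobs
        r = np.empty_like(total)
        r[assoc] = req * (1.0 - np.exp(-kobs * times[assoc]))
        r_end = req * (1.0 - np.exp(-kobs * t_assoc))
        r[~assoc] = r_end * np.exp(-kd * (times[~assoc] - t_assoc))
        total += r
    return total


def simulate_sensorgram(
    kp: KineticParams,
    rmax1: float,
    rmax2: float,
    conc: float,
    times: np.ndarray,
    t_assoc: float,
) -> Sensorgram:
    """Noiseless two-site sensorgram from the closed-form solution."""
    if conc < 0:
        raise ValueError("analyte concentration must be >= 0")
    if rmax1 < 0 or rmax2 < 0:
        raise ValueError("Rmax values must be >= 0")
    times = np.asarray(times, dtype=float)
    resp = _two_site_response(
        times, kp.ka1, kp.kd1, kp.ka2, kp.kd2, rmax1, rmax2, conc, t_assoc
    )
    return Sensorgram(times, resp, conc, t_assoc, rmax1=rmax1, rmax2=rmax2)


# Multi-start grid of initial rates (log-spaced); kd1 <= kd2 starts only,
# since the label permutation is handled by canonical relabelling after fit.
_KA_STARTS = (1e2, 1e4)
_KD_STARTS = (1e-5, 1e-3, 1e-1)
_LOG_BOUNDS_LO = np.log10([1e-2, 1e-8, 1e-2, 1e-8, 1e-4, 1e-4])
_LOG_BOUNDS_HI = np.log10([1e8, 1e2, 1e8, 1e2, 1e6, 1e6])


def _fit_single(
    sg: Sensorgram,
    init: KineticParams | None,
    max_nfev: int = 2000,
) -> tuple[KineticParams, float, float, float]:
    """Fit one sensorgram; returns (params, rmax1, rmax2, cost)."""
    if sg.analyte_conc <= 0:
        raise ValueError("cannot fit a sensorgram with zero analyte concentration")
    rmax0 = max(float(np.max(sg.response)), 1e-3)

    def residual(logp: np.ndarray) -> np.ndarray:
        ka1, kd1, ka2, kd2, r1, r2 = 10.0 ** logp
        return (
            _two_site_response(
                sg.times, ka1, kd1, ka2, kd2, r1, r2, sg.analyte_conc, sg.t_assoc
            )
            - sg.response
        )

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(
            np.log10([init.ka1, init.kd1, init.ka2, init.kd2, rmax0, rmax0])
        )
    for ka1 in _KA_STARTS:
        for kd1 in _KD_STARTS:
            for ka2 in _KA_STARTS:
                for kd2 in _KD_STARTS:
                    if kd1 > kd2:
                        continue
                    starts.append(
                        np.log10([ka1, kd1, ka2, kd2, rmax0, rmax0])
                    )

    scale = float(np.sum(sg.response**2)) + 1e-12
    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(x0, _LOG_BOUNDS_LO, _LOG_BOUNDS_HI)
        try:
            res = least_squares(
                residual,
                x0,
                bounds=(_LOG_BOUNDS_LO, _LOG_BOUNDS_HI),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append((list(x0), repr(exc)))
            continue
        if best is None or res.cost < best.cost:
            best = res
        diagnostics.append((list(x0), float(res.cost)))
        if best.cost / scale < 1e-20:  # perfect fit; further starts are moot
            break
    if best is None:
        raise FitError("all multi-starts failed", diagnostics)
    ka1, kd1, ka2, kd2, r1, r2 = 10.0 ** best.x
    kp = KineticParams(ka1=ka1, kd1=kd1, ka2=ka2, kd2=kd2)
    # canonical site order: carry Rmax along with its site label
    if kp.KD1 > kp.KD2:
        kp = kp.canonical()
        r1, r2 = r2, r1
    return kp, float(r1), float(r2), float(best.cost)


def fit_heterogeneous(
    sensorgrams: Sequence[Sensorgram],
    init: KineticParams | None = None,
    global_fit: bool = False,
) -> tuple[KineticParams, list[KineticParams]]:
    """Fit the two-site model per concentration, then average.

    Returns ``(averaged, per_concentration)``. The averaged parameter set
    carries arithmetic means of the per-concentration rate and KD estimates
    with standard deviations over concentrations in ``.sd`` (ddof=1; zero
    for a single concentration). ``global_fit=True`` instead fits all
    sensorgrams simultaneously with shared rates (one parameter set, no
    averaging) -- a stricter estimator than the per-concentration protocol,
    provided for comparison.
    """
    sensorgrams = list(sensorgrams)
    if not sensorgrams:
        raise ValueError("need at least one sensorgram")
    if global_fit:
        kp = _fit_global(sensorgrams, init)
        return kp, [kp]
    per_conc: list[KineticParams] = []
    for sg in sensorgrams:
        kp, r1, r2, _ = _fit_single(sg, init)
        per_conc.append(kp)
    names = ("ka1", "kd1", "ka2", "kd2", "KD1", "KD2")
    means = {n: float(np.mean([getattr(k, n) for k in per_conc])) for n in names}
    sds = {
        n: (float(np.std([getattr(k, n) for k in per_conc], ddof=1))
            if len(per_conc) > 1 else 0.0)
        for n in names
    }
    averaged = KineticParams(
        ka1=means["ka1"], kd1=means["kd1"], ka2=means["ka2"], kd2=means["kd2"],
        KD1=means["KD1"], KD2=means["KD2"], sd=sds,
    )
    return averaged, per_conc


def _fit_global(
    sensorgrams: Sequence[Sensorgram], init: KineticParams | None
) -> KineticParams:
    """Shared-rate fit across all concentrations (per-curve Rmax pair)."""
    rmax0 = max(max(float(np.max(sg.response)) for sg in sensorgrams), 1e-3)
    n_sg = len(sensorgrams)

    def residual(logp: np.ndarray) -> np.ndarray:
        ka1, kd1, ka2, kd2 = 10.0 ** logp[:4]
        out = []
        for i, sg in enumerate(sensorgrams):
            r1, r2 = 10.0 ** logp[4 + 2 * i], 10.0 ** logp[5 + 2 * i]
            out.append(
                _two_site_response(
                    sg.times, ka1, kd1, ka2, kd2, r1, r2,
                    sg.analyte_conc, sg.t_assoc,
                )
                - sg.response
            )
        return np.concatenate(out)

    lo = np.concatenate([_LOG_BOUNDS_LO[:4], np.tile(_LOG_BOUNDS_LO[4:], n_sg)])
    hi = np.concatenate([_LOG_BOUNDS_HI[:4], np.tile(_LOG_BOUNDS_HI[4:], n_sg)])
    starts = []
    if init is not None:
        starts.append([init.ka1, init.kd1, init.ka2, init.kd2])
    starts += [
        [1e2, 1e-5, 1e2, 1e-3],
        [1e2, 1e-4, 1e3, 1e-2],
        [1e4, 1e-4, 1e4, 1e-2],
    ]
    best = None
    for s in starts:
        x0 = np.clip(
            np.concatenate([np.log10(s), np.tile(np.log10([rmax0, rmax0]), n_sg)]),
            lo, hi,
        )
        res = least_squares(residual, x0, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    ka1, kd1, ka2, kd2 = 10.0 ** best.x[:4]
    return KineticParams(ka1=ka1, kd1=kd1, ka2=ka2, kd2=kd2).canonical()


def equilibrium_kd(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd / ka, M."""
    if ka <= 0:
        raise ValueError("ka must be > 0")
    return kd / ka


@dataclass(frozen=True)
class FreeEnergyResult:
    dG1: float  # kJ/mol
    dG2: float  # kJ/mol
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KJ
    standard_state: float = WATER_MOLARITY


def free_energy(
    KD: float, temperature: float = DEFAULT_TEMPERATURE, unit: str = "kJ/mol"
) -> float:
    """Binding free energy dG = -R*T*ln(55.3/KD).

    Negative for favorable binding; zero exactly at KD = 55.3 M (the
    water-molarity standard state).
    """
    if KD <= 0:
        raise ValueError("KD must be > 0")
    dg = -GAS_CONSTANT_KJ * temperature * math.log(WATER_MOLARITY / KD)
    if unit == "kJ/mol":
        return dg
    if unit == "kcal/mol":
        return dg / 4.184
    raise ValueError(f"unknown unit {unit!r}")


def free_energies(
    kp: KineticParams, temperature: float = DEFAULT_TEMPERATURE
) -> FreeEnergyResult:
    return FreeEnergyResult(
        dG1=free_energy(kp.KD1, temperature),
        dG2=free_energy(kp.KD2, temperature),
        temperature=temperature,
    )


def delta_delta_g(
    kp_ligand: KineticParams,
    kp_baseline: KineticParams,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[float, float]:
    """Ligand-induced change in binding free energy per site, kJ/mol.

    ddG_i = dG_i(ligand) - dG_i(baseline) = R*T*ln(KD_i^ligand / KD_i^baseline);
    negative means the ligand favors HSA-Abeta binding at that site.
    """
    return (
        free_energy(kp_ligand.KD1, temperature) - free_energy(kp_baseline.KD1, temperature),
        free_energy(kp_ligand.KD2, temperature) - free_energy(kp_baseline.KD2, temperature),
    )


def fold_change(
    kp_ligand: KineticParams, kp_baseline: KineticParams
) -> tuple[tuple[float, str], tuple[float, str]]:
    """Per-site KD fold change vs baseline as (ratio >= 1, direction).

    Direction is "increase" when the ligand raises KD (weakens binding),
    "decrease" when it lowers KD, "unchanged" at equality. Rounding to
    whole folds is left to the presentation layer.
    """
    out = []
    for kd_l, kd_b in ((kp_ligand.KD1, kp_baseline.KD1), (kp_ligand.KD2, kp_baseline.KD2)):
        if kd_l == kd_b:
            out.append((1.0, "unchanged"))
        elif kd_l > kd_b:
            out.append((kd_l / kd_b, "increase"))
        else:
            out.append((kd_b / kd_l, "decrease"))
    return out[0], out[1]


def round_fold(ratio: float) -> int:
    """Present a fold change as a whole number, half away from zero."""
    return int(math.floor(ratio + 0.5))


def baseline_correct(
    sg: Sensorgram, blank: Sensorgram, interpolate: bool = False
) -> Sensorgram:
    """Subtract a blank (reference-channel) trace pointwise.

    With ``interpolate=False`` the time grids must match exactly; otherwise
    the blank is linearly interpolated onto the sensorgram's grid.
    """
    if blank.times.shape == sg.times.shape and np.array_equal(blank.times, sg.times):
        corr = sg.response - blank.response
    elif interpolate:
        corr = sg.response - np.interp(sg.times, blank.times, blank.response)
    else:
        raise ValueError("time grids differ; pass interpolate=True")
    return replace(sg, response=corr)


def write_sensorgram_csv(sg: Sensorgram, path: str | Path) -> None:
    """CSV (time_s, response_RU) plus a JSON sidecar with metadata."""
    path = Path(path)
    pd.DataFrame({"time_s": sg.times, "response_RU": sg.response}).to_csv(
        path, index=False
    )
    sidecar = {"conc_M": sg.analyte_conc, "t_assoc_s": sg.t_assoc}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sensorgram_csv(path: str | Path) -> Sensorgram:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Sensorgram(
        times=df["time_s"].to_numpy(),
        response=df["response_RU"].to_numpy(),
        analyte_conc=float(meta["conc_M"]),
        t_assoc=float(meta["t_assoc_s"]),
    )
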