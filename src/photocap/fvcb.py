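"""Farquhar–von Caemmerer–Berry (FvCB) model of C3 leaf photosynthesis and
estimation of Vcmax, Jmax and Rd from a single A/Ci curve.

Net assimilation is the minimum of two potential rates minus day respiration:

    Ac = Vcmax * (Ci - Γ*) / (Ci + Kc * (1 + O/Ko))     Rubisco-limited
    Aj = J     * (Ci - Γ*) / (4*Ci + 8*Γ*)              RuBP-regeneration-limited
    A  = min(Ac, Aj) - Rd

Curves are assumed to be measured at saturating light, so J = Jmax by
default; a non-rectangular-hyperbola light dependence is available but off.
Mesophyll conductance is treated as infinite (the model operates on Ci).

Fitting uses an explicit limitation partition: candidate transition points
are searched exhaustively over the observed Ci ladder; for each candidate
the points at or below it are assigned to the Rubisco-limited branch and
the rest to the RuBP branch, and (Vcmax, Jmax, Rd) are solved by bounded
linear least squares (both branch equations are linear in the parameters
once the partition is fixed).  The partition with the lowest total SSE
wins, with ties broken toward the larger Rubisco-limited segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear

from .thermal import GAS_CONSTANT_KJ, T_REF_K

__all__ = [
    "KineticConstants",
    "ACiCurve",
    "FvCBFit",
    "FitOptions",
    "BERNACCHI_25",
    "bernacchi_kinetics",
    "fvcb_forward",
    "fit_aci",
    "a_sat_from_curve",
    "read_curves_csv",
    "write_fits_csv",
    "InsufficientDataError",
]

O2_MMOL_MOL = 210.0  # atmospheric oxygen, mmol mol⁻¹


class InsufficientDataError(ValueError):
    """Raised when a curve has too few usable points to fit."""


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics at a given leaf temperature.

    kc (µmol mol⁻¹) and ko (mmol mol⁻¹) are the Michaelis constants for CO₂
    and O₂; gamma_star (µmol mol⁻¹) is the photorespiratory CO₂ compensation
    point; o (mmol mol⁻¹) is the oxygen mole fraction.
    """

    kc: float
    ko: float
    gamma_star: float
    o: float = O2_MMOL_MOL

    def __post_init__(self) -> None:
        if min(self.kc, self.ko, self.gamma_star, self.o) <= 0:
            raise ValueError("kinetic constants must all be positive")
        if self.gamma_star >= self.kc:
            raise ValueError("gamma_star must be below Kc")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), µmol mol⁻¹."""
        return self.kc * (1.0 + self.o / self.ko)


# 25°C values and activation energies (kJ mol⁻¹) of the standard
# Bernacchi-2001 temperature response, the de-facto default of A/Ci tools.
_KC25, _KC_HA = 404.9, 79.430
_KO25, _KO_HA = 278.4, 36.380
_GSTAR25, _GSTAR_HA = 42.75, 37.830

BERNACCHI_25 = KineticConstants(kc=_KC25, ko=_KO25, gamma_star=_GSTAR25)


def _arrh_scale(ha: float, tk: float) -> float:
    return float(np.exp(ha * (tk - T_REF_K) / (T_REF_K * GAS_CONSTANT_KJ * tk)))


def bernacchi_kinetics(tk: float = T_REF_K) -> KineticConstants:
    """Bernacchi-2001 Rubisco kinetics evaluated at leaf temperature ``tk`` (K)."""
    return KineticConstants(
        kc=_KC25 * _arrh_scale(_KC_HA, tk),
        ko=_KO25 * _arrh_scale(_KO_HA, tk),
        gamma_star=_GSTAR25 * _arrh_scale(_GSTAR_HA, tk),
    )


@dataclass
class ACiCurve:
    """One leaf's CO₂-response measurement sequence, in protocol order.

    ca, ci (µmol mol⁻¹) and a (µmol m⁻² s⁻¹) are parallel arrays; the
    repeated Ca = 380 stability-check step, if present, is kept in place.
    """

    leaf_id: str
    doy: int
    ca: np.ndarray
    ci: np.ndarray
    a: np.ndarray
    leaf_temperature: float = T_REF_K  # K
    ppfd: float = 1500.0  # µmol m⁻² s⁻¹

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (len(self.ca) == len(self.ci) == len(self.a)):
            raise ValueError(f"curve {self.leaf_id}: ragged point arrays")

    def __len__(self) -> int:
        return len(self.ci)

    def validate(self) -> list[str]:
        """Invariant violations as human-readable strings (empty when clean)."""
        out = []
        if len(self) < 5:
            out.append(f"curve {self.leaf_id}: fewer than 5 points ({len(self)})")
        if np.any(self.ci <= 0):
            out.append(f"curve {self.leaf_id}: nonpositive Ci")
        if not (273.0 <= self.leaf_temperature <= 323.0):
            out.append(
                f"curve {self.leaf_id}: leaf temperature {self.leaf_temperature} K "
                "outside [273, 323]"
            )
        return out


@dataclass
class FvCBFit:
    """Estimated FvCB parameters at the curve's leaf temperature, with diagnostics."""

    leaf_id: str
    doy: int
    vcmax: float
    jmax: float
    rd: float
    limitation_labels: list[str]  # per used point: "rubisco" | "rubp"
    rmse: float
    n_points_used: int
    converged: bool
    transition_ci: float
    leaf_temperature: float = T_REF_K


@dataclass(frozen=True)
class FitOptions:
    """Knobs of :func:`fit_aci`.

    use_duplicate_380
        Include the repeated Ca = 380 stability-check step in the fit
        (default False: it is a protocol check, not an independent step).
    trim_tpu
        Drop trailing high-CO₂ points (Ca ≥ tpu_ca_threshold) where A falls
        as Ci rises, a signature of triose-phosphate limitation that the
        two-branch model does not represent.
    rd_bounds
        Box constraint on day respiration, µmol m⁻² s⁻¹.
    """

    use_duplicate_380: bool = False
    trim_tpu: bool = False
    tpu_ca_threshold: float = 1000.0
    rd_bounds: tuple[float, float] = (0.0, 5.0)
    min_rubisco_points: int = 3
    min_rubp_points: int = 2


def fvcb_forward(vcmax, jmax, rd, ci, kinetics: KineticConstants):
    """Net assimilation A (µmol m⁻² s⁻¹) at intercellular CO₂ ``ci``.

    Vectorized over ``ci``.  Raises for nonpositive ``ci`` or parameters.
    """
    ci_arr = np.asarray(ci, dtype=float)
    if np.any(ci_arr <= 0):
        raise ValueError(f"ci must be positive, got {ci}")
    if min(vcmax, jmax) <= 0 or rd < 0:
        raise ValueError("vcmax and jmax must be positive, rd nonnegative")
    ac = vcmax * (ci_arr - kinetics.gamma_star) / (ci_arr + kinetics.km)
    aj = jmax * (ci_arr - kinetics.gamma_star) / (4.0 * ci_arr + 8.0 * kinetics.gamma_star)
    out = np.minimum(ac, aj) - rd
    return float(out) if np.isscalar(ci) or out.ndim == 0 else out


def _select_points(curve: ACiCurve, options: FitOptions) -> np.ndarray:
    """Boolean mask of points entering the fit."""
    keep = np.ones(len(curve), dtype=bool)
    if not options.use_duplicate_380:
        near380 = np.isclose(curve.ca, 380.0, atol=1.0)
        idx = np.flatnonzero(near380)
        if len(idx) > 1:
            keep[idx[1:]] = False
    if options.trim_tpu:
        order = np.argsort(curve.ci)
        a_sorted = curve.a[order]
        for pos in range(len(order) - 1, 0, -1):
            i = order[pos]
            if curve.ca[i] >= options.tpu_ca_threshold and a_sorted[pos] < a_sorted[pos - 1]:
                keep[i] = False
            else:
                break
    return keep


def fit_aci(
    curve: ACiCurve,
    kinetics: KineticConstants | None = None,
    options: FitOptions = FitOptions(),
) -> FvCBFit:
    """Estimate (Vcmax, Jmax, Rd) from one A/Ci curve.

    For every admissible transition on the observed Ci ladder the two branch
    equations are solved jointly by bounded linear least squares; the
    partition with the smallest SSE seeds a nonlinear refinement of the full
    min-rule model (the partition approximation is exact only away from the
    branch crossover and the compensation point, where the minimum switches
    branch regardless of the Ci ordering).  Rates are at the curve's leaf
    temperature.  Raises :class:`InsufficientDataError` when fewer than
    ``min_rubisco_points + min_rubp_points`` usable points remain.
    """
    if kinetics is None:
        kinetics = bernacchi_kinetics(curve.leaf_temperature)
    keep = _select_points(curve, options)
    ci = curve.ci[keep]
    a = curve.a[keep]
    n = len(ci)
    n_min = options.min_rubisco_points + options.min_rubp_points
    if n < n_min:
        raise InsufficientDataError(
            f"curve {curve.leaf_id}: {n} usable points, need at least {n_min}"
        )

    order = np.argsort(ci)
    ci_s, a_s = ci[order], a[order]
    xc = (ci_s - kinetics.gamma_star) / (ci_s + kinetics.km)
    xj = (ci_s - kinetics.gamma_star) / (4.0 * ci_s + 8.0 * kinetics.gamma_star)

    rd_lo, rd_hi = options.rd_bounds
    best = None  # (sse, -k, theta, k, ok)
    for k in range(options.min_rubisco_points, n - options.min_rubp_points + 1):
        design = np.zeros((n, 3))
        design[:k, 0] = xc[:k]
        design[k:, 1] = xj[k:]
        design[:, 2] = -1.0
        res = lsq_linear(
            design,
            a_s,
            bounds=([1e-9, 1e-9, rd_lo], [np.inf, np.inf, rd_hi]),
            method="bvls",
        )
        sse = float(np.sum((design @ res.x - a_s) ** 2))
        key = (round(sse, 12), -k)  # tie → larger Rubisco-limited segment
        if best is None or key < best[0]:
            best = (key, res.x, k, res.success)

    _, theta, k, ok = best

    # refine on the full min-rule model; the segmented solution is the seed
    def resid(p):
        ac = p[0] * (ci_s - kinetics.gamma_star) / (ci_s + kinetics.km)
        aj = p[1] * (ci_s - kinetics.gamma_star) / (4.0 * ci_s + 8.0 * kinetics.gamma_star)
        return np.minimum(ac, aj) - p[2] - a_s

    x0 = np.clip(theta, [1e-6, 1e-6, rd_lo], [np.inf, np.inf, rd_hi])
    nl = least_squares(
        resid,
        x0,
        bounds=([1e-6, 1e-6, rd_lo], [np.inf, np.inf, rd_hi]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    vcmax, jmax, rd = (float(v) for v in nl.x)
    pred = fvcb_forward(vcmax, jmax, rd, ci_s, kinetics)
    rmse = float(np.sqrt(np.mean((pred - a_s) ** 2)))
    # label each point by the limiting branch at the fitted parameters
    ac = vcmax * (ci_s - kinetics.gamma_star) / (ci_s + kinetics.km)
    aj = jmax * (ci_s - kinetics.gamma_star) / (4.0 * ci_s + 8.0 * kinetics.gamma_star)
    labels_sorted = ["rubisco" if a_c <= a_j else "rubp" for a_c, a_j in zip(ac, aj)]
    # map labels back to protocol order of the used points
    labels = [""] * n
    for pos, i in enumerate(order):
        labels[i] = labels_sorted[pos]
    converged = bool(ok and nl.success and np.isfinite(rmse) and vcmax > 0 and jmax > 0)
    return FvCBFit(
        leaf_id=curve.leaf_id,
        doy=curve.doy,
        vcmax=vcmax,
        jmax=jmax,
        rd=rd,
        limitation_labels=labels,
        rmse=rmse,
        n_points_used=n,
        converged=converged,
        transition_ci=float(ci_s[k - 1]),
        leaf_temperature=curve.leaf_temperature,
    )


def a_sat_from_curve(curve: ACiCurve, mode: str = "first") -> float:
    """Light-saturated net photosynthesis A_sat: the A reading at Ca = 380.

    ``mode="first"`` (default) returns the acclimated first 380 step;
    ``mode="mean"`` averages all 380 steps.  Raises when no 380 step exists.
    """
    idx = np.flatnonzero(np.isclose(curve.ca, 380.0, atol=1.0))
    if len(idx) == 0:
        raise ValueError(f"curve {curve.leaf_id}: no Ca = 380 step")
    if mode == "first":
        return float(curve.a[idx[0]])
    if mode == "mean":
        return float(np.mean(curve.a[idx]))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# tabular I/O

_DEFAULT_ALIASES = {
    "leaf_id": "leaf_id",
    "doy": "doy",
    "ca": "Ca_umol_mol",
    "ci": "Ci_umol_mol",
    "a": "A_umol_m2_s",
    "tleaf": "Tleaf_K",
    "ppfd": "PPFD_umol_m2_s",
}


def read_curves_csv(path, aliases: dict[str, str] | None = None) -> list[ACiCurve]:
    """Read a long-format curves table into per-leaf :class:`ACiCurve` records.

    ``aliases`` maps the canonical keys (leaf_id, doy, ca, ci, a, tleaf,
    ppfd) to the column names of the file, so Li-6400-style exports can be
    consumed by renaming only.
    """
    cols = dict(_DEFAULT_ALIASES)
    if aliases:
        cols.update(aliases)
    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    curves = []
    for leaf_id, grp in df.groupby(cols["leaf_id"], sort=False):
        curves.append(
            ACiCurve(
                leaf_id=str(leaf_id),
                doy=int(grp[cols["doy"]].iloc[0]),
                ca=grp[cols["ca"]].to_numpy(float),
                ci=grp[cols["ci"]].to_numpy(float),
                a=grp[cols["a"]].to_numpy(float),
                leaf_temperature=float(grp[cols["tleaf"]].iloc[0]),
                ppfd=float(grp[cols["ppfd"]].iloc[0]),
            )
        )
    return curves


def write_fits_csv(fits: list[FvCBFit], path) -> pd.DataFrame:
    """Write one row per fitted curve; returns the frame written."""
    df = pd.DataFrame(
        {
            "leaf_id": [f.leaf_id for f in fits],
            "doy": [f.doy for f in fits],
            "vcmax": [f.vcmax for f in fits],
            "jmax": [f.jmax for f in fits],
            "rd": [f.rd for f in fits],
            "rmse": [f.rmse for f in fits],
            "n_points_used": [f.n_points_used for f in fits],
            "converged": [f.converged for f in fits],
            "transition_ci": [f.transition_ci for f in fits],
            "leaf_temperature_K": [f.leaf_temperature for f in fits],
        }
    )
    from .pipeline import write_csv_stable

    write_csv_stable(df, path)
    return df
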