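"""Synthetic winter-wheat field season with known ground truth.

Emulates a single growing season sampled on 8 days of year (DOY 92–147,
n = 3–4 leaves per day, 29 leaves total) spanning the elongation, booting,
flowering and filling stages.  Every trait follows a piecewise-linear
seasonal trajectory that rises to a flowering-stage peak (DOY 126) and
declines during grain filling; within-day leaf-to-leaf variation is
lognormal (traits are strictly positive) with a configurable coefficient
of variation and a shared correlation structure, so that leaves with more
chlorophyll also tend to carry higher carboxylation capacity.

Chlorophyll is generated, by default, from the nitrogen trajectory via the
Chl_area/N_area ratio, which rises early in the season (≈0.23 at DOY 92,
0.32 at DOY 96) and then stabilizes near 0.36 — the hallmark of a constant
fraction of leaf N invested in light harvesting from booting onward.

Gas-exchange A/Ci curves are synthesized from each leaf's true capacities
with the forward FvCB model at the cuvette protocol (Ca ladder
380, 300, 200, 100, 50, 380, 600, 800, 1000, 1200 µmol mol⁻¹, PPFD 1500,
leaf acclimated at 25°C), a fixed Ci/Ca operating ratio, and additive
Gaussian instrument noise on A.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fvcb, thermal

__all__ = [
    "SeasonDesign",
    "TraitAnchors",
    "TraitTrajectoryConfig",
    "SyntheticLeafTruth",
    "PROTOCOL_CA",
    "TRAIT_ORDER",
    "build_default_design",
    "simulate_season",
    "simulate_aci_curve",
    "simulate_curves",
    "truths_to_frame",
    "curves_to_frame",
]

#: Cuvette ambient-CO₂ ladder (µmol mol⁻¹), including the repeated 380
#: stability-check step.
PROTOCOL_CA = (380.0, 300.0, 200.0, 100.0, 50.0, 380.0, 600.0, 800.0, 1000.0, 1200.0)

#: Day respiration temperature response: classical activation energy
#: 46.39 kJ mol⁻¹, with c chosen so the factor is exactly 1 at 25°C.
_RD_HA = 46.39
RD_ARRHENIUS = thermal.ArrheniusParams(
    c=_RD_HA / (thermal.GAS_CONSTANT_KJ * thermal.T_REF_K), delta_ha=_RD_HA
)


@dataclass(frozen=True)
class SeasonDesign:
    """Sampling design of one season: which DOYs, how many leaves, what stage."""

    doys: tuple[int, ...]
    sample_sizes: tuple[int, ...]
    stage_labels: tuple[str, ...]
    stage_boundaries: dict[str, int] = field(
        default_factory=lambda: {
            "Elongation": 95,
            "Booting": 117,
            "Flowering": 131,
            "Filling": 161,
        }
    )

    def __post_init__(self) -> None:
        if not (len(self.doys) == len(self.sample_sizes) == len(self.stage_labels)):
            raise ValueError("design rows must have equal length")
        if any(b <= a for a, b in zip(self.doys, self.doys[1:])):
            raise ValueError("doys must be strictly increasing")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        for doy, label in zip(self.doys, self.stage_labels):
            if self.stage_of(doy) != label:
                raise ValueError(f"DOY {doy} labelled {label} but boundaries say {self.stage_of(doy)}")

    def stage_of(self, doy: int) -> str:
        for stage, last in sorted(self.stage_boundaries.items(), key=lambda kv: kv[1]):
            if doy <= last:
                return stage
        raise ValueError(f"DOY {doy} beyond the last stage boundary")

    @property
    def total_leaves(self) -> int:
        return int(sum(self.sample_sizes))


def build_default_design() -> SeasonDesign:
    """The season actually sampled: 8 DOYs, 29 leaves, elongation→filling."""
    doys = (92, 96, 105, 119, 126, 133, 140, 147)
    sizes = (4, 4, 3, 3, 3, 4, 4, 4)
    design = SeasonDesign(
        doys=doys,
        sample_sizes=sizes,
        stage_labels=tuple(
            _stage_from_default_boundaries(d) for d in doys
        ),
    )
    return design


def _stage_from_default_boundaries(doy: int) -> str:
    for stage, last in (("Elongation", 95), ("Booting", 117), ("Flowering", 131), ("Filling", 161)):
        if doy <= last:
            return stage
    raise ValueError(doy)


@dataclass(frozen=True)
class TraitAnchors:
    """Seasonal trajectory of one trait: value at season start, at the
    flowering peak, and at season end, plus the within-DOY CV."""

    baseline: float
    peak: float
    end: float
    cv: float = 0.10

    def __post_init__(self) -> None:
        if min(self.baseline, self.peak, self.end) <= 0:
            raise ValueError("trajectory anchors must be positive")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")


#: Trait order of the within-DOY correlation matrix.
TRAIT_ORDER = ("vcmax25", "jmax25", "chl_area", "car_area", "n_area", "sla")

# Within-DOY (leaf-to-leaf) correlation of the lognormal deviations,
# calibrated together with the CVs and the trajectory amplitudes so that the
# season-pooled correlation structure reproduces the field pattern:
# corr(Vcmax25, Chl) ≈ 0.83 > corr(Vcmax25, Car) ≈ 0.68 > corr(Vcmax25, N)
# ≈ 0.60.  The pooled correlation mixes the shared seasonal trajectory
# (which alone would tie N almost perfectly to Vcmax, both peaking at
# flowering) with the within-day couplings; the weak direct V–N coupling
# plus a large N leaf-to-leaf CV is what brings the pooled V–N correlation
# down to its observed value.
_DEFAULT_COUPLING = np.array(
    [
        #  V     J     Chl   Car   N     SLA
        [1.00, 0.95, 0.72, 0.65, 0.15, -0.10],
        [0.95, 1.00, 0.68, 0.65, 0.15, -0.10],
        [0.72, 0.68, 1.00, 0.60, 0.55, -0.15],
        [0.65, 0.65, 0.60, 1.00, 0.45, -0.10],
        [0.15, 0.15, 0.55, 0.45, 1.00, -0.20],
        [-0.10, -0.10, -0.15, -0.10, -0.20, 1.00],
    ]
)


def _default_anchors() -> dict[str, TraitAnchors]:
    # Anchor magnitudes match the season's printed extremes: Vcmax25 peaks at
    # 133.46 µmol m⁻² s⁻¹ (62% above the DOY-92 mean, falling to 46 by DOY
    # 147); N_area peaks 26% above its DOY-92 mean and loses ~45% of the peak
    # by DOY 147; carotenoids rise 48% to the peak and change little after.
    return {
        "vcmax25": TraitAnchors(baseline=82.38, peak=133.46, end=46.02, cv=0.12),
        "jmax25": TraitAnchors(baseline=140.0, peak=226.9, end=78.2, cv=0.12),
        "chl_area": TraitAnchors(baseline=36.8, peak=72.6, end=39.7, cv=0.12),
        "car_area": TraitAnchors(baseline=9.0, peak=13.3, end=10.0, cv=0.09),
        "n_area": TraitAnchors(baseline=160.0, peak=201.6, end=110.2, cv=0.20),
    }


def ordered_coupling_config(rng_seed: int = 0) -> "TraitTrajectoryConfig":
    """A season whose trait→capacity coupling strengths are strictly ordered
    Chl > Car > N > SLA, with gaps wide enough to be resolved at the
    season's 29-leaf design.

    Chlorophyll's trajectory is made affine to Vcmax25's (the "capacity
    tracks chlorophyll" pattern at its cleanest), carotenoids and nitrogen
    co-move progressively less, and SLA is held flat with purely
    idiosyncratic variation, so its true association with capacity is nil.
    Used by ranking analyses that need a known importance ordering.
    """
    coupling = np.array(
        [
            #  V     J     Chl   Car   N    SLA
            [1.00, 0.95, 0.85, 0.75, 0.50, 0.0],
            [0.95, 1.00, 0.82, 0.75, 0.50, 0.0],
            [0.85, 0.82, 1.00, 0.60, 0.45, 0.0],
            [0.75, 0.75, 0.60, 1.00, 0.40, 0.0],
            [0.50, 0.50, 0.45, 0.40, 1.00, 0.0],
            [0.00, 0.00, 0.00, 0.00, 0.00, 1.0],
        ]
    )
    anchors = _default_anchors()
    anchors.update(
        {
            "chl_area": TraitAnchors(baseline=44.8, peak=72.6, end=25.0, cv=0.12),
            "car_area": TraitAnchors(baseline=9.0, peak=13.3, end=8.0, cv=0.10),
            "n_area": TraitAnchors(baseline=165.0, peak=200.0, end=125.0, cv=0.18),
        }
    )
    return TraitTrajectoryConfig(
        anchors=anchors,
        chl_mode="anchors",
        sla_start=200.0,
        sla_end=200.0,
        sla_cv=0.10,
        coupling=coupling,
        rng_seed=rng_seed,
    )


@dataclass
class TraitTrajectoryConfig:
    """Everything the season generator needs besides the sampling design.

    ``chl_mode="ratio"`` (default) derives the chlorophyll trajectory from
    the nitrogen trajectory times the Chl/N ratio curve (early anchors then
    a plateau at ``chl_to_n_plateau``); ``chl_mode="anchors"`` uses the
    chl_area anchors directly.
    """

    anchors: dict[str, TraitAnchors] = field(default_factory=_default_anchors)
    peak_doy: int = 126
    chl_to_n_plateau: float = 0.36
    chl_mode: str = "ratio"
    ratio_early_anchors: tuple[tuple[int, float], ...] = ((92, 0.23), (96, 0.32))
    ratio_plateau_start_doy: int = 105
    sla_start: float = 230.0  # cm² g⁻¹, declines as leaves thicken/senesce
    sla_end: float = 160.0
    sla_cv: float = 0.08
    rd_frac_of_vcmax: float = 0.015
    leaf_temperature_k: float = thermal.T_REF_K
    coupling: np.ndarray = field(default_factory=lambda: _DEFAULT_COUPLING.copy())
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "chl_area", "car_area", "n_area"):
            if name not in self.anchors:
                raise ValueError(f"missing anchors for trait {name}")
        if self.chl_to_n_plateau <= 0:
            raise ValueError("chl_to_n_plateau must be positive")
        if min(self.sla_start, self.sla_end) <= 0 or self.sla_cv < 0:
            raise ValueError("SLA settings must be positive (cv nonnegative)")
        if not 0 < self.rd_frac_of_vcmax < 0.2:
            raise ValueError("rd_frac_of_vcmax outside a plausible range")
        c = np.asarray(self.coupling, dtype=float)
        if c.shape != (len(TRAIT_ORDER), len(TRAIT_ORDER)):
            raise ValueError("coupling matrix has wrong shape")
        if not np.allclose(c, c.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("coupling matrix must be positive semidefinite")
        self.coupling = c


@dataclass
class SyntheticLeafTruth:
    """Ground truth for one synthetic leaf."""

    leaf_id: str
    doy: int
    stage: str
    vcmax25: float
    jmax25: float
    rd25: float
    n_area: float  # µg cm⁻²
    chl_area: float  # µg cm⁻²
    car_area: float  # µg cm⁻²
    sla: float  # cm² g⁻¹
    leaf_temperature: float = thermal.T_REF_K  # K

    def __post_init__(self) -> None:
        vals = (self.vcmax25, self.jmax25, self.rd25, self.n_area, self.chl_area, self.car_area, self.sla)
        if min(vals) <= 0:
            raise ValueError(f"leaf {self.leaf_id}: nonpositive truth value")
        ratio = self.jmax25 / self.vcmax25
        if not 1.0 < ratio < 2.5:
            raise ValueError(f"leaf {self.leaf_id}: Jmax25/Vcmax25 = {ratio:.2f} outside (1, 2.5)")


def _trajectory(doy, first_doy, peak_doy, last_doy, anchors: TraitAnchors):
    """Piecewise-linear seasonal mean: rise to the peak, then decline."""
    return np.interp(
        doy,
        [first_doy, peak_doy, last_doy],
        [anchors.baseline, anchors.peak, anchors.end],
    )


def _ratio_trajectory(doy, cfg: TraitTrajectoryConfig):
    xs = [d for d, _ in cfg.ratio_early_anchors] + [cfg.ratio_plateau_start_doy]
    ys = [v for _, v in cfg.ratio_early_anchors] + [cfg.chl_to_n_plateau]
    return np.interp(doy, xs, ys)  # flat at the plateau beyond the last anchor


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_season(
    design: SeasonDesign, cfg: TraitTrajectoryConfig
) -> list[SyntheticLeafTruth]:
    """Draw one season of per-leaf ground truths.

    Within-DOY deviations are multivariate-lognormal: a correlated standard
    normal vector per leaf (Cholesky of the coupling matrix) scaled by each
    trait's log-sd and mean-corrected, so the per-DOY expectation equals the
    trajectory value exactly.  Deterministic given ``cfg.rng_seed``;
    per-leaf streams are derived by seed-sequence spawning keyed on the leaf
    index, so inserting a DOY does not reshuffle other leaves' draws.
    """
    first_doy, last_doy = design.doys[0], design.doys[-1]
    if not first_doy <= cfg.peak_doy <= last_doy:
        raise ValueError(f"peak DOY {cfg.peak_doy} outside the season")
    chol = np.linalg.cholesky(
        cfg.coupling + 1e-12 * np.eye(len(TRAIT_ORDER))
    )
    sigmas = np.array(
        [
            _sigma(cfg.anchors["vcmax25"].cv),
            _sigma(cfg.anchors["jmax25"].cv),
            _sigma(cfg.anchors["chl_area"].cv),
            _sigma(cfg.anchors["car_area"].cv),
            _sigma(cfg.anchors["n_area"].cv),
            _sigma(cfg.sla_cv),
        ]
    )
    truths: list[SyntheticLeafTruth] = []
    leaf_counter = 0
    for doy, n in zip(design.doys, design.sample_sizes):
        stage = design.stage_of(doy)
        means = {
            name: float(_trajectory(doy, first_doy, cfg.peak_doy, last_doy, cfg.anchors[name]))
            for name in ("vcmax25", "jmax25", "car_area", "n_area")
        }
        if cfg.chl_mode == "ratio":
            means["chl_area"] = float(_ratio_trajectory(doy, cfg)) * means["n_area"]
        elif cfg.chl_mode == "anchors":
            means["chl_area"] = float(
                _trajectory(doy, first_doy, cfg.peak_doy, last_doy, cfg.anchors["chl_area"])
            )
        else:
            raise ValueError(f"unknown chl_mode {cfg.chl_mode!r}")
        sla_mean = float(np.interp(doy, [first_doy, last_doy], [cfg.sla_start, cfg.sla_end]))
        for j in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.rng_seed) % (2**31), leaf_counter])
            )
            z = chol @ rng.standard_normal(len(TRAIT_ORDER))
            dev = np.exp(sigmas * z - 0.5 * sigmas**2)
            leaf_id = f"D{doy:03d}L{j + 1}"
            truths.append(
                SyntheticLeafTruth(
                    leaf_id=leaf_id,
                    doy=int(doy),
                    stage=stage,
                    vcmax25=means["vcmax25"] * dev[0],
                    jmax25=means["jmax25"] * dev[1],
                    chl_area=means["chl_area"] * dev[2],
                    car_area=means["car_area"] * dev[3],
                    n_area=means["n_area"] * dev[4],
                    sla=sla_mean * dev[5],
                    rd25=cfg.rd_frac_of_vcmax * means["vcmax25"] * dev[0],
                    leaf_temperature=cfg.leaf_temperature_k,
                )
            )
            leaf_counter += 1
    return truths


def simulate_aci_curve(
    truth: SyntheticLeafTruth,
    protocol=PROTOCOL_CA,
    noise_sd: float = 0.3,
    seed: int = 0,
    ci_ca_ratio: float = 0.7,
    ppfd: float = 1500.0,
) -> fvcb.ACiCurve:
    """Synthesize one A/Ci curve from a leaf's true capacities.

    Ci is derived from each Ca setpoint with a constant operating ratio
    (default 0.7, a typical C3 value); A comes from the forward FvCB model
    at the leaf temperature with Gaussian noise of sd ``noise_sd`` added.
    Protocol order, including the repeated 380 step, is preserved.
    """
    ca = np.asarray(protocol, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("Ca setpoints must be positive")
    if not 0 < ci_ca_ratio <= 1:
        raise ValueError("ci_ca_ratio must be in (0, 1]")
    tk = truth.leaf_temperature
    kin = fvcb.bernacchi_kinetics(tk)
    vcmax_t = thermal.project_from_25(truth.vcmax25, tk, thermal.VCMAX_ARRHENIUS)
    jmax_t = thermal.project_from_25(truth.jmax25, tk, thermal.JMAX_ARRHENIUS)
    rd_t = truth.rd25 * thermal.arrhenius_factor(tk, RD_ARRHENIUS)
    ci = ci_ca_ratio * ca
    a = fvcb.fvcb_forward(vcmax_t, jmax_t, rd_t, ci, kin)
    if noise_sd > 0:
        leaf_key = zlib.crc32(truth.leaf_id.encode())
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), leaf_key]))
        a = a + rng.normal(0.0, noise_sd, size=len(ca))
    return fvcb.ACiCurve(
        leaf_id=truth.leaf_id,
        doy=truth.doy,
        ca=ca,
        ci=ci,
        a=np.asarray(a, dtype=float),
        leaf_temperature=tk,
        ppfd=ppfd,
    )


def simulate_curves(
    truths: list[SyntheticLeafTruth],
    protocol=PROTOCOL_CA,
    noise_sd: float = 0.3,
    seed: int = 0,
    ci_ca_ratio: float = 0.7,
) -> list[fvcb.ACiCurve]:
    """A/Ci curves for a whole season; one noise stream per leaf."""
    return [
        simulate_aci_curve(t, protocol, noise_sd, seed + i, ci_ca_ratio)
        for i, t in enumerate(truths)
    ]


def truths_to_frame(truths: list[SyntheticLeafTruth]) -> pd.DataFrame:
    """Ground-truth table matching the on-disk truth CSV schema."""
    return pd.DataFrame(
        {
            "leaf_id": [t.leaf_id for t in truths],
            "doy": [t.doy for t in truths],
            "stage": [t.stage for t in truths],
            "vcmax25": [t.vcmax25 for t in truths],
            "jmax25": [t.jmax25 for t in truths],
            "rd25": [t.rd25 for t in truths],
            "n_area_ug_cm2": [t.n_area for t in truths],
            "chl_area_ug_cm2": [t.chl_area for t in truths],
            "car_area_ug_cm2": [t.car_area for t in truths],
            "sla_cm2_g": [t.sla for t in truths],
        }
    )


def curves_to_frame(curves: list[fvcb.ACiCurve], design: SeasonDesign | None = None) -> pd.DataFrame:
    """Long-format curve table matching the on-disk curves CSV schema."""
    rows = []
    for c in curves:
        stage = design.stage_of(c.doy) if design is not None else ""
        for k in range(len(c)):
            rows.append(
                (c.leaf_id, c.doy, stage, k, c.ca[k], c.ci[k], c.a[k], c.leaf_temperature, c.ppfd)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "leaf_id",
            "doy",
            "stage",
            "step_index",
            "Ca_umol_mol",
            "Ci_umol_mol",
            "A_umol_m2_s",
            "Tleaf_K",
            "PPFD_umol_m2_s",
        ],
    )
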