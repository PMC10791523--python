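"""Parameter containers for the myoblast-fusion agent-based model.

Units are fixed across the package: lengths in micrometres (μm), time in
minutes (except ``t_mtfuse`` which is conventionally quoted in days),
densities in nuclei per mm², speeds in μm·min⁻¹ and angular rates in
degrees·min⁻¹.  Validation raises :class:`ParameterError` naming the
offending field so configuration mistakes surface immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ParameterError",
    "MediaComposition",
    "BehaviourMetrics",
    "FusionParams",
    "MechanicsParams",
    "SimParams",
    "MINUTES_PER_DAY",
]

MINUTES_PER_DAY = 1440.0


class ParameterError(ValueError):
    """A parameter failed its invariant; the message names the field."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ParameterError(f"{field_name}: {message}")


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass(frozen=True)
class MediaComposition:
    """Differentiation-medium composition.

    alpha
        Fraction of the medium that is neuronal (N2B27) differentiation
        medium, in [0, 1].
    beta
        Serum concentration, percent by volume (>= 0; 0-10% in the trials
        this model emulates).
    """

    alpha: float = 0.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        _require(_finite(self.alpha) and 0.0 <= self.alpha <= 1.0,
                 "alpha", "neuronal-medium fraction must be in [0, 1]")
        _require(_finite(self.beta) and self.beta >= 0.0,
                 "beta", "serum percentage must be >= 0")


@dataclass(frozen=True)
class BehaviourMetrics:
    """Early-stage myoblast behaviour metrics (model inputs).

    s_mb_mean, s_mb_sd
        Mean and SD of per-cell myoblast speed S_mb (μm·min⁻¹).
    omega_mb_sd
        SD of angular velocity ω_mb (degrees·min⁻¹); drives per-step
        heading noise in the persistent random walk.
    p_rate
        Proliferation rate P, divisions·cell⁻¹·min⁻¹.
    direction_mean, persistence
        Optional diagnostics when measured from tracks: circular mean
        direction of motion (degrees) and net-displacement / path-length.
    """

    s_mb_mean: float = 0.5
    s_mb_sd: float = 0.2
    omega_mb_sd: float = 10.0
    p_rate: float = 2e-4
    direction_mean: float | None = None
    persistence: float | None = None

    def __post_init__(self) -> None:
        _require(_finite(self.s_mb_mean) and self.s_mb_mean >= 0.0,
                 "s_mb_mean", "speed must be >= 0")
        _require(_finite(self.s_mb_sd) and self.s_mb_sd >= 0.0,
                 "s_mb_sd", "speed SD must be >= 0")
        _require(_finite(self.omega_mb_sd) and self.omega_mb_sd >= 0.0,
                 "omega_mb_sd", "angular-velocity SD must be >= 0")
        _require(_finite(self.p_rate) and self.p_rate >= 0.0,
                 "p_rate", "proliferation rate must be >= 0")
        if self.persistence is not None:
            _require(0.0 <= self.persistence <= 1.0,
                     "persistence", "must be in [0, 1]")


@dataclass(frozen=True)
class FusionParams:
    """Residence-time fusion parameters.

    aoi_radius
        Radius (μm) of the circular area of influence (AoI) around each
        nucleus; contact inside the AoI starts the residence clock.
    t_rmax
        Residence-time threshold (minutes): cumulative uninterrupted
        contact required before fusion triggers.
    t_mtfuse
        Maximum myotube age (days) at which a tube may still initiate
        fusion with another myotube.
    allow_mb_mb_fusion
        Whether two myoblasts in sustained contact found a new
        two-nucleus myotube (needed for fusion to start when no tubes
        are seeded at day 0).
    """

    aoi_radius: float = 15.0
    t_rmax: float = 30.0
    t_mtfuse: float = 3.0
    allow_mb_mb_fusion: bool = True

    def __post_init__(self) -> None:
        _require(_finite(self.aoi_radius) and self.aoi_radius > 0.0,
                 "aoi_radius", "AoI radius must be > 0")
        _require(isinstance(self.t_rmax, (int, float))
                 and not math.isnan(self.t_rmax) and self.t_rmax > 0.0,
                 "t_rmax", "residence-time threshold must be > 0 "
                 "(+inf disables fusion)")
        _require(_finite(self.t_mtfuse) and self.t_mtfuse >= 0.0,
                 "t_mtfuse", "myotube fusion age threshold must be >= 0")

    @property
    def gamma(self) -> float:
        """Combined residence parameter γ = AoI area / t_rmax (μm²·min⁻¹)."""
        return math.pi * self.aoi_radius**2 / self.t_rmax

    @property
    def t_mtfuse_minutes(self) -> float:
        return self.t_mtfuse * MINUTES_PER_DAY


@dataclass(frozen=True)
class MechanicsParams:
    """Myonuclei force-balance coefficients (overdamped dynamics).

    k_lat
        Lateral spring coefficient (min⁻¹ at unit mobility): pulls a
        myonucleus perpendicularly toward its tube's major axis.
    k_nuc
        Repulsion coefficient (μm³·min⁻¹ equivalent at unit mobility) of
        the inverse-square pairwise myonuclei repulsion, projected onto
        the tube axis (lengthwise).
    min_separation
        Singularity guard (μm) for the inverse-square law.
    mobility
        Displacement per unit force per minute; fixed at 1 by
        convention so the k's absorb the mobility scale.
    """

    k_lat: float = 0.2
    k_nuc: float = 0.5
    min_separation: float = 1.0
    mobility: float = 1.0

    def __post_init__(self) -> None:
        _require(_finite(self.k_lat) and self.k_lat >= 0.0,
                 "k_lat", "lateral coefficient must be >= 0")
        _require(_finite(self.k_nuc) and self.k_nuc >= 0.0,
                 "k_nuc", "repulsion coefficient must be >= 0")
        _require(_finite(self.min_separation) and self.min_separation > 0.0,
                 "min_separation", "singularity guard must be > 0")
        _require(_finite(self.mobility) and self.mobility > 0.0,
                 "mobility", "mobility must be > 0")


@dataclass(frozen=True)
class SimParams:
    """Complete configuration of one simulation run.

    The domain is a periodic (toroidal) rectangle ``domain_width`` ×
    ``domain_height`` μm.  ``dt`` defaults to 5 minutes, the live-imaging
    frame interval the behaviour metrics are defined at.
    """

    behaviour: BehaviourMetrics = field(default_factory=BehaviourMetrics)
    fusion: FusionParams = field(default_factory=FusionParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    media: MediaComposition = field(default_factory=MediaComposition)
    domain_width: float = 1000.0
    domain_height: float = 1000.0
    dt: float = 5.0
    duration: float = 5.0 * MINUTES_PER_DAY
    n_myoblasts_t0: int = 200
    myotube_proportion_t0: float = 0.0
    seed: int = 0
    record_every: float = 60.0  # minutes between density snapshots

    def __post_init__(self) -> None:
        _require(_finite(self.domain_width) and self.domain_width > 0.0,
                 "domain_width", "must be > 0")
        _require(_finite(self.domain_height) and self.domain_height > 0.0,
                 "domain_height", "must be > 0")
        _require(_finite(self.dt) and self.dt > 0.0, "dt", "must be > 0")
        _require(_finite(self.duration) and self.duration >= self.dt,
                 "duration", "must be >= dt")
        _require(isinstance(self.n_myoblasts_t0, int)
                 and self.n_myoblasts_t0 >= 0,
                 "n_myoblasts_t0", "must be a non-negative integer")
        _require(_finite(self.myotube_proportion_t0)
                 and 0.0 <= self.myotube_proportion_t0 <= 1.0,
                 "myotube_proportion_t0", "must be in [0, 1]")
        _require(self.behaviour.p_rate * self.dt < 1.0,
                 "p_rate", "p_rate * dt must be < 1 (per-step division "
                 "probability)")
        _require(_finite(self.record_every) and self.record_every > 0.0,
                 "record_every", "must be > 0")

    @property
    def area_mm2(self) -> float:
        return self.domain_width * self.domain_height / 1e6

    def with_inferred(self, *, t_rmax: float | None = None,
                      t_mtfuse: float | None = None,
                      k_lat: float | None = None,
                      k_nuc: float | None = None,
                      seed: int | None = None) -> "SimParams":
        """Copy with the ABC-inferred fields (and optionally seed) replaced."""
        fusion = replace(
            self.fusion,
            t_rmax=self.fusion.t_rmax if t_rmax is None else float(t_rmax),
            t_mtfuse=(self.fusion.t_mtfuse if t_mtfuse is None
                      else float(t_mtfuse)),
        )
        mech = replace(
            self.mechanics,
            k_lat=self.mechanics.k_lat if k_lat is None else float(k_lat),
            k_nuc=self.mechanics.k_nuc if k_nuc is None else float(k_nuc),
        )
        return replace(self, fusion=fusion, mechanics=mech,
                       seed=self.seed if seed is None else int(seed))
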