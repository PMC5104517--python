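"""Parameter containers for the monolayer simulator and imaging model.

All defaults describe a super-confluent, quiescent MDCK-like Fucci monolayer
on a biaxial stretcher: a 656 x 656 um field (~0.43 mm^2, one movie frame) at
~1000 cells/mm^2, imaged every 15 min at 0.65 um/px.  The cell-cycle defaults
are calibrated through steady-state relations so that the two baseline
observables of such a monolayer -- ~10% of cells Geminin-positive (S/G2) and
~1 division/hour/0.1 mm^2 -- follow analytically from a basal S-entry flux of
~0.01 per cell per hour and a 10 h S/G2 dwell time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class CycleParams:
    """Two-threshold beta-catenin activity model of cell-cycle progression.

    Each cell carries a scalar activity ``A`` (a beta-catenin transcriptional
    activity proxy).  G1->S requires ``A >= theta1``; mitotic entry from G2 is
    a graded hazard ``mitotic_rate * A / theta2`` that is only open for
    ``A >= theta2``.  Strain and Wnt/CKI-inhibition multiply activity through
    independent arms; iCRT3 forces it to zero.

    Attributes
    ----------
    basal_exit_rate : float
        Spontaneous G0->G1 hazard (1/h) per quiescent cell.  0.014/h yields a
        per-total-cell S-entry flux of ~0.01/h once the steady-state G0
        fraction (~0.72) is accounted for.
    strain_exit_rate : float
        Additional G0->G1 hazard (1/h) while strain is applied (Yap1 arm).
    g1_mean_h, g1_shape : float, int
        Erlang-distributed G1 transit time (mean, shape).
    s_duration_h : float
        Fixed S-phase duration (h).
    mitotic_rate : float
        G2->M hazard (1/h) at ``A == theta2``; scales linearly with ``A``.
    requiescence_rate : float
        Hazard (1/h) for a G1 cell whose timer has elapsed but whose gate is
        closed (A < theta1, or an unlicensed daughter) to return to G0.
    theta1, theta2 : float
        Lower (G1->S) and upper (G2->M) activity thresholds.
    activity_median, activity_sigma : float
        Log-normal intrinsic activity: ``ln A0 ~ N(ln median, sigma)``.
        Basal-trigger cells resample from the tail above ``theta2`` (only
        high-activity cells complete spontaneous cycles); strain-induced
        entrants draw from the full distribution and mostly land between the
        thresholds once strain multiplies their activity.
    beta_strain, beta_wnt : float
        Fractional activity increments of the strain (delayed, sigmoidal) and
        Wnt3A / D4476 (immediate) arms.
    strain_delay_h, strain_rise_h : float
        Centre (after strain onset) and width of the logistic activity rise;
        6 h delay reproduces S entries 6-8 h after strain.
    red_max, red_production_rate, red_decay_halflife_h : float
        mKO2-Cdt1 kinetics: produced in G0/G1 (relaxation towards red_max),
        degraded exponentially in S/G2 with a 1 h half-life.
    green_rate, green_cap : float
        mAG-Geminin accumulates linearly from S entry (a.u./h) up to a
        saturation level, and collapses to zero at mitosis.
    jitter_um : float
        RMS Brownian nuclear displacement per 15-min frame (um).
    division_separation_um : float
        Centre-to-centre distance of the two daughters at birth.
    """

    basal_exit_rate: float = 0.014
    strain_exit_rate: float = 0.02
    g1_mean_h: float = 6.0
    g1_shape: int = 4
    s_duration_h: float = 8.0
    mitotic_rate: float = 0.5
    requiescence_rate: float = 1.0
    theta1: float = 1.0
    theta2: float = 2.0
    activity_median: float = 0.3
    activity_sigma: float = 0.5
    beta_strain: float = 2.0
    beta_wnt: float = 9.0
    strain_delay_h: float = 6.0
    strain_rise_h: float = 0.75
    red_max: float = 100.0
    red_production_rate: float = 2.0
    red_decay_halflife_h: float = 1.0
    green_rate: float = 12.0
    green_cap: float = 200.0
    jitter_um: float = 0.3
    division_separation_um: float = 8.0
    #: excluded volume: nuclei closer than this are pushed apart (1.5 nuclear
    #: radii); prevents physically impossible overlapping nuclei
    min_separation_um: float = 6.0

    # steady-state calibration targets (per-total-cell basal S-entry flux and
    # S/G2 dwell); used when seeding an equilibrated movie-start state
    nominal_s_entry_flux: float = 0.01
    nominal_sg2_dwell_h: float = 10.0


@dataclass
class FieldParams:
    """Monolayer geometry and maturation settings."""

    width_um: float = 656.0
    height_um: float = 656.0
    density_per_mm2: float = 1000.0
    maturation_hours: float = 48.0
    #: fraction of plated cells still cycling at plating (trypsinized stock)
    plating_cycling_fraction: float = 0.05
    #: contact-inhibition half-point and steepness of the maturation-phase
    #: suppression of the basal G0-exit hazard, (rho_q / rho)^gamma
    quiescence_density_per_mm2: float = 750.0
    quiescence_exponent: float = 8.0
    #: positional jitter of the hexagonal packing (um)
    packing_jitter_um: float = 2.5

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass
class ImagingParams:
    """Image-formation model: Gaussian nuclear spots plus Poisson/read noise."""

    pixel_size_um: float = 0.65
    frame_interval_min: float = 15.0
    nucleus_radius_um: float = 4.0
    nuclear_amp: float = 300.0
    red_gain: float = 5.0
    green_gain: float = 5.0
    background: float = 100.0
    read_noise: float = 2.0
    shot_noise: bool = True
    bit_depth: int = 16

    @property
    def spot_sigma_px(self) -> float:
        # spot sigma = half the nuclear radius, in pixels
        return (self.nucleus_radius_um / 2.0) / self.pixel_size_um

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0


@dataclass
class SegmentationParams:
    """Nuclear segmentation recipe settings (smooth, background-subtract,
    Otsu, fill, watershed, size filter)."""

    smooth_sigma_px: float = 1.0
    background_radius_px: float = 25.0
    #: ~one nuclear radius at the default optics: closer seeds cannot be
    #: two distinct nuclei, while division daughters (two radii apart) split
    min_seed_separation_px: int = 6
    min_area_px: int = 10
    #: require the Otsu threshold to clear this many robust noise SDs,
    #: otherwise the frame is called empty
    min_foreground_snr: float = 4.0


@dataclass
class TrackingParams:
    max_displacement_um: float = 1.5
    max_gap_frames: int = 1
    split_radius_um: float = 6.0
    split_window_frames: int = 2


@dataclass
class EventParams:
    #: hysteresis thresholds on green/(green+red) of background-subtracted means
    on_ratio: float = 0.6
    off_ratio: float = 0.4
    #: raw mean-intensity threshold calling a nucleus Geminin-positive
    green_positive_threshold: float = 120.0
    bin_hours: float = 1.0


@dataclass
class Config:
    """Resolved run configuration; serializable to/from YAML."""

    cycle: CycleParams = field(default_factory=CycleParams)
    field_: FieldParams = field(default_factory=FieldParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    events: EventParams = field(default_factory=EventParams)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sections = {
            "cycle": CycleParams,
            "field_": FieldParams,
            "imaging": ImagingParams,
            "segmentation": SegmentationParams,
            "tracking": TrackingParams,
            "events": EventParams,
        }
        kwargs = {}
        for name, klass in sections.items():
            data = raw.get(name, {})
            kwargs[name] = klass(**data)
        return cls(**kwargs)
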