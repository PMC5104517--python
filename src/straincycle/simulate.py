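"""Stochastic cell-cycle simulator for quiescent epithelial monolayers.

The model is an agent-based state machine over {G0, G1, S, G2, M} driven by a
per-cell scalar ``A`` standing in for beta-catenin transcriptional activity.
Two thresholds grade the response: a lower one (``theta1``) gates the G1->S
transition, a higher one (``theta2``) gates and scales mitotic entry.  This
reproduces the four monolayer phenotypes:

* control -- a small basal flux of high-activity cells cycles continuously,
  holding ~10% of cells in S/G2 and ~1 division/h/0.1 mm^2;
* strain -- extra G0 exits (Yap arm) plus a delayed, sigmoidal activity rise
  push cells over ``theta1`` but usually not ``theta2``: S/G2 accumulates
  without extra divisions;
* Wnt3A or D4476 -- an immediate activity increment clears ``theta2`` for the
  standing S/G2 pool (an early transient burst of mitoses) but cannot license
  quiescence exit on its own;
* strain + Wnt3A/D4476 -- both arms combine and induced entrants complete the
  cycle, producing a sustained rise in divisions; iCRT3 zeroes activity and
  abolishes every activity-dependent response.

Mitosis is instantaneous: the parent is replaced by two adjacent daughters in
G1 with red fluorescence restored.  Daughters are unlicensed (contact
inhibition) and return to G0 after their G1 transit.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .params import CycleParams, FieldParams

__all__ = [
    "CellState",
    "Condition",
    "MonolayerState",
    "GroundTruthTable",
    "CONDITIONS",
    "condition_from_name",
    "initialize_quiescent_monolayer",
    "equilibrate_cycle",
    "advance_state",
    "apply_stretch",
    "simulate_bead_fixture",
]

PHASES = ("G0", "G1", "S", "G2", "M")


@dataclass
class CellState:
    """A single cell: position, cycle phase and Fucci fluorophore levels."""

    cell_id: int
    x: float
    y: float
    phase: str
    phase_entry_time: float
    trigger: Optional[str]  # "basal", "induced", "daughter" or None (G0)
    activity: float  # intrinsic A0 (>= 0)
    red_level: float
    green_level: float
    g1_duration: float = 0.0
    s_entry_time: Optional[float] = None


@dataclass(frozen=True)
class Condition:
    """Treatment regime applied to a monolayer movie."""

    strain_applied: bool = False
    strain_onset_time: float = 0.0
    wnt: bool = False
    cki_inhibited: bool = False  # D4476: same effect arm as Wnt3A
    icrt3: bool = False
    stretch_factor: float = 1.085

    def __post_init__(self):
        if self.stretch_factor < 1.0:
            raise ValueError("stretch_factor must be >= 1")


CONDITIONS = {
    "control": Condition(),
    "strain": Condition(strain_applied=True),
    "wnt": Condition(wnt=True),
    "strain-wnt": Condition(strain_applied=True, wnt=True),
    "d4476": Condition(cki_inhibited=True),
    "strain-d4476": Condition(strain_applied=True, cki_inhibited=True),
    "strain-d4476-icrt3": Condition(
        strain_applied=True, cki_inhibited=True, icrt3=True
    ),
}


def condition_from_name(name: str) -> Condition:
    try:
        return CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; choose from {sorted(CONDITIONS)}"
        ) from None


@dataclass
class MonolayerState:
    """Simulator ground truth at one instant."""

    time: float
    cells: list[CellState]
    field_size: tuple[float, float]
    rng: np.random.Generator
    params: CycleParams
    next_cell_id: int = 0
    #: (time_h, type, parent_id, daughter1_id, daughter2_id); for g1s_entry
    #: events parent_id holds the cell id and the daughter slots are -1
    events: list[tuple] = field(default_factory=list)

    def copy(self) -> "MonolayerState":
        new = MonolayerState(
            time=self.time,
            cells=[replace(c) for c in self.cells],
            field_size=self.field_size,
            rng=copy.deepcopy(self.rng),
            params=self.params,
            next_cell_id=self.next_cell_id,
            events=list(self.events),
        )
        return new

    def phase_fractions(self) -> dict[str, float]:
        n = len(self.cells)
        out = {p: 0.0 for p in PHASES}
        for c in self.cells:
            out[c.phase] += 1
        return {p: v / n for p, v in out.items()} if n else out


@dataclass
class GroundTruthTable:
    """Per-frame cell records and the cycle-event log of one simulated movie."""

    cells: pd.DataFrame  # frame, cell_id, x_um, y_um, phase, red, green
    events: pd.DataFrame  # time_h, type, parent_id, daughter1_id, daughter2_id

    def n_mitoses(self) -> int:
        return int((self.events["type"] == "mitosis").sum())

    def n_s_entries(self) -> int:
        return int((self.events["type"] == "g1s_entry").sum())


# ---------------------------------------------------------------------------
# activity model


def _sample_activity(rng: np.random.Generator, p: CycleParams, n: int) -> np.ndarray:
    """Intrinsic activities from the full log-normal."""
    return np.exp(np.log(p.activity_median) + p.activity_sigma * rng.standard_normal(n))


def _sample_tail_activity(rng: np.random.Generator, p: CycleParams, n: int) -> np.ndarray:
    """Activities conditioned on exceeding theta2 (basal-trigger cells).

    Inverse-CDF sampling of the log-normal upper tail; numerically this sits
    far out (several sigma), so values land just above theta2.
    """
    z0 = (np.log(p.theta2) - np.log(p.activity_median)) / p.activity_sigma
    lo = ndtr(z0)
    u = lo + (1.0 - lo) * rng.random(n)
    # guard against u == 1 rounding
    u = np.clip(u, lo, 1.0 - 1e-16)
    z = ndtri(u)
    return np.exp(np.log(p.activity_median) + p.activity_sigma * z)


def strain_activity_factor(t: float, condition: Condition, p: CycleParams) -> float:
    """Sigmoidal strain arm of the activity multiplier at time ``t``."""
    if not condition.strain_applied:
        return 0.0
    centre = condition.strain_onset_time + p.strain_delay_h
    return p.beta_strain / (1.0 + math.exp(-(t - centre) / p.strain_rise_h))


def effective_activity(a0: float, t: float, condition: Condition, p: CycleParams) -> float:
    """A_i(t) = A0 * (1 + strain arm + wnt arm); iCRT3 forces zero."""
    if condition.icrt3:
        return 0.0
    f = 1.0 + strain_activity_factor(t, condition, p)
    if condition.wnt or condition.cki_inhibited:
        f += p.beta_wnt
    return a0 * f


# ---------------------------------------------------------------------------
# initialization


def _hexagonal_positions(fp: FieldParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal packing at the requested density (positions in um)."""
    rho = fp.density_per_mm2 / 1e6  # cells / um^2
    spacing = math.sqrt(2.0 / (math.sqrt(3.0) * rho))
    row_pitch = spacing * math.sqrt(3.0) / 2.0
    pts = []
    y = row_pitch / 2.0
    row = 0
    while y < fp.height_um:
        x0 = spacing / 2.0 + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        while x < fp.width_um:
            pts.append((x, y))
            x += spacing
        y += row_pitch
        row += 1
    pts = np.asarray(pts, dtype=float)
    pts += rng.normal(0.0, fp.packing_jitter_um, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, fp.width_um)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, fp.height_um)
    return pts


def _stage_cycling_cell(
    cell: CellState, rng: np.random.Generator, p: CycleParams, t: float,
    phase: str | None = None,
) -> None:
    """Put ``cell`` at a uniformly random point of the basal cycle pipeline.

    Occupancy-weighted over G1 (Erlang transit), S (fixed) and G2
    (exponential at the basal mitotic hazard) unless ``phase`` pins the
    target phase; fluorophores are set consistently with the staged age.
    """
    tau_g2 = 1.0 / p.mitotic_rate  # basal cells sit just above theta2
    if phase is None:
        weights = np.array([p.g1_mean_h, p.s_duration_h, tau_g2])
        weights /= weights.sum()
        phase = rng.choice(["G1", "S", "G2"], p=weights)
    cell.trigger = "basal"
    cell.activity = float(_sample_tail_activity(rng, p, 1)[0])
    halflife = p.red_decay_halflife_h
    if phase == "G1":
        cell.phase = "G1"
        # stationary standing pool: length-biased transit duration
        # (gamma(k, theta) -> gamma(k + 1, theta)), age uniform given duration
        cell.g1_duration = float(
            rng.gamma(p.g1_shape + 1, p.g1_mean_h / p.g1_shape)
        )
        age = rng.random() * cell.g1_duration
        cell.phase_entry_time = t - age
        cell.red_level = p.red_max
        cell.green_level = 0.0
    elif phase == "S":
        age = rng.random() * p.s_duration_h
        cell.phase = "S"
        cell.phase_entry_time = t - age
        cell.s_entry_time = t - age
        cell.green_level = min(p.green_rate * age, p.green_cap)
        cell.red_level = p.red_max * 2.0 ** (-age / halflife)
    else:
        g2_age = min(float(rng.exponential(tau_g2)), 3.0 * tau_g2)
        cell.phase = "G2"
        cell.phase_entry_time = t - g2_age
        cell.s_entry_time = t - g2_age - p.s_duration_h
        total = p.s_duration_h + g2_age
        cell.green_level = min(p.green_rate * total, p.green_cap)
        cell.red_level = p.red_max * 2.0 ** (-total / halflife)


def initialize_quiescent_monolayer(
    field_size: tuple[float, float] | FieldParams = None,
    density_per_mm2: float = None,
    maturation_hours: float = None,
    seed: int = 0,
    params: CycleParams | None = None,
    field_params: FieldParams | None = None,
) -> MonolayerState:
    """Plate a monolayer and mature it into contact-inhibited quiescence.

    Cells are placed on a jittered hexagonal packing at the plating density.
    A small fraction is still cycling at plating; during the maturation phase
    the basal G0-exit hazard is suppressed by rising density (contact
    inhibition, ``(rho_q/rho)^gamma``), so cycling cells finish their cycle
    and re-quiesce.  After the default 48 h, >=95% of cells are in G0.

    Parameters may be given either through ``field_params`` or through the
    positional ``field_size`` / ``density_per_mm2`` / ``maturation_hours``
    shortcuts.  Deterministic given ``seed``.
    """
    fp = field_params or FieldParams()
    if isinstance(field_size, FieldParams):
        fp = field_size
    elif field_size is not None:
        fp = replace(fp, width_um=float(field_size[0]), height_um=float(field_size[1]))
    if density_per_mm2 is not None:
        fp = replace(fp, density_per_mm2=float(density_per_mm2))
    if maturation_hours is not None:
        fp = replace(fp, maturation_hours=float(maturation_hours))
    if fp.density_per_mm2 <= 0:
        raise ValueError(f"density must be positive, got {fp.density_per_mm2}")
    if fp.width_um <= 0 or fp.height_um <= 0:
        raise ValueError(f"field area must be positive, got {fp.width_um}x{fp.height_um}")
    p = params or CycleParams()
    rng = np.random.default_rng(seed)

    pts = _hexagonal_positions(fp, rng)
    cells = [
        CellState(
            cell_id=i,
            x=float(x),
            y=float(y),
            phase="G0",
            phase_entry_time=0.0,
            trigger=None,
            activity=float(a0),
            red_level=p.red_max,
            green_level=0.0,
        )
        for i, ((x, y), a0) in enumerate(zip(pts, _sample_activity(rng, p, len(pts))))
    ]
    state = MonolayerState(
        time=0.0,
        cells=cells,
        field_size=(fp.width_um, fp.height_um),
        rng=rng,
        params=p,
        next_cell_id=len(cells),
    )
    n_cycling = int(round(fp.plating_cycling_fraction * len(cells)))
    for idx in rng.choice(len(cells), size=n_cycling, replace=False):
        _stage_cycling_cell(cells[idx], rng, p, t=0.0)

    # maturation: density-suppressed basal hazard, no treatment, no jitter cost
    control = Condition()
    dt = 0.25
    steps = int(round(fp.maturation_hours / dt))
    area = fp.area_mm2
    for _ in range(steps):
        rho = len(state.cells) / area
        suppression = min(1.0, (fp.quiescence_density_per_mm2 / rho) ** fp.quiescence_exponent)
        advance_state(
            state, dt, control, basal_rate_override=p.basal_exit_rate * suppression
        )

    # reset the movie clock to zero
    shift = state.time
    state.time = 0.0
    for c in state.cells:
        c.phase_entry_time -= shift
        if c.s_entry_time is not None:
            c.s_entry_time -= shift
    state.events = []
    return state


def equilibrate_cycle(state: MonolayerState) -> MonolayerState:
    """Top the basal cycling pools up to their steady-state occupancy.

    A matured monolayer is deeply quiescent (>=95% G0); a monolayer under the
    microscope shows the basal-flux steady state (~6% G1, ~8% S, ~2% G2 at the
    nominal calibration).  This converts randomly chosen G0 cells into staged
    basal cyclers so that a movie opens at that steady state.  Mutates and
    returns ``state``.
    """
    p = state.params
    rng = state.rng
    n = len(state.cells)
    lam = p.nominal_s_entry_flux
    tau_g2 = 1.0 / p.mitotic_rate
    targets = {
        "G1": lam * p.g1_mean_h,
        "S": lam * p.s_duration_h,
        "G2": lam * tau_g2,
    }
    # count only licensed cyclers against the targets: unlicensed G1 cells
    # (re-quiescing daughters) do not feed the S-entry pipeline
    current = {ph: 0.0 for ph in targets}
    for c in state.cells:
        if c.phase in current and c.trigger in ("basal", "induced"):
            current[c.phase] += 1.0 / n
    deficits = {
        ph: max(0, int(round((targets[ph] - current[ph]) * n)))
        for ph in targets
    }
    g0_idx = np.array([i for i, c in enumerate(state.cells) if c.phase == "G0"])
    rng.shuffle(g0_idx)
    cursor = 0
    for ph, count in deficits.items():
        for _ in range(min(count, len(g0_idx) - cursor)):
            _stage_cycling_cell(state.cells[g0_idx[cursor]], rng, p, t=state.time, phase=ph)
            cursor += 1
    return state


# ---------------------------------------------------------------------------
# dynamics


def advance_state(
    state: MonolayerState,
    dt: float,
    condition: Condition,
    basal_rate_override: float | None = None,
) -> MonolayerState:
    """Advance the monolayer by ``dt`` hours under ``condition`` (in place).

    Transitions: G0->G1 at hazard ``basal + strain`` (Yap arm); G1->S once the
    Erlang timer has elapsed *and* the activity gate ``A >= theta1`` is open
    for a licensed (basal/induced) entrant -- unlicensed or sub-threshold
    cells re-quiesce at ``requiescence_rate``; S->G2 after the fixed S
    duration; G2->M at the graded hazard ``mitotic_rate * A/theta2`` above
    ``theta2``; M is instantaneous, replacing the parent with two daughters.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    rng = state.rng
    t = state.time
    t_next = t + dt
    h0 = p.basal_exit_rate if basal_rate_override is None else basal_rate_override
    hs = (
        p.strain_exit_rate
        if condition.strain_applied and t >= condition.strain_onset_time
        else 0.0
    )
    h_exit = h0 + hs
    p_exit = -math.expm1(-h_exit * dt) if h_exit > 0 else 0.0
    p_requiesce = -math.expm1(-p.requiescence_rate * dt)
    halflife = p.red_decay_halflife_h
    red_decay = 2.0 ** (-dt / halflife)
    red_relax = math.exp(-p.red_production_rate * dt)
    w, h = state.field_size
    jitter_sd = (p.jitter_um / math.sqrt(2.0)) * math.sqrt(dt / 0.25)

    new_cells: list[CellState] = []
    for cell in state.cells:
        a_eff = effective_activity(cell.activity, t, condition, p)
        divided = False
        if cell.phase == "G0":
            cell.red_level = p.red_max - (p.red_max - cell.red_level) * red_relax
            if p_exit > 0 and rng.random() < p_exit:
                basal_share = h0 / h_exit
                if rng.random() < basal_share:
                    cell.trigger = "basal"
                    cell.activity = float(_sample_tail_activity(rng, p, 1)[0])
                else:
                    cell.trigger = "induced"
                    cell.activity = float(_sample_activity(rng, p, 1)[0])
                cell.phase = "G1"
                cell.phase_entry_time = t_next
                cell.g1_duration = float(rng.gamma(p.g1_shape, p.g1_mean_h / p.g1_shape))
        elif cell.phase == "G1":
            cell.red_level = p.red_max - (p.red_max - cell.red_level) * red_relax
            age = t_next - cell.phase_entry_time
            if age >= cell.g1_duration:
                licensed = cell.trigger in ("basal", "induced")
                if licensed and a_eff >= p.theta1:
                    cell.phase = "S"
                    cell.phase_entry_time = t_next
                    cell.s_entry_time = t_next
                    state.events.append((t_next, "g1s_entry", cell.cell_id, -1, -1))
                elif rng.random() < p_requiesce:
                    cell.phase = "G0"
                    cell.phase_entry_time = t_next
                    cell.trigger = None
        elif cell.phase == "S":
            cell.red_level *= red_decay
            cell.green_level = min(cell.green_level + p.green_rate * dt, p.green_cap)
            if t_next - cell.phase_entry_time >= p.s_duration_h:
                cell.phase = "G2"
                cell.phase_entry_time = t_next
        elif cell.phase == "G2":
            cell.red_level *= red_decay
            cell.green_level = min(cell.green_level + p.green_rate * dt, p.green_cap)
            if a_eff >= p.theta2:
                hazard = p.mitotic_rate * a_eff / p.theta2
                if rng.random() < -math.expm1(-hazard * dt):
                    divided = True
        if divided:
            # instantaneous mitosis: parent -> two adjacent daughters in G1
            angle = rng.random() * 2.0 * math.pi
            half = p.division_separation_um / 2.0
            dx, dy = half * math.cos(angle), half * math.sin(angle)
            daughters = []
            for sx, sy in ((dx, dy), (-dx, -dy)):
                d = CellState(
                    cell_id=state.next_cell_id,
                    x=float(np.clip(cell.x + sx, 0.0, w)),
                    y=float(np.clip(cell.y + sy, 0.0, h)),
                    phase="G1",
                    phase_entry_time=t_next,
                    trigger="daughter",
                    activity=float(_sample_activity(rng, p, 1)[0]),
                    red_level=p.red_max,
                    green_level=0.0,
                    g1_duration=float(rng.gamma(p.g1_shape, p.g1_mean_h / p.g1_shape)),
                )
                state.next_cell_id += 1
                daughters.append(d)
            state.events.append(
                (t_next, "mitosis", cell.cell_id, daughters[0].cell_id, daughters[1].cell_id)
            )
            new_cells.extend(daughters)
        else:
            new_cells.append(cell)

    if p.jitter_um > 0:
        steps = rng.normal(0.0, jitter_sd, size=(len(new_cells), 2))
        for cell, (sx, sy) in zip(new_cells, steps):
            cell.x = float(np.clip(cell.x + sx, 0.0, w))
            cell.y = float(np.clip(cell.y + sy, 0.0, h))
    if p.min_separation_um > 0:
        _resolve_overlaps(new_cells, p.min_separation_um, (w, h))

    state.cells = new_cells
    state.time = t_next
    return state


def _resolve_overlaps(
    cells: list[CellState], min_sep: float, field: tuple[float, float]
) -> None:
    """Excluded volume: push cell pairs closer than ``min_sep`` apart.

    One symmetric relaxation pass per step; the slow dynamics make a single
    pass sufficient to keep nuclei from interpenetrating.
    """
    if len(cells) < 2:
        return
    from scipy.spatial import cKDTree

    pts = np.array([(c.x, c.y) for c in cells])
    pairs = cKDTree(pts).query_pairs(min_sep, output_type="ndarray")
    if len(pairs) == 0:
        return
    w, h = field
    for i, j in pairs:
        dx = pts[j, 0] - pts[i, 0]
        dy = pts[j, 1] - pts[i, 1]
        d = math.hypot(dx, dy)
        if d < 1e-9:
            dx, dy, d = 1.0, 0.0, 1.0  # coincident: arbitrary fixed axis
        push = 0.5 * (min_sep - d) / d
        cells[i].x = float(np.clip(cells[i].x - push * dx, 0.0, w))
        cells[i].y = float(np.clip(cells[i].y - push * dy, 0.0, h))
        cells[j].x = float(np.clip(cells[j].x + push * dx, 0.0, w))
        cells[j].y = float(np.clip(cells[j].y + push * dy, 0.0, h))


def apply_stretch(state: MonolayerState, stretch_factor: float) -> MonolayerState:
    """Equi-biaxial stretch: scale positions about the field centre (in place).

    All pairwise distances are multiplied by exactly ``stretch_factor``; the
    field rectangle scales identically.
    """
    if stretch_factor < 1.0:
        raise ValueError(f"stretch_factor must be >= 1, got {stretch_factor}")
    w, h = state.field_size
    cx, cy = w / 2.0, h / 2.0
    for c in state.cells:
        c.x = cx * stretch_factor + (c.x - cx) * stretch_factor
        c.y = cy * stretch_factor + (c.y - cy) * stretch_factor
    # equivalently: new = factor * old (scaling about the origin-anchored
    # centre keeps positions inside the scaled field)
    state.field_size = (w * stretch_factor, h * stretch_factor)
    return state


# ---------------------------------------------------------------------------
# bead calibration fixture


def simulate_bead_fixture(
    n_beads: int,
    stretch_factor: float,
    localization_noise_px: float,
    seed: int,
    field_um: tuple[float, float] = (656.0, 656.0),
    pixel_size_um: float = 0.65,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched fiducial-bead positions before/after an equi-biaxial stretch.

    Beads are scattered uniformly over the field; post positions are the pre
    positions scaled about the field centre, with each coordinate perturbed
    by Gaussian localization noise of ``localization_noise_px`` pixels.
    Returns ``(pre, post)`` as (n, 2) arrays in um, in matched order.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads for a similarity fit")
    rng = np.random.default_rng(seed)
    w, h = field_um
    pre = rng.random((n_beads, 2)) * np.array([w, h])
    centre = np.array([w / 2.0, h / 2.0])
    post = centre + stretch_factor * (pre - centre)
    if localization_noise_px > 0:
        post = post + rng.normal(
            0.0, localization_noise_px * pixel_size_um, size=post.shape
        )
    return pre, post


# ---------------------------------------------------------------------------
# ground-truth assembly (used by the time-lapse driver)


def ground_truth_row(frame: int, cell: CellState) -> tuple:
    return (
        frame,
        cell.cell_id,
        cell.x,
        cell.y,
        cell.phase,
        cell.red_level,
        cell.green_level,
        cell.trigger or "",
    )


GT_COLUMNS = ["frame", "cell_id", "x_um", "y_um", "phase", "red", "green", "trigger"]
EVENT_COLUMNS = ["time_h", "type", "parent_id", "daughter1_id", "daughter2_id"]


def build_ground_truth(rows: list[tuple], events: list[tuple]) -> GroundTruthTable:
    cells = pd.DataFrame(rows, columns=GT_COLUMNS)
    ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return GroundTruthTable(cells=cells, events=ev)
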