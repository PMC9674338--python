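"""Ball-and-stick starburst amacrine cell model with moving-bar input.

An isolated SAC dendritic computational unit: one somatic compartment and
three passive dendritic sections (initial, middle, terminal), driven by
bipolar-cell synapses whose vesicle trains are Poisson-discretized
release-rate profiles.  Proximal synapses carry sustained release
kinetics, distal synapses transient kinetics (the "space-time wiring"
arrangement).  A simulated 400-µm bar sweeps the dendrite at 0.1–2 mm/s,
activating each synapse while the bar overlaps its 60-µm receptive field;
each released vesicle opens a fast AMPA-like conductance (0.14/0.54 ms,
0 mV reversal) whose peak is scaled linearly from 172.2 pS (proximal) to
68.6 pS (distal).  Direction selectivity is read out from the peak
terminal Ca²⁺ signal as DSi = centrifugal − centripetal (subtraction
mode; a normalized (CF−CP)/(CF+CP) index is also provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._cable import integrate
from .release import _biexp_peak_time
from .synth import ReleaseProfileSpec

__all__ = [
    "Section",
    "Morphology",
    "PassiveParams",
    "CaParams",
    "SynapseKinetics",
    "TruncatedGaussian",
    "BarStimulus",
    "Synapse",
    "SACModel",
    "SimResult",
    "sample_synapse_locations",
    "conductance_scale",
    "schedule_activation",
    "build_release_for_speed",
    "build_roster",
    "simulate",
    "inject_current",
    "compute_dsi",
    "run_direction_pair",
    "run_velocity_sweep",
    "run_incremental_conversion",
    "run_distance_regression",
    "regress_dsi_distance",
]

G_PEAK_PROXIMAL_PS = 172.2
G_PEAK_DISTAL_PS = 68.6


@dataclass
class Section:
    length_um: float
    diam_um: float

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diam_um <= 0:
            raise ValueError("section length and diameter must be positive")


@dataclass
class Morphology:
    """Soma plus dendritic sections listed from the soma outward.

    Defaults: 8-µm soma; initial dendrite 0–40 µm × 0.9 µm, middle
    40–110 µm × 0.4 µm, terminal 110–150 µm × 0.3 µm; 2-µm spatial step.
    """

    sections: list[Section] = field(
        default_factory=lambda: [Section(40, 0.9), Section(70, 0.4), Section(40, 0.3)]
    )
    soma_diam_um: float | None = 8.0
    dx_um: float = 2.0

    @property
    def dendrite_length_um(self) -> float:
        return sum(s.length_um for s in self.sections)

    def compartments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(diam_um, length_um, center_position_um); soma first if present.

        Soma center position is 0; dendritic positions measure distance
        from the soma along the dendrite.
        """
        diams, lengths, centers = [], [], []
        if self.soma_diam_um is not None:
            diams.append(self.soma_diam_um)
            lengths.append(self.soma_diam_um)  # soma as an equivalent cylinder L = d
            centers.append(0.0)
        x = 0.0
        for sec in self.sections:
            n = max(1, int(round(sec.length_um / self.dx_um)))
            dx = sec.length_um / n
            for i in range(n):
                diams.append(sec.diam_um)
                lengths.append(dx)
                centers.append(x + (i + 0.5) * dx)
            x += sec.length_um
        return np.array(diams), np.array(lengths), np.array(centers)


@dataclass
class PassiveParams:
    """Passive membrane properties (stand-ins for unpublished values)."""

    cm_uf_cm2: float = 1.0
    rm_kohm_cm2: float = 20.0
    ra_ohm_cm: float = 100.0
    e_leak_mv: float = -60.0


@dataclass
class CaParams:
    """Boltzmann-activated Ca conductance feeding a decaying pool.

    Instantaneous activation, half-activation −30 mV, 6 mV slope; the pool
    obeys dCa/dt = gain·I_Ca − Ca/τ with τ = 50 ms.  Ca is reported in
    arbitrary units (only peak ratios/differences are used).
    """

    gbar_s: float = 1e-9
    vhalf_mv: float = -30.0
    slope_mv: float = 6.0
    erev_mv: float = 45.0
    tau_s: float = 0.050
    gain: float = 1e12


@dataclass
class SynapseKinetics:
    """AMPA miniature-event conductance time course."""

    tau_rise_s: float = 0.14e-3
    tau_decay_s: float = 0.54e-3
    e_rev_mv: float = 0.0


@dataclass
class TruncatedGaussian:
    """Truncated normal density for synapse positions along the dendrite."""

    mean_um: float
    sd_um: float
    lo_um: float
    hi_um: float

    def _frozen(self):
        a = (self.lo_um - self.mean_um) / self.sd_um
        b = (self.hi_um - self.mean_um) / self.sd_um
        return stats.truncnorm(a, b, loc=self.mean_um, scale=self.sd_um)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self._frozen().rvs(size=n, random_state=rng), float)

    @property
    def expected_mean_um(self) -> float:
        return float(self._frozen().mean())

    @property
    def expected_sd_um(self) -> float:
        return float(self._frozen().std())


@dataclass
class BarStimulus:
    """A bright bar moving along the dendrite axis at constant velocity."""

    velocity_mm_s: float
    direction: str = "centrifugal"  # soma → tips; "centripetal" reverses
    bar_width_um: float = 400.0
    rf_diameter_um: float = 60.0

    def __post_init__(self) -> None:
        if self.velocity_mm_s <= 0:
            raise ValueError("velocity must be positive")
        if self.direction not in ("centrifugal", "centripetal"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def velocity_um_s(self) -> float:
        return self.velocity_mm_s * 1000.0

    @property
    def dwell_s(self) -> float:
        """Per-synapse active duration: (bar width + RF diameter)/velocity."""
        return (self.bar_width_um + self.rf_diameter_um) / self.velocity_um_s

    def reversed(self) -> "BarStimulus":
        other = "centripetal" if self.direction == "centrifugal" else "centrifugal"
        return replace(self, direction=other)


@dataclass
class Synapse:
    position_um: float
    kind: str  # "sustained" | "transient"
    g_peak_ps: float


@dataclass
class SACModel:
    """Full model configuration: cell, channels, inputs and solver."""

    morphology: Morphology = field(default_factory=Morphology)
    passive: PassiveParams = field(default_factory=PassiveParams)
    ca: CaParams = field(default_factory=CaParams)
    synapse_kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    n_proximal: int = 6
    n_distal: int = 12
    proximal_density: TruncatedGaussian = field(
        default_factory=lambda: TruncatedGaussian(25.0, 10.0, 5.0, 45.0)
    )
    distal_density: TruncatedGaussian = field(
        default_factory=lambda: TruncatedGaussian(75.0, 20.0, 45.0, 145.0)
    )
    sustained_profile: ReleaseProfileSpec = field(
        default_factory=ReleaseProfileSpec.sustained
    )
    transient_profile: ReleaseProfileSpec = field(
        default_factory=ReleaseProfileSpec.transient
    )
    g_anchor_um: tuple[float, float] = (5.0, 145.0)
    dt_s: float = 0.025e-3
    poisson_bin_s: float = 1e-3
    record_dt_s: float = 0.5e-3

    def profile_for(self, kind: str) -> ReleaseProfileSpec:
        if kind == "sustained":
            return self.sustained_profile
        if kind == "transient":
            return self.transient_profile
        raise ValueError(f"unknown synapse kind {kind!r}")


@dataclass
class SimResult:
    """One direction's simulation output."""

    direction: str
    time_s: np.ndarray
    soma_vm_mv: np.ndarray
    terminal_ca: np.ndarray
    peak_ca: float
    roster: list[Synapse]
    seed: int | None
    vm_all_mv: np.ndarray | None = None


def sample_synapse_locations(
    n_proximal: int = 6,
    n_distal: int = 12,
    proximal_density: TruncatedGaussian | None = None,
    distal_density: TruncatedGaussian | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw proximal and distal synapse positions from their densities."""
    proximal_density = proximal_density or TruncatedGaussian(25.0, 10.0, 5.0, 45.0)
    distal_density = distal_density or TruncatedGaussian(75.0, 20.0, 45.0, 145.0)
    rng = np.random.default_rng(seed)
    return (
        proximal_density.sample(n_proximal, rng),
        distal_density.sample(n_distal, rng),
    )


def conductance_scale(
    position_um: float | np.ndarray, d_min: float = 5.0, d_max: float = 145.0
) -> float | np.ndarray:
    """Peak AMPA conductance, linear from 172.2 pS (d_min) to 68.6 pS (d_max)."""
    if d_min >= d_max:
        raise ValueError("d_min must be below d_max")
    pos = np.asarray(position_um, float)
    if np.any(pos < d_min) or np.any(pos > d_max):
        warnings.warn("synapse position outside scaling anchors; clamping")
    frac = np.clip((pos - d_min) / (d_max - d_min), 0.0, 1.0)
    g = G_PEAK_PROXIMAL_PS + (G_PEAK_DISTAL_PS - G_PEAK_PROXIMAL_PS) * frac
    return float(g) if np.isscalar(position_um) else g


def schedule_activation(
    stimulus: BarStimulus, positions_um: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-synapse (onset, offset) times for the moving bar.

    A synapse turns on when the bar's leading edge reaches the near edge
    of its receptive field and off when the trailing edge clears the far
    edge; the bar starts just fully outside all receptive fields, so the
    first synapse switches on at t = 0.
    """
    pos = np.asarray(positions_um, float)
    half_rf = stimulus.rf_diameter_um / 2.0
    v = stimulus.velocity_um_s
    if stimulus.direction == "centrifugal":
        lead0 = pos.min() - half_rf
        onset = (pos - half_rf - lead0) / v
    else:
        lead0 = pos.max() + half_rf
        onset = (lead0 - (pos + half_rf)) / v
    return onset, onset + stimulus.dwell_s


def build_release_for_speed(
    profile: ReleaseProfileSpec,
    onset_s: float,
    offset_s: float,
    bin_s: float = 1e-3,
):
    """Window the canonical release profile to a bar's dwell time.

    The onset transient plays from *onset_s*; the plateau is held until
    *offset_s*; the rate is zero outside the window.  Returns
    (bin_center_times, rate_vps) on an absolute clock.
    """
    from .release import ReleaseRate

    if offset_s <= onset_s:
        raise ValueError("offset must exceed onset")
    centers = onset_s + (np.arange(int(round((offset_s - onset_s) / bin_s))) + 0.5) * bin_s
    return ReleaseRate(time_s=centers, rate_vps=profile.evoked_rate_at(centers - onset_s))


def build_roster(model: SACModel, seed: int | None, condition: str = "native") -> list[Synapse]:
    """Sample a synapse roster and assign kinetics per experiment condition.

    Conditions: ``native`` (proximal sustained, distal transient),
    ``swapped`` (reversed), ``all_sustained``, ``all_transient``.
    """
    kinds = {
        "native": ("sustained", "transient"),
        "swapped": ("transient", "sustained"),
        "all_sustained": ("sustained", "sustained"),
        "all_transient": ("transient", "transient"),
    }
    if condition not in kinds:
        raise ValueError(f"unknown condition {condition!r}")
    prox_kind, dist_kind = kinds[condition]
    prox, dist = sample_synapse_locations(
        model.n_proximal, model.n_distal, model.proximal_density, model.distal_density, seed
    )
    d_min, d_max = model.g_anchor_um
    roster = [
        Synapse(float(x), prox_kind, float(conductance_scale(x, d_min, d_max))) for x in prox
    ] + [Synapse(float(x), dist_kind, float(conductance_scale(x, d_min, d_max))) for x in dist]
    return roster


def _draw_trains(
    model: SACModel,
    roster: list[Synapse],
    stimulus: BarStimulus,
    seed: int | None,
    rate_scale: float = 1.0,
) -> list[np.ndarray]:
    """Per-synapse vesicle times in synapse-local time (0 = RF entry).

    Drawn once per (seed, synapse); a bar's transit over a receptive field
    is direction-independent, so the same trains serve both directions
    (common random numbers — the direction comparison then reflects
    timing, not train sampling noise).
    """
    dwell = stimulus.dwell_s
    bins = np.arange(int(round(dwell / model.poisson_bin_s)))
    centers = (bins + 0.5) * model.poisson_bin_s
    base = [0] if seed is None else ([seed] if np.isscalar(seed) else list(seed))
    trains = []
    for j, syn in enumerate(roster):
        rate = model.profile_for(syn.kind).evoked_rate_at(centers) * rate_scale
        rng = np.random.default_rng([int(b) for b in base] + [j])
        counts = rng.poisson(rate * model.poisson_bin_s)
        trains.append(centers[counts > 0].repeat(counts[counts > 0]))
    return trains


def _passive_arrays(morph: Morphology, passive: PassiveParams):
    diam_um, len_um, centers = morph.compartments()
    d_cm, l_cm = diam_um * 1e-4, len_um * 1e-4
    area = np.pi * d_cm * l_cm
    cm = passive.cm_uf_cm2 * 1e-6 * area
    g_leak = area / (passive.rm_kohm_cm2 * 1e3)
    r_half = 4.0 * passive.ra_ohm_cm * (l_cm / 2.0) / (np.pi * d_cm**2)
    g_ax = 1.0 / (r_half[:-1] + r_half[1:])
    return cm, g_leak, g_ax, centers


def _position_to_comp(morph: Morphology, centers: np.ndarray, position_um: float) -> int:
    has_soma = morph.soma_diam_um is not None
    dend_centers = centers[1:] if has_soma else centers
    i = int(np.argmin(np.abs(dend_centers - position_um)))
    return i + (1 if has_soma else 0)


def simulate(
    model: SACModel,
    roster: list[Synapse],
    stimulus: BarStimulus,
    seed: int | None = None,
    record_all: bool = False,
    duration_s: float | None = None,
    trains: list[np.ndarray] | None = None,
) -> SimResult:
    """Simulate one bar sweep; returns voltage, terminal Ca and its peak.

    Vesicle trains may be passed in (synapse-local times) or are drawn
    from *seed*; the same seed yields identical trains for both
    directions.  With an empty roster the membrane rests at the leak
    reversal throughout.
    """
    cm, g_leak, g_ax, centers = _passive_arrays(model.morphology, model.passive)
    n = cm.size
    kin = model.synapse_kinetics
    tp = _biexp_peak_time(kin.tau_rise_s, kin.tau_decay_s)
    peak_norm = np.exp(-tp / kin.tau_decay_s) - np.exp(-tp / kin.tau_rise_s)

    positions = np.array([s.position_um for s in roster])
    if roster:
        onsets, offsets = schedule_activation(stimulus, positions)
        if trains is None:
            trains = _draw_trains(model, roster, stimulus, seed)
        t_end = float(offsets.max()) + 0.35
    else:
        onsets = offsets = np.array([])
        trains = []
        t_end = 0.35
    if duration_s is not None:
        t_end = duration_s

    ev_t, ev_j = [], []
    for j, local in enumerate(trains):
        ev_t.append(local + onsets[j])
        ev_j.append(np.full(local.size, j, dtype=np.int64))
    if ev_t:
        ev_t = np.concatenate(ev_t)
        ev_j = np.concatenate(ev_j)
        order = np.argsort(ev_t, kind="stable")
        ev_t, ev_j = ev_t[order], ev_j[order]
    else:
        ev_t = np.empty(0)
        ev_j = np.empty(0, dtype=np.int64)

    dt = model.dt_s
    n_steps = int(np.ceil(t_end / dt))
    ev_step = np.maximum(1, np.round(ev_t / dt).astype(np.int64))
    syn_comp = np.array(
        [_position_to_comp(model.morphology, centers, s.position_um) for s in roster],
        dtype=np.int64,
    )
    syn_amp = np.array([s.g_peak_ps * 1e-12 / peak_norm for s in roster])
    record_every = max(1, int(round(model.record_dt_s / dt)))
    e_leak_v = model.passive.e_leak_mv * 1e-3

    rec_v, rec_ca = integrate(
        dt,
        n_steps,
        cm,
        g_leak,
        e_leak_v,
        g_ax,
        np.zeros(n),
        syn_comp,
        syn_amp,
        kin.tau_decay_s,
        kin.tau_rise_s,
        kin.e_rev_mv * 1e-3,
        ev_step,
        ev_j,
        n - 1,
        model.ca.gbar_s,
        model.ca.vhalf_mv * 1e-3,
        model.ca.slope_mv * 1e-3,
        model.ca.erev_mv * 1e-3,
        model.ca.tau_s,
        model.ca.gain,
        record_every,
        e_leak_v,
    )
    t_rec = np.arange(rec_v.shape[0]) * record_every * dt
    return SimResult(
        direction=stimulus.direction,
        time_s=t_rec,
        soma_vm_mv=rec_v[:, 0] * 1e3,
        terminal_ca=rec_ca,
        peak_ca=float(rec_ca.max()),
        roster=roster,
        seed=seed,
        vm_all_mv=rec_v * 1e3 if record_all else None,
    )


def inject_current(
    morph: Morphology,
    passive: PassiveParams,
    amp_a: float,
    comp: int = 0,
    duration_s: float = 0.3,
    dt_s: float = 0.025e-3,
    record_dt_s: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant current injection into one compartment (no synapses).

    Returns (time_s, vm_mv_all_compartments) — the oracle entry point for
    comparing the solver's steady state against the analytic finite-cable
    solution.
    """
    cm, g_leak, g_ax, _ = _passive_arrays(morph, passive)
    n = cm.size
    i_inj = np.zeros(n)
    i_inj[comp] = amp_a
    e_leak_v = passive.e_leak_mv * 1e-3
    rec_v, _ = integrate(
        dt_s,
        int(np.ceil(duration_s / dt_s)),
        cm,
        g_leak,
        e_leak_v,
        g_ax,
        i_inj,
        np.empty(0, dtype=np.int64),
        np.empty(0),
        0.54e-3,
        0.14e-3,
        0.0,
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        n - 1,
        0.0,
        -0.03,
        0.006,
        0.045,
        0.05,
        0.0,
        max(1, int(round(record_dt_s / dt_s))),
        e_leak_v,
    )
    return np.arange(rec_v.shape[0]) * max(1, int(round(record_dt_s / dt_s))) * dt_s, rec_v * 1e3


def compute_dsi(
    result_cf: SimResult, result_cp: SimResult, mode: str = "subtraction"
) -> float:
    """DSi from peak terminal Ca: CF − CP, or normalized (CF−CP)/(CF+CP)."""
    cf, cp = result_cf.peak_ca, result_cp.peak_ca
    if mode == "subtraction":
        return cf - cp
    if mode == "normalized":
        if cf + cp == 0:
            raise ValueError("zero total response in normalized mode")
        return (cf - cp) / (cf + cp)
    raise ValueError(f"unknown DSi mode {mode!r}")


def run_direction_pair(
    model: SACModel,
    roster: list[Synapse],
    velocity_mm_s: float,
    seed: int | None = None,
    deterministic: bool = False,
) -> tuple[SimResult, SimResult]:
    """Simulate centrifugal and centripetal sweeps with common trains.

    With ``deterministic=True`` the Poisson rates are oversampled 64-fold
    and the unitary conductances scaled down accordingly — the
    infinite-vesicle limit in which the response approaches its
    expectation (useful for studying the model's timing structure without
    train sampling noise).
    """
    stim_cf = BarStimulus(velocity_mm_s=velocity_mm_s, direction="centrifugal")
    if deterministic:
        scale = 64
        roster = [replace(s, g_peak_ps=s.g_peak_ps / scale) for s in roster]
        trains = _draw_trains(model, roster, stim_cf, seed, rate_scale=scale)
    else:
        trains = _draw_trains(model, roster, stim_cf, seed)
    res_cf = simulate(model, roster, stim_cf, seed=seed, trains=trains)
    res_cp = simulate(model, roster, stim_cf.reversed(), seed=seed, trains=trains)
    return res_cf, res_cp


def _pair_peaks(
    model: SACModel,
    roster: list[Synapse],
    velocity_mm_s: float,
    seed: int,
    n_presentations: int,
) -> tuple[float, float]:
    """Per-direction peak terminal Ca, averaged over stimulus presentations.

    Each presentation draws fresh vesicle trains (shared between the two
    directions); averaging the peaks over presentations is the usual
    trial-averaging step and suppresses Poisson train noise relative to
    the roster's directional signal.
    """
    base = [seed] if np.isscalar(seed) else list(seed)
    cf_pk, cp_pk = 0.0, 0.0
    for p in range(n_presentations):
        cf, cp = run_direction_pair(model, roster, velocity_mm_s, seed=base + [p])
        cf_pk += cf.peak_ca
        cp_pk += cp.peak_ca
    return cf_pk / n_presentations, cp_pk / n_presentations


def _repeat_dsi(
    model: SACModel,
    velocity: float,
    n_repeats: int,
    seed: int,
    condition: str,
    n_presentations: int = 5,
) -> pd.DataFrame:
    rows = []
    vkey = int(round(velocity * 1e4))
    for r in range(n_repeats):
        roster = build_roster(model, seed=[seed, vkey, r, 0], condition=condition)
        cf_pk, cp_pk = _pair_peaks(model, roster, velocity, [seed, vkey, r, 1], n_presentations)
        prox = np.mean([s.position_um for s in roster[: model.n_proximal]])
        dist = np.mean([s.position_um for s in roster[model.n_proximal :]])
        rows.append(
            {
                "velocity_mm_s": velocity,
                "repeat": r,
                "condition": condition,
                "dsi": cf_pk - cp_pk,
                "dsi_normalized": (cf_pk - cp_pk) / (cf_pk + cp_pk),
                "peak_ca_cf": cf_pk,
                "peak_ca_cp": cp_pk,
                "centroid_distance_um": dist - prox,
            }
        )
    return pd.DataFrame(rows)


def run_velocity_sweep(
    model: SACModel,
    velocities_mm_s,
    n_repeats: int = 10,
    seed: int = 0,
    condition: str = "native",
    n_presentations: int = 5,
) -> pd.DataFrame:
    """Mean ± s.e.m. DSi per velocity, rosters resampled per repeat.

    Each repeat samples a fresh synapse roster, runs *n_presentations*
    stimulus presentations in each direction and computes DSi from the
    presentation-averaged peak Ca.
    """
    per_trial = pd.concat(
        [
            _repeat_dsi(model, float(v), n_repeats, seed, condition, n_presentations)
            for v in velocities_mm_s
        ],
        ignore_index=True,
    )
    agg = (
        per_trial.groupby("velocity_mm_s")
        .agg(
            dsi_mean=("dsi", "mean"),
            dsi_sem=("dsi", "sem"),
            dsi_norm_mean=("dsi_normalized", "mean"),
            dsi_norm_sem=("dsi_normalized", "sem"),
            n=("dsi", "size"),
        )
        .reset_index()
    )
    agg.attrs["per_trial"] = per_trial
    agg.attrs["condition"] = condition
    return agg


def run_incremental_conversion(
    model: SACModel,
    velocity_mm_s: float = 0.15,
    n_repeats: int = 10,
    seed: int = 0,
    n_presentations: int = 5,
) -> pd.DataFrame:
    """DSi versus number of sustained (proximal-profile) inputs, 0…6.

    Roster positions are fixed per repeat; proximal inputs are converted
    to transient kinetics one at a time, starting from the proximal site
    furthest from the soma.
    """
    rows = []
    for r in range(n_repeats):
        roster = build_roster(model, seed=[seed, r, 7], condition="native")
        prox_idx = np.argsort([-roster[i].position_um for i in range(model.n_proximal)])
        for n_sus in range(model.n_proximal + 1):
            mod = [replace(s) for s in roster]
            for k in range(model.n_proximal - n_sus):
                mod[int(prox_idx[k])].kind = "transient"
            cf_pk, cp_pk = _pair_peaks(
                model, mod, velocity_mm_s, [seed, r, n_sus, 1], n_presentations
            )
            rows.append(
                {
                    "repeat": r,
                    "n_sustained": n_sus,
                    "dsi": cf_pk - cp_pk,
                    "dsi_normalized": (cf_pk - cp_pk) / (cf_pk + cp_pk),
                }
            )
    per_trial = pd.DataFrame(rows)
    agg = (
        per_trial.groupby("n_sustained")
        .agg(dsi_mean=("dsi", "mean"), dsi_sem=("dsi", "sem"), n=("dsi", "size"))
        .reset_index()
    )
    agg.attrs["per_trial"] = per_trial
    return agg


def regress_dsi_distance(
    centroid_distances_um: np.ndarray, dsi: np.ndarray
) -> tuple[float, float]:
    """OLS of |DSi| on the proximal–distal centroid distance → (slope, R²)."""
    x = np.asarray(centroid_distances_um, float)
    y = np.abs(np.asarray(dsi, float))
    if x.size < 3 or np.std(x) == 0:
        raise ValueError("degenerate distances (need variance across ≥3 repeats)")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


def run_distance_regression(
    model: SACModel,
    velocity_mm_s: float = 0.15,
    n_repeats: int = 100,
    seed: int = 0,
    condition: str = "native",
    n_presentations: int = 5,
) -> tuple[pd.DataFrame, float, float]:
    """Re-run the roster-resampling experiment and regress |DSi| on distance."""
    per_trial = _repeat_dsi(model, velocity_mm_s, n_repeats, seed, condition, n_presentations)
    slope, r2 = regress_dsi_distance(
        per_trial["centroid_distance_um"].to_numpy(), per_trial["dsi"].to_numpy()
    )
    return per_trial, slope, r2
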