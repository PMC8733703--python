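"""Ground-truth fed-batch CHO simulator and design factories.

The original cultivation data are not public, so every pipeline stage is
developed and tested against this simulator, whose true rate functions,
adaptation lag, and noise model are known exactly.

The ground truth encodes the qualitative process behavior the hybrid
model must recover, and deliberately routes every scale- and
age-dependent effect through *observable* quantities (the model inputs),
so that the rate surfaces are identifiable from sampled data:

- growth peaks near 37 C and is driven by glutamine (whose first-order
  chemical degradation acts as a culture-age clock), supported by
  asparagine, and inhibited by accumulated alanine;
- bolus-fed shake flasks run substrate-replete and grow fast, but the
  daily boom-bust feeding cycles accumulate stress; the stress ramp
  secretes overflow alanine, which first stops growth, then kills the
  culture (viability harvest criterion < 70% around day 11);
- continuously fed 15 L reactors secrete overflow alanine under
  sustained trickle feeding up to a re-consumption plateau that is
  independent of biomass and CPP setting; the plateau-level growth
  inhibition is what caps their growth, so they stay viable through
  day 15 at roughly half the shake-flask peak cell density;
- alanine secretion drains glutamate (alanine aminotransferase), so the
  aspartate/glutamate ratio rises as the culture shifts metabolically;
  product formation is favored in this shifted state and saturates with
  the feed glucose level, which is why the slower-growing reactors reach
  the higher titers;
- cells adapt to CPP shifts with a first-order lag (time constant
  ~2 days), so intensified runs respond gradually.

Analytes that the true rates do not use (serine, glycine, tyrosine,
hydroxyproline, proline) are kept near feed balance: their small dynamic
range leaves them dominated by assay noise, as befits non-causal
candidates in the input-selection experiments.  Proline closely tracks
hydroxyproline (shared collagen-turnover source), providing the
collinear pair the selection screen must catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from hybridoe.datamodel import (
    ANALYTE_NAMES,
    BATCH_END_H,
    FEED_LEVEL_GLUCOSE,
    SEEDING_DENSITY,
    CultivationRun,
    Design,
    FeedSchedule,
    SampleSeries,
    Segment,
)

#: Basal medium composition at inoculation (g/L).
INITIAL_MEDIUM: dict[str, float] = {
    "glucose": 6.0,
    "glutamine": 1.2,  # 8 mM supplement
    "asparagine": 2.5,
    "alanine": 0.05,
    "aspartate": 0.25,
    "glutamate": 0.45,
    "serine": 0.9,
    "glycine": 0.25,
    "tyrosine": 0.6,
    "hydroxyproline": 0.3,
    "proline": 0.9,
}

#: Feed medium analytes common to all levels (g/L); glucose is the base
#: feed value before the level-specific addition.
FEED_BASE: dict[str, float] = {
    "glucose": 7.0,
    "glutamine": 0.0,
    "asparagine": 6.0,
    "alanine": 0.0,
    "aspartate": 0.3,
    "glutamate": 0.5,
    "serine": 1.0,
    "glycine": 0.25,
    "tyrosine": 0.5,
    "hydroxyproline": 0.28,
    "proline": 0.84,
}

SHAKER_VOLUME_L = 0.3
BIOREACTOR_VOLUME_L = 15.0
SHAKER_PLANNED_H = 336.0
BIOREACTOR_PLANNED_H = 360.0


def feed_composition() -> dict[str, dict[str, float]]:
    """Analyte composition of the three feed media (g/L)."""
    comp = {}
    for level, added in FEED_LEVEL_GLUCOSE.items():
        c = dict(FEED_BASE)
        c["glucose"] = FEED_BASE["glucose"] + added
        comp[level] = c
    return comp


@dataclass
class ObservationModel:
    """Sampling schedule and measurement noise.

    Samples are taken every 24 h from inoculation, plus 6 h after each
    CPP shift in intensified runs.  Noise is multiplicative lognormal
    with per-variable coefficients of variation; it is mean-preserving
    and deterministic given the seed.
    """

    sampling_interval_h: float = 24.0
    post_shift_offset_h: float = 6.0
    cv_vcc: float = 0.05
    cv_titer: float = 0.07
    cv_analytes: float = 0.05
    cv_viability: float = 0.02

    def sampling_times(self, design: Design, t_end: float) -> np.ndarray:
        times = set(np.arange(0.0, t_end + 1e-9, self.sampling_interval_h))
        for t_shift in design.shift_times:
            t = t_shift + self.post_shift_offset_h
            if t <= t_end:
                times.add(t)
        return np.array(sorted(times))

    def _noisy(self, rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
        if cv <= 0:
            return values.copy()
        sigma = np.sqrt(np.log1p(cv**2))
        z = rng.standard_normal(len(values))
        return values * np.exp(sigma * z - 0.5 * sigma**2)


@dataclass
class GroundTruth:
    """True rate functions, adaptation lag, yields and noise model.

    All rates are h^-1; concentrations g/L; VCC 10^6 cells/mL.  The
    defaults are calibrated so the noiseless center-point (34 C, F2)
    trajectories reproduce the landmark behavior of the study system:
    shake flask VCC peaking ~20.8 at day 9, harvest (<70% viability) on
    day 11, maximum titer ~0.64 g/L on day 10; bioreactor VCC ~10.5 and
    titer ~0.76 g/L at day 15 with no viability decline.
    """

    # growth rate
    mu_max: float = 0.086  # h^-1
    T_opt_mu: float = 37.0
    T_width_mu: float = 4.0
    K_asn: float = 1.2  # g/L, Monod constant on asparagine
    beta_gln: float = 0.92  # fraction of growth dependent on glutamine
    K_gln: float = 0.35
    K_ala: float = 1.6  # g/L, alanine growth inhibition
    ala_pow: float = 3.0  # steepness of the alanine inhibition
    a_cont: float = float("inf")  # h; no explicit culture-age term by default
    k_death: float = 0.012  # h^-1 at s = 1

    # product formation
    v_max: float = 5.07e-4  # g/L/h per 10^6 cells/mL
    T_opt_v: float = 35.0
    T_width_v: float = 5.0
    K_feed_glc: float = 10.0  # g/L on the feed glucose CPP value
    K_ratio: float = 0.6  # ratio half-stimulating production (metabolic shift)
    k_vs: float = 0.0  # optional latent stress suppression of production

    # stress and viability
    k_stress_bolus: float = 0.0040  # h^-1, bolus fed-batch ramp
    k_stress_starv: float = 2.0e-4  # h^-1 times nutrient shortfall
    viab_s50: float = 0.825
    viab_hill: float = 16.0

    # adaptation lag to CPP shifts
    tau: float = 48.0  # h

    # analyte stoichiometry (g per 10^6 cells/mL grown, and g/L/h per X)
    y_glc: float = 0.35
    m_glc: float = 8.0e-4
    y_gln: float = 0.01
    m_gln: float = 1.0e-4
    k_gln_deg: float = 1.2e-2  # h^-1 spontaneous degradation (dominant sink)
    y_asn: float = 0.05
    m_asn: float = 2.0e-4
    y_ala: float = 0.01  # produced per unit growth
    s_ala: float = 0.14  # produced per unit stress increase (times X), bolus
    q_ala_cont: float = 3.55e-2  # g/L/h per X: overflow secretion, continuous feed
    c_ala_cont: float = 4.5e-2  # g/L/h per X: alanine re-consumption, continuous
    K_ala_cons: float = 0.7  # g/L, saturation of alanine re-consumption
    y_asp: float = 0.004  # produced per unit growth
    m_asp: float = 0.5e-4
    m_glu: float = 1.0e-4
    lam_glu: float = 0.08  # g glutamate consumed per g alanine secreted (ALT coupling)
    y_ser: float = 0.004
    m_ser: float = 1.0e-4
    g_gly: float = 0.30  # glycine produced per serine consumed
    m_gly: float = 1.0e-4  # glycine maintenance consumption
    m_tyr: float = 0.2e-4
    y_tyr: float = 3.0e-4  # growth-linked tyrosine consumption
    m_hyp: float = 1.5e-5
    m_pro: float = 4.2e-5  # ~2.8x hydroxyproline (collinear)
    y_pro: float = 2.0e-4  # small growth-linked proline use (decorrelates)

    observation: ObservationModel = field(default_factory=ObservationModel)
    seed: int = 0

    # -- rate functions ---------------------------------------------------
    def mu_true(
        self,
        T_eff: float | np.ndarray,
        asn: float | np.ndarray,
        gln: float | np.ndarray,
        ala: float | np.ndarray,
        stress: float | np.ndarray,
        age_fb: float | np.ndarray,
        mode: str,
    ) -> float | np.ndarray:
        """True specific growth rate (h^-1), clipped to |mu| <= 0.1."""
        bell = np.exp(-0.5 * ((T_eff - self.T_opt_mu) / self.T_width_mu) ** 2)
        f_asn = asn / (self.K_asn + asn)
        f_gln = (1 - self.beta_gln) + self.beta_gln * gln / (self.K_gln + gln)
        f_ala = 1.0 / (1.0 + (ala / self.K_ala) ** self.ala_pow)
        if mode == "continuous" and np.isfinite(self.a_cont):
            g_mode = 1.0 / (1.0 + np.maximum(age_fb, 0.0) / self.a_cont)
        else:
            g_mode = 1.0
        mu = self.mu_max * bell * f_asn * f_gln * f_ala * g_mode - self.k_death * stress**2
        return np.clip(mu, -0.1, 0.1)

    def vpx_true(
        self,
        T_eff: float | np.ndarray,
        feed_glc_eff: float | np.ndarray,
        asp_glu_ratio: float | np.ndarray,
        stress: float | np.ndarray,
    ) -> float | np.ndarray:
        """True specific production rate (g/L/h per 10^6 cells/mL)."""
        bell = np.exp(-0.5 * ((T_eff - self.T_opt_v) / self.T_width_v) ** 2)
        f_glc = feed_glc_eff / (self.K_feed_glc + feed_glc_eff)
        R = asp_glu_ratio
        # product formation is favored in the shifted (post-exponential)
        # metabolic state indicated by a rising aspartate/glutamate ratio
        f_r = R**2 / (self.K_ratio**2 + R**2)
        return self.v_max * bell * f_glc * f_r * (1.0 - self.k_vs * stress)

    def viability(self, stress: float | np.ndarray) -> float | np.ndarray:
        """Culture viability (%) as a declining function of cumulative stress."""
        return 100.0 / (1.0 + (np.maximum(stress, 0.0) / self.viab_s50) ** self.viab_hill)


# ---------------------------------------------------------------------------
# design factories


def make_shaker_doe() -> list[Design]:
    """The 18 shake-flask full-factorial designs (3 temperatures x 3 feed
    levels, each in duplicate), batch 72 h at 37 C, temperature shift at
    fed-batch start."""
    designs = []
    for T in (31.0, 34.0, 37.0):
        for level in ("F1", "F2", "F3"):
            for _dup in range(2):
                designs.append(
                    Design(
                        doe_mode="static",
                        segments=[Segment(BATCH_END_H, T, level)],
                        planned_duration=SHAKER_PLANNED_H,
                    )
                )
    return designs


def make_bioreactor_designs() -> list[Design]:
    """The 11 bioreactor designs: 5 static (incl. one at 36.3 C/F3 and the
    center-point triplicate) and 6 intensified with CPP shifts at
    120/192/240 h."""

    def static(T, level):
        return Design(
            doe_mode="static",
            segments=[Segment(BATCH_END_H, T, level)],
            planned_duration=BIOREACTOR_PLANNED_H,
        )

    def intensified(*segs):
        return Design(
            doe_mode="intensified",
            segments=[Segment(t, T, lvl) for (t, T, lvl) in segs],
            planned_duration=BIOREACTOR_PLANNED_H,
        )

    return [
        static(36.3, "F3"),
        static(34.0, "F1"),
        intensified((72.0, 37.0, "F3"), (192.0, 37.0, "F1")),
        intensified((72.0, 34.0, "F2"), (120.0, 37.0, "F2"), (192.0, 34.0, "F1"), (240.0, 31.0, "F1")),
        intensified((72.0, 31.0, "F2"), (120.0, 34.0, "F2"), (192.0, 37.0, "F3"), (240.0, 34.0, "F3")),
        intensified((72.0, 34.0, "F1"), (120.0, 31.0, "F1"), (192.0, 31.0, "F2"), (240.0, 34.0, "F2")),
        intensified((72.0, 37.0, "F2"), (120.0, 34.0, "F3"), (192.0, 31.0, "F2"), (240.0, 34.0, "F1")),
        intensified((72.0, 34.0, "F3"), (120.0, 37.0, "F2"), (192.0, 31.0, "F2"), (240.0, 37.0, "F3")),
        static(34.0, "F2"),
        static(34.0, "F2"),
        static(34.0, "F2"),
    ]


# ---------------------------------------------------------------------------
# effective (adapted) CPP profiles


def _cpp_set_profile(design: Design, which: str) -> list[tuple[float, float]]:
    """Breakpoints (t, set value) of the CPP step profile, right-continuous."""
    pieces: list[tuple[float, float]] = []
    first = design.segments[0]
    first_val = first.temperature if which == "temperature" else FEED_LEVEL_GLUCOSE[first.feed_level]
    if design.batch_end > 0:
        # batch phase: 37 C; the feed level is carried at its first setting
        # (cells meet the feed only at fed-batch onset, already adapted to it)
        pieces.append((0.0, 37.0 if which == "temperature" else first_val))
    for seg in design.segments:
        val = seg.temperature if which == "temperature" else FEED_LEVEL_GLUCOSE[seg.feed_level]
        pieces.append((seg.start_time, val))
    return pieces


def _first_order_lag(pieces: list[tuple[float, float]], tau: float, t: np.ndarray) -> np.ndarray:
    """First-order response of a step profile, continuous across steps."""
    t = np.asarray(t, dtype=float)
    if tau <= 1e-9:
        out = np.full_like(t, pieces[0][1])
        for t0, val in pieces:
            out = np.where(t >= t0, val, out)
        return out
    out = np.empty_like(t)
    c_start = pieces[0][1]  # equilibrated at the initial set value
    for i, (t0, val) in enumerate(pieces):
        t1 = pieces[i + 1][0] if i + 1 < len(pieces) else np.inf
        mask = (t >= t0) & (t < t1)
        out[mask] = val + (c_start - val) * np.exp(-(t[mask] - t0) / tau)
        c_start = val + (c_start - val) * (np.exp(-(t1 - t0) / tau) if np.isfinite(t1) else 0.0)
    before = t < pieces[0][0]
    out[before] = pieces[0][1]
    return out


def effective_cpp(design: Design, tau: float, t: float | np.ndarray) -> tuple:
    """Effective (cell-experienced) CPPs at time ``t``.

    First-order lag of the set-point step profile,
    ``dC_eff/dt = (C_set - C_eff)/tau``, continuous across shifts.
    Returns ``(T_eff, feed_glucose_eff)``; the feed level is expressed as
    its numeric added-glucose value (g/L).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    T = _first_order_lag(_cpp_set_profile(design, "temperature"), tau, t_arr)
    G = _first_order_lag(_cpp_set_profile(design, "feed_glucose"), tau, t_arr)
    if np.ndim(t) == 0:
        return float(T[0]), float(G[0])
    return T, G


# ---------------------------------------------------------------------------
# simulation


_AIDX = {name: i for i, name in enumerate(ANALYTE_NAMES)}


def _soft(a: float, k: float = 0.02) -> float:
    """Soft floor factor: -> 1 for a >> k, -> 0 as a -> 0 (keeps analytes >= 0)."""
    return a / (a + k) if a > 0 else 0.0


def simulate_truth(
    design: Design,
    scale: str,
    gt: GroundTruth,
    dense_step_h: float = 1.0,
):
    """Integrate the full ground-truth state over the planned duration.

    Returns a dict with dense traces: ``times, X, P, V, stress, viability,
    mu, vpx, T_eff, G_eff`` and ``analytes`` (name -> trace).  No noise,
    no truncation (the harvest rule is applied by :func:`simulate_run`).
    """
    if scale == "shake_flask":
        mode, V0, t_end = "bolus", SHAKER_VOLUME_L, design.planned_duration
    elif scale == "bioreactor":
        mode, V0, t_end = "continuous", BIOREACTOR_VOLUME_L, design.planned_duration
    else:
        raise ValueError(f"unknown scale {scale!r}")
    comp = feed_composition()
    fb = design.batch_end
    flow = 0.033 * V0 / 24.0  # continuous feed: same daily v/v as the bolus

    n_a = len(ANALYTE_NAMES)
    y0 = np.empty(4 + n_a)
    y0[0] = SEEDING_DENSITY  # X
    y0[1] = 0.0  # P
    y0[2] = V0  # V
    y0[3] = 0.0  # stress
    for name, i in _AIDX.items():
        y0[4 + i] = INITIAL_MEDIUM[name]

    def rates_at(t, y):
        X, P, V, s = y[0], y[1], y[2], y[3]
        a = y[4:]
        T_eff, G_eff = effective_cpp(design, gt.tau, float(t))
        age_fb = max(0.0, t - fb)
        asn = a[_AIDX["asparagine"]]
        gln = a[_AIDX["glutamine"]]
        ala = a[_AIDX["alanine"]]
        asp = a[_AIDX["aspartate"]]
        glu = a[_AIDX["glutamate"]]
        ratio = asp / max(glu, 1e-3)
        mu = gt.mu_true(T_eff, max(asn, 0.0), max(gln, 0.0), max(ala, 0.0), s, age_fb, mode)
        vpx = gt.vpx_true(T_eff, G_eff, ratio, s)
        return mu, vpx, T_eff, G_eff

    def rhs(t, y):
        X, P, V, s = y[0], y[1], y[2], y[3]
        a = y[4:]
        mu, vpx, T_eff, G_eff = rates_at(t, y)
        asn = a[_AIDX["asparagine"]]
        gln = a[_AIDX["glutamine"]]
        f_asn = max(asn, 0.0) / (gt.K_asn + max(asn, 0.0))
        f_gln = (1 - gt.beta_gln) + gt.beta_gln * max(gln, 0.0) / (gt.K_gln + max(gln, 0.0))
        ds = gt.k_stress_starv * (1.0 - f_asn * f_gln)
        if mode == "bolus" and t >= fb:
            ds += gt.k_stress_bolus

        in_fed = mode == "continuous" and t >= fb
        F = flow if in_fed else 0.0
        D = F / V
        mu_pos = max(mu, 0.0)

        dy = np.zeros_like(y)
        dy[0] = (mu - D) * X
        dy[1] = vpx * X - D * P
        dy[2] = F
        dy[3] = ds

        level = design.segment_at(t).feed_level if t >= fb else design.segments[0].feed_level
        feed_c = comp[level]

        def q(idx, rate):  # consumption with soft floor
            return rate * _soft(a[idx])

        dA = np.zeros(n_a)
        dA[_AIDX["glucose"]] = -q(_AIDX["glucose"], (gt.y_glc * mu_pos + gt.m_glc) * X)
        dA[_AIDX["glutamine"]] = -q(
            _AIDX["glutamine"], (gt.y_gln * mu_pos + gt.m_gln) * X
        ) - gt.k_gln_deg * max(gln, 0.0)
        dA[_AIDX["asparagine"]] = -q(_AIDX["asparagine"], (gt.y_asn * mu_pos + gt.m_asn) * X)
        ala = a[_AIDX["alanine"]]
        d_ala = (gt.y_ala * mu_pos + gt.s_ala * ds) * X
        if in_fed:
            # sustained mild overflow under trickle feeding, balanced by
            # re-consumption once substrate is limiting: alanine plateaus at
            # a level independent of biomass and CPP setting
            d_ala += gt.q_ala_cont * X
            d_ala -= gt.c_ala_cont * X * max(ala, 0.0) / (gt.K_ala_cons + max(ala, 0.0))
        dA[_AIDX["alanine"]] = d_ala
        dA[_AIDX["aspartate"]] = gt.y_asp * mu_pos * X - q(_AIDX["aspartate"], gt.m_asp * X)
        # alanine secretion consumes glutamate (alanine aminotransferase)
        dA[_AIDX["glutamate"]] = -q(
            _AIDX["glutamate"], gt.m_glu * X + gt.lam_glu * max(d_ala, 0.0)
        )
        ser_cons = q(_AIDX["serine"], (gt.y_ser * mu_pos + gt.m_ser) * X)
        dA[_AIDX["serine"]] = -ser_cons
        dA[_AIDX["glycine"]] = gt.g_gly * ser_cons - q(_AIDX["glycine"], gt.m_gly * X)
        dA[_AIDX["tyrosine"]] = -q(_AIDX["tyrosine"], (gt.y_tyr * mu_pos + gt.m_tyr) * X)
        dA[_AIDX["hydroxyproline"]] = -q(_AIDX["hydroxyproline"], gt.m_hyp * X)
        dA[_AIDX["proline"]] = -q(_AIDX["proline"], (gt.m_pro + gt.y_pro * mu_pos) * X)
        if in_fed:
            for name, i in _AIDX.items():
                dA[i] += D * (feed_c.get(name, 0.0) - a[i])
        dy[4:] = dA
        return dy

    # breakpoints: bolus events, segment starts, end
    breaks = {0.0, float(t_end)}
    breaks.update(float(s.start_time) for s in design.segments if 0 < s.start_time < t_end)
    if mode == "bolus":
        bolus_ts = np.arange(fb, t_end - 1e-9, 24.0)
        breaks.update(map(float, bolus_ts))
    else:
        bolus_ts = np.empty(0)
    breaks = np.array(sorted(breaks))

    grid = np.unique(np.concatenate([
        np.arange(0.0, t_end + 1e-9, dense_step_h), breaks,
    ]))

    times, traj = [], []
    y = y0.copy()
    for a0, b0 in zip(breaks[:-1], breaks[1:]):
        if a0 in bolus_ts:
            level = design.segment_at(a0).feed_level
            feed_c = comp[level]
            V = y[2]
            vB = 0.033 * V
            f = V / (V + vB)
            y[0] *= f
            y[1] *= f
            for name, i in _AIDX.items():
                y[4 + i] = (y[4 + i] * V + feed_c.get(name, 0.0) * vB) / (V + vB)
            y[2] = V + vB
        t_eval = grid[(grid >= a0) & (grid <= b0)]
        sol = solve_ivp(rhs, (a0, b0), y, method="LSODA", rtol=1e-8, atol=1e-10, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"ground-truth integration failed: {sol.message}")
        # samples at bolus times are drawn before feeding: keep the earlier
        # (pre-bolus) value where a boundary appears in both sub-intervals
        start = 1 if times and np.isclose(sol.t[0], times[-1]) else 0
        for i in range(start, len(sol.t)):
            times.append(float(sol.t[i]))
            traj.append(sol.y[:, i].copy())
        y = sol.y[:, -1].copy()

    times = np.array(times)
    Y = np.array(traj).T
    mu_tr = np.empty(len(times))
    v_tr = np.empty(len(times))
    Te = np.empty(len(times))
    Ge = np.empty(len(times))
    for i, t in enumerate(times):
        mu_tr[i], v_tr[i], Te[i], Ge[i] = rates_at(t, Y[:, i])
    return {
        "times": times,
        "X": np.maximum(Y[0], 0.0),
        "P": np.maximum(Y[1], 0.0),
        "V": Y[2],
        "stress": Y[3],
        "viability": gt.viability(Y[3]),
        "mu": mu_tr,
        "vpx": v_tr,
        "T_eff": Te,
        "G_eff": Ge,
        "analytes": {name: np.maximum(Y[4 + i], 0.0) for name, i in _AIDX.items()},
        "mode": mode,
    }


def simulate_run(
    design: Design,
    scale: str,
    gt: GroundTruth,
    seed: int = 0,
    noiseless: bool = False,
    run_id: str = "run",
) -> CultivationRun:
    """Simulate one cultivation and apply the observation model.

    Samples are drawn daily (plus 6 h after each CPP shift); shake-flask
    runs are truncated at the first sample whose measured viability falls
    below 70% (that sample is retained as the harvest sample); bioreactor
    runs always run to 360 h.  With ``noiseless=True`` the measurements
    equal the simulator states and the result is seed-independent.
    """
    if scale == "shake_flask" and design.planned_duration > SHAKER_PLANNED_H:
        design = replace(design, planned_duration=SHAKER_PLANNED_H)
    truth = simulate_truth(design, scale, gt)
    obs = gt.observation
    t_end = design.planned_duration
    t_s = obs.sampling_times(design, t_end)

    def at(trace: np.ndarray) -> np.ndarray:
        return np.interp(t_s, truth["times"], trace)

    vcc = at(truth["X"])
    titer = at(truth["P"])
    viab = at(truth["viability"])
    vol = at(truth["V"])
    analytes = {name: at(tr) for name, tr in truth["analytes"].items()}

    if not noiseless:
        rng = np.random.default_rng(seed)
        vcc = obs._noisy(rng, vcc, obs.cv_vcc)
        titer = obs._noisy(rng, titer, obs.cv_titer)
        viab = np.clip(obs._noisy(rng, viab, obs.cv_viability), 0.0, 100.0)
        analytes = {n: obs._noisy(rng, a, obs.cv_analytes) for n, a in analytes.items()}

    if scale == "shake_flask":
        below = np.flatnonzero(viab < 70.0)
        if len(below):
            keep = below[0] + 1
            t_s = t_s[:keep]
            vcc, titer, viab, vol = vcc[:keep], titer[:keep], viab[:keep], vol[:keep]
            analytes = {n: a[:keep] for n, a in analytes.items()}

    samples = SampleSeries(times=t_s, vcc=vcc, viability=viab, titer=titer, analytes=analytes)
    run = CultivationRun(
        run_id=run_id,
        scale=scale,
        working_volume=SHAKER_VOLUME_L if scale == "shake_flask" else BIOREACTOR_VOLUME_L,
        design=design,
        feed=FeedSchedule(
            mode="bolus" if scale == "shake_flask" else "continuous",
            composition=feed_composition(),
        ),
        samples=samples,
        volume_times=truth["times"],
        volume_l=truth["V"],
    )
    return run


SCENARIOS = ("shaker_doe", "bioreactor_all", "transfer_training", "idoe_training")


def make_dataset(
    scenario: str, gt: GroundTruth | None = None, seed: int = 0, noiseless: bool = False
) -> dict[str, list[CultivationRun]]:
    """Simulate a named study scenario.

    Returns ``{"train": [...], "test": [...]}``:

    - ``shaker_doe``: the 18 shake-flask runs (no test set);
    - ``bioreactor_all``: the 11 bioreactor runs (no test set);
    - ``transfer_training``: 18 shaker runs + the 3 bioreactor center
      points as training; the remaining 8 bioreactor runs as test;
    - ``idoe_training``: the 6 intensified bioreactor runs as training;
      the 5 static bioreactor runs as test.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    gt = gt or GroundTruth()
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(64))

    def sim(design, scale, rid):
        return simulate_run(design, scale, gt, seed=next(child).generate_state(1)[0] % (2**31), noiseless=noiseless, run_id=rid)

    shaker = [
        sim(d, "shake_flask", f"SF{i+1:02d}") for i, d in enumerate(make_shaker_doe())
    ]
    bio = [
        sim(d, "bioreactor", f"BR{i+1:02d}") for i, d in enumerate(make_bioreactor_designs())
    ]
    center = [bio[8], bio[9], bio[10]]  # BR09-BR11, the center-point triplicate
    others = bio[:8]
    intensified = [r for r in bio if r.design.doe_mode == "intensified"]
    static = [r for r in bio if r.design.doe_mode == "static"]

    if scenario == "shaker_doe":
        return {"train": shaker, "test": []}
    if scenario == "bioreactor_all":
        return {"train": bio, "test": []}
    if scenario == "transfer_training":
        return {"train": shaker + center, "test": others}
    return {"train": intensified, "test": static}
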