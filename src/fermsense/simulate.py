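"""Fed-batch *E. coli* fermentation and optical-probe simulator.

This is the package's synthetic-data generator: it produces probe logs,
ground-truth biomass trajectories, offline reference samples and event logs
so the signal-conditioning, calibration and control modules are testable
end-to-end without hardware.

Process model (Euler-stepped at the probe sampling interval ``dt``):

* **waiting** — the fermenter equilibrates (aerating, heating, stirring)
  with no biomass: OD 0, transmission at its clean-medium level.
* **batch** — growth on the initial glucose bolus with Monod kinetics,
  ``dX/dt = mu_max * X * S/(ks + S)``, ``dS/dt = -(1/yield_xs) dX/dt``.
  Dissolved oxygen is depressed in proportion to the oxygen uptake rate
  (here ``mu * X``); when glucose runs out, uptake collapses and DO rises
  sharply — the classic exhaustion spike used to start the feed.
* **fed-batch** — an exponential glucose feed
  ``F(t) = feed_rate0 * exp(mu_set (t - t_feed))`` holds the specific
  growth rate at ``mu_set``; volume grows by feed and antifoam boluses.
* **induction** — growth continues at ``mu_set * induction_mu_factor``.

Optical forward model: transmission saturates reciprocally in biomass,
``T = c_t / (1 + k_t (OD + gamma AF%))``, so that 1/T is *exactly* linear
in OD — making the calibration's inverse transform sharp on noiseless data
— and reflection is affine, ``R = r0 + r1 OD + r2 AF%``. Antifoam enters
both channels because the dosed emulsion is optically active. Channels are
corrupted with multiplicative Gaussian noise plus rare bubble artifacts
(transmission dips, reflection spikes).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import events as ev
from .exceptions import InvalidInputError
from .signals import DEFAULT_MA_WINDOW, PROBE_LOG_COLUMNS, featurize_log

PHASES = ("waiting", "batch", "fedbatch", "induction")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ProbeModel:
    """Optical forward-model coefficients for one physical probe.

    ``c_t`` is the clean-medium transmission level (detector units) and
    ``k_t`` the attenuation per OD unit, so ``1/T = (1 + k_t OD)/c_t``.
    ``gamma_t`` converts antifoam %vol into equivalent OD on the
    transmission channel; ``r0/r1/r2`` are the reflection intercept, slope
    per OD and slope per antifoam %vol. ``probe_jitter`` is the +/- relative
    range within which each coefficient varies from probe to probe.
    """

    c_t: float = 100.0
    k_t: float = 0.5
    gamma_t: float = 3.0
    r0: float = 2.0
    r1: float = 1.2
    r2: float = 5.0
    probe_jitter: float = 0.01

    def __post_init__(self):
        if self.c_t <= 0 or self.k_t <= 0 or self.r1 <= 0:
            raise InvalidInputError("c_t, k_t and r1 must be > 0")
        if not 0 <= self.probe_jitter < 1:
            raise InvalidInputError("probe_jitter must be in [0, 1)")

    def jittered(self, rng: np.random.Generator) -> "ProbeModel":
        """An individual probe: each coefficient scaled by an independent
        factor drawn uniformly from 1 +/- probe_jitter."""
        j = self.probe_jitter

        def f():
            return 1.0 + rng.uniform(-j, j)

        return replace(
            self,
            c_t=self.c_t * f(), k_t=self.k_t * f(), gamma_t=self.gamma_t * f(),
            r0=self.r0 * f(), r1=self.r1 * f(), r2=self.r2 * f(),
        )


@dataclass
class NoiseModel:
    """Stochastic corruption of the probe channels and offline assay.

    ``mult_sd`` is the relative Gaussian noise SD applied to each channel
    per sample. Bubble artifacts occur per sample with probability
    ``spike_prob`` and multiply transmission by a factor drawn from
    ``spike_trans_range`` (a dip) and reflection by one from
    ``spike_refl_range`` (a flare — bubbles backscatter strongly).
    ``offline_sd`` is the absolute OD600 noise SD of the offline
    spectrophotometer reference (dilution series included).
    """

    mult_sd: float = 0.02
    spike_prob: float = 0.01
    spike_trans_range: tuple[float, float] = (0.6, 0.9)
    spike_refl_range: tuple[float, float] = (1.5, 2.5)
    offline_sd: float = 2.0

    def __post_init__(self):
        self.spike_trans_range = tuple(self.spike_trans_range)
        self.spike_refl_range = tuple(self.spike_refl_range)
        if min(self.mult_sd, self.spike_prob, self.offline_sd) < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")
        if self.spike_prob >= 1:
            raise InvalidInputError("spike_prob must be < 1")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(mult_sd=0.0, spike_prob=0.0, offline_sd=0.0)

    @property
    def is_noiseless(self) -> bool:
        return self.mult_sd == 0.0 and self.spike_prob == 0.0


@dataclass
class SimConfig:
    """Full parameterization of one simulated fermentation run.

    Times in hours, volumes in mL, biomass as OD600, glucose in g/L.
    ``yield_xs`` converts consumed glucose into OD (OD units per g/L).
    ``induce_at_od`` arms the simulator's own truth-based induction switch
    (closed-loop runs leave it None and let the controller decide).
    ``antifoam_od_bias``, when set, overrides the probe's ``gamma_t`` —
    it is a property of the antifoam stock in use, not of the probe.
    ``do_gain`` maps oxygen uptake (``mu * X``, OD/h) onto DO depression
    in % saturation points.
    """

    seed: int = 0
    dt: float = 30.0 / 3600.0
    waiting_h: float = 1.0
    duration_h: float = 20.0
    od0: float = 0.2
    mu_max: float = 0.6
    s0: float = 20.0
    ks: float = 0.1
    yield_xs: float = 1.25
    mu_set: float = 0.15
    induction_mu_factor: float = 0.8
    induce_at_od: float | None = None
    v0: float = 1500.0
    feed_rate0: float = 15.0
    s_exhaust: float = 0.05
    do_gain: float = 3.2
    do_spike_delta: float = 20.0
    do_spike_window: float = 0.1
    probe: ProbeModel = field(default_factory=ProbeModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    antifoam_schedule: list[tuple[float, float]] = field(default_factory=list)
    antifoam_od_bias: float | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if self.od0 < 0:
            raise InvalidInputError("od0 must be >= 0")
        if not self.mu_max > self.mu_set > 0:
            raise InvalidInputError("need mu_max > mu_set > 0")
        if self.v0 <= 0 or self.feed_rate0 < 0:
            raise InvalidInputError("volumes must be positive")
        if self.duration_h <= 0 or self.waiting_h < 0:
            raise InvalidInputError("durations must be positive")
        if any(b <= 0 for _, b in self.antifoam_schedule):
            raise InvalidInputError("antifoam boluses must be > 0 mL")

    @property
    def gamma_eff(self) -> float:
        return self.probe.gamma_t if self.antifoam_od_bias is None else self.antifoam_od_bias


# ---------------------------------------------------------------------------
# run container


@dataclass
class SimRun:
    """One simulated trajectory with its ground truth.

    ``records`` holds the (noisy) probe log in the canonical schema;
    ``truth`` the true OD600 and phase label per timestamp; ``offline``
    the reference samples; ``events`` the process/control event log.
    ``predictions`` is filled by closed-loop runs with the streaming
    inline-OD estimate at every timestamp.
    """

    config: SimConfig
    probe: ProbeModel
    records: pd.DataFrame
    truth: pd.DataFrame
    offline: pd.DataFrame
    events: list[ev.ControlEvent]
    predictions: np.ndarray | None = None

    @property
    def phase_labels(self) -> pd.Series:
        return self.truth["phase"]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time, e.kind, e.detail) for e in self.events],
            columns=["time_h", "event", "detail"],
        )


# ---------------------------------------------------------------------------
# stepper


class FermentationSimulator:
    """Explicit-step fermentation simulator.

    With ``auto=True`` the simulator switches phases itself: inoculation at
    ``waiting_h``, feed start when the DO exhaustion spike is detected, and
    induction when true OD crosses ``induce_at_od`` (if set). With
    ``auto=False`` only inoculation is automatic and an external controller
    must call :meth:`start_fedbatch` / :meth:`induce`; this is the mode the
    closed loop uses, mirroring a plant where the supervisory layer owns
    those decisions.

    Use :meth:`observe` to read the (noisy) probe record at the current
    time, :meth:`advance` to integrate one ``dt``, and :meth:`finish` to
    collect the assembled :class:`SimRun`.
    """

    def __init__(self, config: SimConfig, auto: bool = True):
        self.config = config
        self.probe = config.probe
        self.auto = auto
        self.rng = np.random.default_rng(config.seed)
        self.time = 0.0
        self._i = 0
        self.phase = "waiting"
        self.X = 0.0
        self.S = config.s0
        self.V = config.v0
        self.af_cum = 0.0
        self.t_feed: float | None = None
        self.events: list[ev.ControlEvent] = []
        self._schedule = deque(sorted(config.antifoam_schedule))
        self._do_hist: deque[tuple[float, float]] = deque()
        self._rows: list[tuple] = []
        self._truth: list[tuple] = []
        self._cached: dict | None = None
        self._finished = False

    # -- state transitions ----------------------------------------------

    def _log(self, kind: str, detail: str = "") -> None:
        # in manual (closed-loop) mode the external controller owns the
        # event log; logging here too would double-count every action
        if self.auto:
            self.events.append(ev.ControlEvent(self.time, kind, detail))

    def start_fedbatch(self, detail: str = "") -> None:
        if self.phase not in ("batch", "waiting"):
            raise InvalidInputError(f"cannot start feed from phase {self.phase!r}")
        self.phase = "fedbatch"
        self.t_feed = self.time
        self._log(ev.FEEDBATCH_START, detail or f"S={self.S:.3f} g/L")

    def induce(self, iptg_ml: float = 0.0, detail: str = "") -> None:
        if self.phase != "fedbatch":
            raise InvalidInputError(f"cannot induce from phase {self.phase!r}")
        self.phase = "induction"
        self.V += iptg_ml
        self._log(ev.IPTG_ADD, detail or f"true OD {self.X:.1f}, {iptg_ml:g} mL IPTG")

    def withdraw(self, volume_ml: float) -> None:
        """Remove culture (e.g. the automated before-induction sample)."""
        if volume_ml < 0 or volume_ml >= self.V:
            raise InvalidInputError("sample volume out of range")
        self.V -= volume_ml

    # -- per-step physics ------------------------------------------------

    def _mu(self) -> float:
        if self.phase == "batch":
            return self.config.mu_max * self.S / (self.config.ks + self.S)
        if self.phase == "fedbatch":
            return self.config.mu_set
        if self.phase == "induction":
            return self.config.mu_set * self.config.induction_mu_factor
        return 0.0

    def _channels(self) -> tuple[float, float, float]:
        """Noiseless (transmission, reflection, DO) at the current state."""
        cfg, pr = self.config, self.probe
        af_pct = 100.0 * self.af_cum / self.V
        od_app = self.X + cfg.gamma_eff * af_pct
        trans = pr.c_t / (1.0 + pr.k_t * od_app)
        refl = pr.r0 + pr.r1 * self.X + pr.r2 * af_pct
        do = 100.0 - cfg.do_gain * self._mu() * self.X
        do = min(100.0, max(5.0, do))
        return trans, refl, do

    def observe(self) -> dict:
        """Probe record at the current time (computed once per step)."""
        if self._cached is not None:
            return self._cached
        cfg = self.config

        # automatic, time-based transitions happen before sampling
        if self.phase == "waiting" and self.time >= cfg.waiting_h:
            self.phase = "batch"
            self.X = cfg.od0
        while self._schedule and self._schedule[0][0] <= self.time:
            _, bolus = self._schedule.popleft()
            self.af_cum += bolus
            self.V += bolus

        trans0, refl0, do0 = self._channels()

        if self.auto:
            self._auto_triggers(do0)

        trans, refl, do = trans0, refl0, do0
        noise = cfg.noise
        if not noise.is_noiseless:
            g = self.rng.normal(0.0, 1.0, size=3)
            trans *= 1.0 + noise.mult_sd * g[0]
            refl *= 1.0 + noise.mult_sd * g[1]
            do *= 1.0 + noise.mult_sd * g[2]
            if self.rng.random() < noise.spike_prob:
                trans *= self.rng.uniform(*noise.spike_trans_range)
                refl *= self.rng.uniform(*noise.spike_refl_range)
            trans = max(trans, 1e-6)
            refl = max(refl, 0.0)
            do = min(100.0, max(0.0, do))

        rec = {
            "time_h": self.time,
            "transmission": trans,
            "reflection": refl,
            "do_pct": do,
            "volume_ml": self.V,
            "antifoam_cum_ml": self.af_cum,
        }
        self._rows.append(tuple(rec[c] for c in PROBE_LOG_COLUMNS))
        self._truth.append((self.time, self.X, self.phase))
        self._cached = rec
        return rec

    def _auto_triggers(self, do_now: float) -> None:
        cfg = self.config
        if self.phase == "batch" and self.t_feed is None:
            self._do_hist.append((self.time, do_now))
            cutoff = self.time - cfg.do_spike_window
            while self._do_hist and self._do_hist[0][0] < cutoff:
                self._do_hist.popleft()
            do_min = min(d for _, d in self._do_hist)
            if do_now - do_min >= cfg.do_spike_delta:
                self.start_fedbatch(detail=f"DO spike +{do_now - do_min:.1f} pp")
        elif (
            self.phase == "fedbatch"
            and cfg.induce_at_od is not None
            and self.X >= cfg.induce_at_od
        ):
            self._log(ev.INDUCTION_TRIGGER, f"true OD {self.X:.1f}")
            self.induce()

    def advance(self) -> None:
        """Integrate the state over one ``dt`` (forward Euler)."""
        if self._cached is None:
            self.observe()  # keep the record grid complete
        cfg = self.config
        dt = cfg.dt
        if self.phase == "batch":
            mu = self._mu()
            dX = mu * self.X * dt
            dX = min(dX, self.S * cfg.yield_xs)  # cannot grow past the glucose
            self.X += dX
            self.S = max(0.0, self.S - dX / cfg.yield_xs)
        elif self.phase in ("fedbatch", "induction"):
            self.X += self._mu() * self.X * dt
            feed = cfg.feed_rate0 * math.exp(cfg.mu_set * (self.time - self.t_feed))
            self.V += feed * dt
        self.time = round((self._i + 1) * dt, 12)  # avoid cumulative float drift
        self._i += 1
        self._cached = None

    # -- assembly --------------------------------------------------------

    def finish(self, offline_times=()) -> SimRun:
        """Close the run, draw offline reference samples, assemble SimRun."""
        if self._finished:
            raise InvalidInputError("run already finished")
        self._finished = True
        cfg = self.config
        self._log(ev.HARVEST, f"true OD {self.X:.1f}")  # no-op in manual mode
        records = pd.DataFrame(self._rows, columns=list(PROBE_LOG_COLUMNS))
        truth = pd.DataFrame(self._truth, columns=["time_h", "od600", "phase"])

        offline_times = np.asarray(sorted(offline_times), dtype=float)
        if offline_times.size and (
            offline_times[0] < 0 or offline_times[-1] > self.time
        ):
            raise InvalidInputError("offline sample time outside run duration")
        od_true = np.interp(offline_times, truth["time_h"], truth["od600"])
        if cfg.noise.offline_sd > 0 and offline_times.size:
            od_obs = od_true + self.rng.normal(0.0, cfg.noise.offline_sd,
                                               size=od_true.size)
            od_obs = np.maximum(od_obs, 0.0)  # a spectrophotometer never reads < 0
        else:
            od_obs = od_true.copy()
        offline = pd.DataFrame({"time_h": offline_times, "od600": od_obs})
        return SimRun(config=cfg, probe=self.probe, records=records,
                      truth=truth, offline=offline, events=self.events)


def simulate_run(config: SimConfig, od_at_offline_times=()) -> SimRun:
    """Run one fully automatic simulation and return its :class:`SimRun`.

    ``od_at_offline_times`` lists the hours at which offline OD600
    reference samples are drawn (true OD plus offline assay noise).
    """
    times = list(od_at_offline_times)
    if times and (min(times) < 0 or max(times) > config.duration_h):
        raise InvalidInputError("offline sample time outside run duration")
    sim = FermentationSimulator(config, auto=True)
    n_steps = int(round(config.duration_h / config.dt))
    for _ in range(n_steps):
        sim.advance()
    sim.observe()  # final sample at duration_h
    return sim.finish(offline_times=times)


# ---------------------------------------------------------------------------
# training corpus


def generate_training_corpus(
    n_runs: int = 15,
    n_offline_total: int = 159,
    n_probes: int = 5,
    seed: int = 0,
    base_config: SimConfig | None = None,
    window: float = DEFAULT_MA_WINDOW,
):
    """Emulate a multi-run calibration campaign and return the paired
    feature/offline dataset ready for :class:`~fermsense.calibration.InlineODModel`.

    ``n_runs`` fermentations are simulated with per-probe jittered optical
    coefficients (runs assigned round-robin to ``n_probes`` probes) and two
    antifoam stocks alternating across runs: a concentrated stock dosed in
    small boluses with a strong optical bias, and a dilute stock dosed in
    larger boluses with a weak one. Induction targets are spread across
    runs so that true OD over the corpus spans 0 up to >= 140. Offline
    sampling avoids a simulated overnight gap (hours 3-14), mirroring how
    reference points cluster at the start and the morning after.

    Returns
    -------
    (pandas.DataFrame, list[SimRun])
        The calibration table with columns ``run_id, probe_id, time_h,
        inv_trans_ma, refl_ma, antifoam_pct, interaction, offline_od``
        (``n_offline_total`` rows), and the underlying runs.
    """
    if n_offline_total < n_runs:
        raise InvalidInputError("need at least one offline point per run")
    if n_probes < 1:
        raise InvalidInputError("need at least one probe")
    base = base_config if base_config is not None else SimConfig()
    rng = np.random.default_rng(seed)
    probes = [base.probe.jittered(rng) for _ in range(n_probes)]

    # (bolus mL, equivalent-OD bias per %vol): concentrated vs dilute stock
    stocks = [(2.0, 3.0), (6.0, 1.0)]
    od_batch_end = base.od0 + base.yield_xs * base.s0
    t_feed_est = base.waiting_h + math.log(od_batch_end / base.od0) / base.mu_max + 0.3
    targets = np.linspace(55.0, 120.0, n_runs)
    gap_start, gap_end = 3.0, 14.0  # overnight: no offline coverage

    counts = [n_offline_total // n_runs + (1 if r < n_offline_total % n_runs else 0)
              for r in range(n_runs)]
    rows, runs = [], []
    for r in range(n_runs):
        probe_idx = r % n_probes
        bolus, bias = stocks[r % 2]
        target = float(targets[r])
        t_ind_est = t_feed_est + math.log(target / od_batch_end) / base.mu_set
        duration = t_ind_est + 2.5
        schedule = [(t, bolus) for t in np.arange(t_feed_est + 0.5, duration - 0.3, 1.5)]
        cfg = replace(
            base,
            seed=int(rng.integers(2**31)),
            duration_h=duration,
            induce_at_od=target,
            probe=probes[probe_idx],
            antifoam_schedule=schedule,
            antifoam_od_bias=bias,
        )
        early = (0.25, min(gap_start, duration - 0.1))
        late = (gap_end, duration - 0.1)
        w_early = max(early[1] - early[0], 0.0)
        w_late = max(late[1] - late[0], 0.0)
        p_early = w_early / (w_early + w_late)
        n_r = counts[r]
        in_early = rng.random(n_r) < p_early
        times = np.where(
            in_early,
            rng.uniform(early[0], early[1], n_r),
            rng.uniform(late[0], late[1], n_r),
        )
        run = simulate_run(cfg, od_at_offline_times=times)
        runs.append(run)

        feats = featurize_log(run.records, window=window)
        # nearest record on the regular dt grid
        idx = np.clip(np.round(run.offline["time_h"].to_numpy() / cfg.dt)
                      .astype(int), 0, len(feats) - 1)
        for k, (t_off, od_off) in enumerate(
            zip(run.offline["time_h"], run.offline["od600"])
        ):
            frow = feats.iloc[idx[k]]
            rows.append((
                f"run{r:02d}", f"probe{probe_idx}", float(t_off),
                frow["inv_trans_ma"], frow["refl_ma"],
                frow["antifoam_pct"], frow["interaction"], float(od_off),
            ))

    corpus = pd.DataFrame(
        rows,
        columns=["run_id", "probe_id", "time_h", "inv_trans_ma", "refl_ma",
                 "antifoam_pct", "interaction", "offline_od"],
    )
    return corpus, runs
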