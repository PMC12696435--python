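"""Automated induction logic and the hardware-free closed loop.

The controller reproduces the supervisory logic of an automated
fermentation: before the feed starts it watches dissolved oxygen for the
glucose-exhaustion spike (a sharp rise above the recent trailing minimum)
and starts the fed-batch; afterwards it watches the streaming inline-OD
prediction and, once the prediction has held at or above the induction
target for ``debounce_n`` consecutive evaluations, it fires the induction
sequence — withdraw the before-induction (BI) verification sample, then add
the pre-determined IPTG volume. All triggers are single-shot (latched), so
a closed-loop run needs exactly two manual touches: inoculation and
harvest.

The debounce requirement is a noise guard: a single bubble-induced spike in
the prediction must not induce a reactor. ``debounce_n = 1`` recovers the
bare threshold rule.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import events as ev
from .calibration import ODModelSpec, predict_od
from .exceptions import ClosedRunError, InvalidInputError
from .signals import DEFAULT_MA_WINDOW, StreamingMovingAverage, build_features
from .simulate import FermentationSimulator, SimConfig, SimRun


@dataclass
class ControlConfig:
    """Tunables of the induction controller.

    ``od_target`` is the inline OD600 threshold for induction;
    ``debounce_n`` the number of consecutive at-or-above-target evaluations
    required. ``control_dt`` (hours) thins the evaluation rate below the
    sampling rate; None evaluates every sample. ``adjust_hook`` is an
    optional callback run between the BI sample and the IPTG addition —
    the slot where a plant would adjust culture conditions before
    induction; default is a no-op.
    """

    od_target: float
    debounce_n: int = 3
    control_dt: float | None = None
    bi_sample_ml: float = 10.0
    iptg_ml: float = 5.0
    do_spike_delta: float = 20.0
    do_spike_window: float = 0.1
    adjust_hook: Callable[[float], None] | None = None

    def __post_init__(self):
        if self.od_target <= 0:
            raise InvalidInputError("od_target must be > 0")
        if self.debounce_n < 1:
            raise InvalidInputError("debounce_n must be >= 1")
        if self.bi_sample_ml < 0 or self.iptg_ml < 0:
            raise InvalidInputError("volumes must be >= 0")
        if self.control_dt is not None and self.control_dt <= 0:
            raise InvalidInputError("control_dt must be > 0")


@dataclass
class ControllerState:
    """Mutable controller memory (exposed for inspection/logging)."""

    feed_started: bool = False
    induced: bool = False
    closed: bool = False
    counter: int = 0
    last_time: float = -np.inf
    last_eval: float | None = None
    do_hist: deque = field(default_factory=deque)


class InductionController:
    """Single-run, single-shot induction state machine.

    Call :meth:`step` once per evaluation with the current time, inline-OD
    prediction and DO reading; it returns the (possibly empty) list of
    events fired at that timestamp. Call :meth:`close` at harvest; stepping
    a closed run raises :class:`~fermsense.exceptions.ClosedRunError`.
    """

    def __init__(self, config: ControlConfig, assume_feed_started: bool = False):
        self.config = config
        self.state = ControllerState(feed_started=assume_feed_started)
        self.events: list[ev.ControlEvent] = []

    def _emit(self, time: float, kind: str, detail: str = "") -> ev.ControlEvent:
        e = ev.ControlEvent(time, kind, detail)
        self.events.append(e)
        return e

    def step(self, time: float, inline_od: float, do_pct: float) -> list[ev.ControlEvent]:
        cfg, st = self.config, self.state
        if st.closed:
            raise ClosedRunError("controller stepped after harvest")
        if time <= st.last_time:
            raise InvalidInputError("controller call times must be increasing")
        st.last_time = time

        if cfg.control_dt is not None and st.last_eval is not None:
            if time < st.last_eval + cfg.control_dt - 1e-12:
                return []
        st.last_eval = time

        fired: list[ev.ControlEvent] = []
        if not st.feed_started:
            # trailing DO minimum over the spike window
            st.do_hist.append((time, do_pct))
            cutoff = time - cfg.do_spike_window
            while st.do_hist and st.do_hist[0][0] < cutoff:
                st.do_hist.popleft()
            do_min = min(d for _, d in st.do_hist)
            if do_pct - do_min >= cfg.do_spike_delta:
                st.feed_started = True
                fired.append(self._emit(
                    time, ev.FEEDBATCH_START, f"DO spike +{do_pct - do_min:.1f} pp"))
        elif not st.induced:
            if inline_od >= cfg.od_target:
                st.counter += 1
            else:
                st.counter = 0
            if st.counter >= cfg.debounce_n:
                st.induced = True
                fired.append(self._emit(
                    time, ev.INDUCTION_TRIGGER,
                    f"inline OD {inline_od:.1f} >= target {cfg.od_target:g} "
                    f"for {cfg.debounce_n} evaluations"))
                fired.append(self._emit(
                    time, ev.BI_SAMPLE, f"{cfg.bi_sample_ml:g} mL, stored 2-8 C"))
                if cfg.adjust_hook is not None:
                    cfg.adjust_hook(time)
                fired.append(self._emit(
                    time, ev.IPTG_ADD, f"{cfg.iptg_ml:g} mL IPTG"))
        # after induction: inert
        return fired

    def close(self, time: float) -> ev.ControlEvent:
        if self.state.closed:
            raise ClosedRunError("run already closed")
        self.state.closed = True
        return self._emit(time, ev.HARVEST, "run end")


def run_closed_loop(
    sim_config: SimConfig,
    model: "ODModelSpec | object",
    control: ControlConfig,
    window: float = DEFAULT_MA_WINDOW,
) -> SimRun:
    """Co-simulate fermentation, streaming soft sensor, and controller.

    The simulator runs with its automatic phase switching disabled; every
    sample is smoothed incrementally, featurized, pushed through the
    calibration model, and handed to the controller, whose events drive the
    simulation (feed start, BI sample withdrawal, IPTG addition + phase
    switch). Returns the full :class:`SimRun` with ``predictions`` filled
    and the controller's event log attached.
    """
    spec: ODModelSpec = getattr(model, "spec", model)
    if not isinstance(spec, ODModelSpec):
        raise InvalidInputError("model must be an ODModelSpec or fitted results")

    sim = FermentationSimulator(sim_config, auto=False)
    ma_t = StreamingMovingAverage(window)
    ma_r = StreamingMovingAverage(window)
    ctrl = InductionController(control)
    preds: list[float] = []

    n_steps = int(round(sim_config.duration_h / sim_config.dt))
    for i in range(n_steps + 1):
        rec = sim.observe()
        t = rec["time_h"]
        trans_ma = ma_t.update(t, rec["transmission"])
        refl_ma = ma_r.update(t, rec["reflection"])
        feats = build_features(trans_ma, refl_ma,
                               rec["antifoam_cum_ml"], rec["volume_ml"])
        od_hat = predict_od(spec, feats)
        preds.append(od_hat)
        for e in ctrl.step(t, od_hat, rec["do_pct"]):
            if e.kind == ev.FEEDBATCH_START:
                sim.start_fedbatch(detail=e.detail)
            elif e.kind == ev.BI_SAMPLE:
                sim.withdraw(control.bi_sample_ml)
            elif e.kind == ev.IPTG_ADD:
                sim.induce(iptg_ml=control.iptg_ml, detail=e.detail)
        if i < n_steps:
            sim.advance()

    ctrl.close(sim.time)
    run = sim.finish()
    run.events = list(ctrl.events)
    run.predictions = np.asarray(preds)
    return run
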