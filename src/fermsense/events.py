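"""Timestamped control/process events shared by the simulator and controller."""

from __future__ import annotations

from dataclasses import dataclass

FEEDBATCH_START = "FEEDBATCH_START"
INDUCTION_TRIGGER = "INDUCTION_TRIGGER"
BI_SAMPLE = "BI_SAMPLE"
IPTG_ADD = "IPTG_ADD"
HARVEST = "HARVEST"

EVENT_KINDS = (FEEDBATCH_START, INDUCTION_TRIGGER, BI_SAMPLE, IPTG_ADD, HARVEST)


@dataclass(frozen=True)
class ControlEvent:
    """One timestamped action taken on (or by) the fermentation run.

    Parameters
    ----------
    time : float
        Hours since run start.
    kind : str
        One of :data:`EVENT_KINDS`.
    detail : str
        Free text — volumes moved, predicted OD at trigger, etc.
    """

    time: float
    kind: str
    detail: str = ""

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
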