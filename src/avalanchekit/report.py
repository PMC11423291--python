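"""Report schema for one analysed recording or simulation.

A :class:`RecordingReport` summarises one analysed dataset: per-state
exponents and family, plus the state-duration and ISI summaries.  The
pydantic models double as the published JSON schema
(``schemas/recording_report.schema.json``); a test keeps the shipped file
in sync with ``RecordingReport.model_json_schema()``.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict


class StateResult(BaseModel):
    """Avalanche statistics of one state (up or down)."""

    model_config = ConfigDict(extra="forbid")

    state: str
    family: str  # "power_law" | "exponential_like" | "undefined"
    n_avalanches: dict[int, int]
    tau: float | None = None
    tau_unc: float | None = None
    alpha: float | None = None
    alpha_unc: float | None = None
    beta_S: float | None = None
    beta_S_unc: float | None = None
    beta_T: float | None = None
    beta_T_unc: float | None = None
    gamma: float | None = None
    gamma_unc: float | None = None
    size_fit: dict | None = None
    duration_fit: dict | None = None
    scaling_relation: dict | None = None
    beta_relation: dict | None = None


class RecordingReport(BaseModel):
    """Full per-recording analysis output."""

    model_config = ConfigDict(extra="forbid")

    label: str
    seed: int
    n_neurons: int
    duration_s: float
    frame_interval_s: float
    state_durations: dict
    isi: dict
    up: StateResult
    down: StateResult
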