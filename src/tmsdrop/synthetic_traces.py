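"""Synthetic two-channel droplet fluorescence traces.

Stands in for the raw time-lapse movies: every droplet contributes a green
reference trace (Atto 488-like dye supplied with the invader solution, so
its intensity is proportional to the mixing ratio xi and constant in time)
and a red reporter trace (ROX-like dye unquenched as displacement proceeds).

Noise model: one multiplicative per-frame factor shared by both channels
(illumination/focus fluctuation — the component that reference
normalization cancels) plus independent additive read noise per channel.
QC-relevant artifacts can be injected with ground-truth labels: inverted
(negative-slope) traces, step-like intensity jumps, and an out-of-focus
proxy (attenuated, noisier droplets).

Trace tables and their ground-truth sidecars are plain CSV; analysis
operations only ever see the trace table, keeping them blind to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compartments import DropletSpec
from .errors import InputError, ParseError
from .kinetics import MAX_NU, RateParameters, closed_form_conversion
from .seeding import substream

__all__ = [
    "AcquisitionConfig",
    "NoiseModel",
    "ArtifactSpec",
    "TraceTruth",
    "DropletTrace",
    "GREEN_FULL_SCALE",
    "DEFAULT_BACKGROUND",
    "simulate_trace_set",
    "inject_artifacts",
    "write_trace_table",
    "read_trace_table",
]

GREEN_FULL_SCALE = 200.0  # n.u. of reference dye at xi = 1 (1 uM Atto 488 proxy)
DEFAULT_BACKGROUND = 10.0  # n.u., imperfect quenching of the intact reporter
DEFAULT_FULL_SCALE_CONC = 200e-9  # M product mapping to MAX_NU


@dataclass(frozen=True)
class AcquisitionConfig:
    """Time-lapse acquisition grid.

    ``start_time`` is the first usable frame after the droplet flow stops
    (a few seconds after generation); the default 2 s frame interval over
    300 frames covers both slope windows and most of the reaction.
    """

    frame_interval: float = 2.0  # s
    start_time: float = 4.0  # s
    n_frames: int = 300
    reference_conc: float = 1e-6  # M reference dye in the invader stock

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InputError("frame_interval must be positive")
        if self.n_frames < 2:
            raise InputError("n_frames must be >= 2")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class NoiseModel:
    """Additive (per channel) and multiplicative (shared) intensity noise."""

    additive_sd: float = 1.0  # n.u.
    multiplicative_sd: float = 0.02  # fraction, common-mode across channels

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise InputError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Fractions of droplets receiving each QC artifact (disjoint)."""

    frac_negative_slope: float = 0.0
    frac_jump: float = 0.0
    frac_out_of_focus: float = 0.0
    jump_magnitude: float = 0.5  # relative step height

    def __post_init__(self) -> None:
        fracs = (self.frac_negative_slope, self.frac_jump, self.frac_out_of_focus)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise InputError("artifact fractions must be >= 0 and sum to <= 1")


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth recorded at simulation time (test harness use only)."""

    xi: float
    k_eff: float  # M^-1 s^-1
    artifact: str = "none"  # none | negative_slope | jump | out_of_focus


@dataclass(frozen=True)
class DropletTrace:
    """Two-channel intensity time series for one tracked droplet."""

    droplet_id: str
    times: np.ndarray  # s, strictly increasing
    green: np.ndarray  # n.u., reference channel
    red: np.ndarray  # n.u., reporter channel
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.green) == len(self.red)):
            raise InputError("times, green and red must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")


def simulate_trace_set(
    emulsion: Sequence[DropletSpec],
    params: RateParameters,
    acq: AcquisitionConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    background: float = DEFAULT_BACKGROUND,
    full_scale_conc: float = DEFAULT_FULL_SCALE_CONC,
) -> list[DropletTrace]:
    """Simulate two-channel traces for every droplet of an emulsion.

    Red channel: exact bimolecular trajectory at k_eff = rate_factor * k
    from ([I]0, [R]0) = (conc_invader, conc_reporter), converted to n.u.
    Green channel: constant xi * GREEN_FULL_SCALE.  The same per-frame
    multiplicative factor perturbs both channels; additive noise is drawn
    independently per channel.
    """
    if not emulsion:
        raise InputError("emulsion must be non-empty")
    acq = acq or AcquisitionConfig()
    noise = noise or NoiseModel()
    rng = substream(seed, "noise")
    times = acq.times

    k_eff = np.array([d.rate_factor * params.k for d in emulsion])
    i0 = np.array([d.conc_invader for d in emulsion])
    r0 = np.array([d.conc_reporter for d in emulsion])
    xi = np.array([d.xi for d in emulsion])

    # vectorized closed-form product concentration, droplets x frames
    conc_f = np.empty((len(emulsion), times.size))
    for j, d in enumerate(emulsion):
        conc_f[j] = closed_form_conversion(float(k_eff[j]), float(i0[j]),
                                           float(r0[j]), times)
    red = background + MAX_NU * conc_f / full_scale_conc
    green = np.repeat((xi * GREEN_FULL_SCALE)[:, None], times.size, axis=1)

    if noise.multiplicative_sd > 0:
        m = rng.normal(1.0, noise.multiplicative_sd, size=red.shape)
        red = red * m
        green = green * m
    if noise.additive_sd > 0:
        red = red + rng.normal(0.0, noise.additive_sd, size=red.shape)
        green = green + rng.normal(0.0, noise.additive_sd, size=green.shape)

    return [
        DropletTrace(
            droplet_id=d.id,
            times=times.copy(),
            green=green[j],
            red=red[j],
            truth=TraceTruth(xi=float(xi[j]), k_eff=float(k_eff[j])),
        )
        for j, d in enumerate(emulsion)
    ]


def inject_artifacts(
    traces: Sequence[DropletTrace], spec: ArtifactSpec, seed: int = 0
) -> list[DropletTrace]:
    """Return a copy of the trace set with QC artifacts injected.

    Disjoint random subsets get exactly one artifact each:

    * ``negative_slope`` — red trace mirrored about its first frame, so its
      slope is the negative of the original.
    * ``jump`` — all frames after a random interior frame (middle 60% of the
      acquisition) scaled by (1 + jump_magnitude) in the red channel.
    * ``out_of_focus`` — both channels attenuated to 30% and given extra
      additive noise (blur proxy).
    """
    rng = substream(seed, "artifacts")
    n = len(traces)
    order = rng.permutation(n)
    n_neg = int(round(spec.frac_negative_slope * n))
    n_jump = int(round(spec.frac_jump * n))
    n_oof = int(round(spec.frac_out_of_focus * n))
    groups = {
        "negative_slope": set(order[:n_neg].tolist()),
        "jump": set(order[n_neg : n_neg + n_jump].tolist()),
        "out_of_focus": set(order[n_neg + n_jump : n_neg + n_jump + n_oof].tolist()),
    }

    out: list[DropletTrace] = []
    for j, tr in enumerate(traces):
        red, green = tr.red.copy(), tr.green.copy()
        label = "none"
        if j in groups["negative_slope"]:
            red = 2.0 * red[0] - red
            label = "negative_slope"
        elif j in groups["jump"]:
            lo = int(0.2 * red.size)
            hi = max(lo + 1, int(0.8 * red.size))
            cut = int(rng.integers(lo, hi))
            red[cut:] *= 1.0 + spec.jump_magnitude
            label = "jump"
        elif j in groups["out_of_focus"]:
            red = 0.3 * red + rng.normal(0.0, 2.0, red.size)
            green = 0.3 * green + rng.normal(0.0, 2.0, green.size)
            label = "out_of_focus"
        truth = replace(tr.truth, artifact=label) if tr.truth else None
        out.append(
            DropletTrace(tr.droplet_id, tr.times.copy(), green, red, truth)
        )
    return out


_TRACE_COLUMNS = ["droplet_id", "frame", "time_s", "green_nu", "red_nu"]


def write_trace_table(
    traces: Sequence[DropletTrace],
    path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write traces as long-format CSV (6 significant digits).

    Ground truth, when present, goes to a separate sidecar CSV so analysis
    can be run blind on the trace table alone.
    """
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "droplet_id": tr.droplet_id,
                    "frame": np.arange(tr.times.size),
                    "time_s": tr.times,
                    "green_nu": tr.green,
                    "red_nu": tr.red,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )
    if truth_path is not None:
        pd.DataFrame(
            {
                "droplet_id": [tr.droplet_id for tr in traces],
                "xi_true": [tr.truth.xi if tr.truth else np.nan for tr in traces],
                "k_eff": [tr.truth.k_eff if tr.truth else np.nan for tr in traces],
                "artifact": [tr.truth.artifact if tr.truth else "" for tr in traces],
            }
        ).to_csv(truth_path, index=False, float_format="%.6g")


def read_trace_table(
    path: str | Path, truth_path: str | Path | None = None
) -> list[DropletTrace]:
    """Read a trace-table CSV (and optional truth sidecar) back into traces."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface pandas detail
        raise ParseError(f"cannot parse trace table {path}: {exc}") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"trace table {path} is missing columns: {missing}")

    truth_by_id: dict[str, TraceTruth] = {}
    if truth_path is not None:
        tdf = pd.read_csv(truth_path)
        for _, row in tdf.iterrows():
            truth_by_id[str(row["droplet_id"])] = TraceTruth(
                xi=float(row["xi_true"]),
                k_eff=float(row["k_eff"]),
                artifact=str(row["artifact"]),
            )

    traces = []
    for droplet_id, grp in df.groupby("droplet_id", sort=False):
        grp = grp.sort_values("frame")
        traces.append(
            DropletTrace(
                droplet_id=str(droplet_id),
                times=grp["time_s"].to_numpy(float),
                green=grp["green_nu"].to_numpy(float),
                red=grp["red_nu"].to_numpy(float),
                truth=truth_by_id.get(str(droplet_id)),
            )
        )
    return traces
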