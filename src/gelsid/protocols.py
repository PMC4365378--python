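"""Synthetic mechanical-test protocols and datasets.

Generates the input waveforms of a desk-top materials tester operating in
unconfined compression — constant-speed ramps, triangular strain cycles and
step-relaxation holds — and full synthetic datasets (model output plus
additive Gaussian load noise) standing in for real load-cell records.

Protocol descriptors are written the way an operator programs the machine:
crosshead speed in mm/min and *magnitudes* of engineering strain.  The
conversion to the signed internal strain happens when a model input is
built from the resulting :class:`~gelsid.kinematics.KinematicSignal`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .kinematics import KinematicSignal
from . import models as _m

__all__ = [
    "ProtocolSpec",
    "TimeSeriesDataset",
    "make_ramp",
    "make_cycles",
    "make_step_relaxation",
    "make_signal",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
    "DatasetParseError",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Descriptor of one mechanical test.

    kind is one of 'ramp', 'cycles', 'step_relaxation'.  Strains are
    engineering-strain magnitudes (fractions); speeds are crosshead speeds in
    mm/min; sample_rate in Hz; e0 (mm) and A0 (mm^2) describe the sample.
    """

    kind: str
    crosshead_speed: float = 1.0
    target_strain: float = 0.2
    cycle_bounds: tuple = (0.15, 0.25)
    n_cycles: int = 8
    hold_duration: float = 1800.0
    sample_rate: float = 10.0
    e0: float = 5.0
    A0: float = 700.0

    def __post_init__(self):
        if self.kind not in ("ramp", "cycles", "step_relaxation"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not self.crosshead_speed > 0:
            raise ValueError("crosshead speed must be positive")
        if not self.sample_rate > 0:
            raise ValueError("sample rate must be positive")
        lo, hi = self.cycle_bounds
        if not (0 <= lo <= hi < 1):
            raise ValueError("cycle bounds must satisfy 0 <= low <= high < 1")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if not (0 <= self.target_strain < 1):
            raise ValueError("target strain must lie in [0, 1)")
        if self.hold_duration < 0:
            raise ValueError("hold duration must be non-negative")


def _grid_from_breakpoints(tb, eb, rate):
    """Uniformly sampled grid containing every phase boundary exactly.

    Each phase of duration d is subdivided into max(1, round(d*rate)) equal
    steps, so the grid is exactly uniform whenever the durations are
    multiples of the sample period (true for the default protocols) and
    piecewise uniform otherwise, with breakpoints always on-grid.
    """
    ts = [np.array([tb[0]])]
    for a, b in zip(tb[:-1], tb[1:]):
        d = b - a
        if d <= 0:
            continue
        n = max(1, round(d * rate))
        ts.append(a + d * np.arange(1, n + 1) / n)
    t = np.concatenate(ts)
    e = np.interp(t, tb, eb)
    return t, e


def make_ramp(spec: ProtocolSpec) -> KinematicSignal:
    """Constant-speed compression ramp from e0 to (1 - target_strain)*e0."""
    if spec.kind != "ramp":
        raise ValueError("spec.kind must be 'ramp'")
    v = spec.crosshead_speed / 60.0  # mm/s
    travel = spec.e0 * spec.target_strain
    if travel == 0.0:
        return KinematicSignal(t=np.array([0.0]), e=np.array([spec.e0]), e0=spec.e0)
    T = travel / v
    t, e = _grid_from_breakpoints([0.0, T], [spec.e0, spec.e0 - travel], spec.sample_rate)
    return KinematicSignal(t=t, e=e, e0=spec.e0)


def make_cycles(spec: ProtocolSpec) -> KinematicSignal:
    """Approach ramp to the mean of the cycle bounds, then triangular cycles.

    Each cycle runs mean -> high -> low -> mean at the crosshead speed, so a
    record holds exactly n_cycles local maxima of compression magnitude after
    the approach, and the cycling phase lasts n_cycles * 2*(high-low)*e0/v.
    """
    if spec.kind != "cycles":
        raise ValueError("spec.kind must be 'cycles'")
    lo, hi = spec.cycle_bounds
    mean = 0.5 * (lo + hi)
    v = spec.crosshead_speed / 60.0
    e_mean = spec.e0 * (1.0 - mean)
    e_hi = spec.e0 * (1.0 - hi)   # deepest compression
    e_lo = spec.e0 * (1.0 - lo)
    tb = [0.0]
    eb = [spec.e0]

    def _seg(e_next):
        d = abs(e_next - eb[-1]) / v
        if d > 0:
            tb.append(tb[-1] + d)
            eb.append(e_next)

    _seg(e_mean)
    for _ in range(spec.n_cycles):
        _seg(e_hi)
        _seg(e_lo)
        _seg(e_mean)
    t, e = _grid_from_breakpoints(tb, eb, spec.sample_rate)
    return KinematicSignal(t=t, e=e, e0=spec.e0)


def make_step_relaxation(spec: ProtocolSpec) -> KinematicSignal:
    """Fast ramp to the final strain, then a constant hold of hold_duration."""
    if spec.kind != "step_relaxation":
        raise ValueError("spec.kind must be 'step_relaxation'")
    v = spec.crosshead_speed / 60.0
    travel = spec.e0 * spec.target_strain
    e_final = spec.e0 - travel
    T_ramp = travel / v
    tb = [0.0]
    eb = [spec.e0]
    if T_ramp > 0:
        tb.append(T_ramp)
        eb.append(e_final)
    if spec.hold_duration > 0:
        tb.append(tb[-1] + spec.hold_duration)
        eb.append(e_final)
    t, e = _grid_from_breakpoints(tb, eb, spec.sample_rate)
    return KinematicSignal(t=t, e=e, e0=spec.e0)


_MAKERS = {
    "ramp": make_ramp,
    "cycles": make_cycles,
    "step_relaxation": make_step_relaxation,
}


def make_signal(spec: ProtocolSpec) -> KinematicSignal:
    """Dispatch to the maker for spec.kind."""
    return _MAKERS[spec.kind](spec)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesDataset:
    """Paired input/output record {t_k, eps(t_k), y(t_k)} with provenance.

    eps is the signed strain (e - e0)/e (negative in compression); y is the
    measured load in N.  meta records the sample label, geometry, protocol,
    generating model and noise descriptor, so that a dataset is regenerable
    from its metadata (same seed -> identical record).
    """

    t: np.ndarray
    eps: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.eps.shape == self.y.shape):
            raise ValueError("t, eps, y must have equal shapes")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def e0(self) -> float:
        return float(self.meta.get("e0", 5.0))

    @property
    def A0(self) -> float:
        return float(self.meta.get("A0", 700.0))

    @property
    def extension(self) -> np.ndarray:
        """Extension e = e0/(1 - eps), mm."""
        return self.e0 / (1.0 - self.eps)

    def kinematics(self) -> KinematicSignal:
        return KinematicSignal(t=self.t, e=self.extension, e0=self.e0)

    @property
    def label(self) -> str:
        return str(self.meta.get("label", ""))

    def __len__(self) -> int:
        return self.t.size


def _simulate(model: str, params, kin: KinematicSignal):
    if model == "linear":
        tf = params if isinstance(params, _m.LinearTF) else _m.maxwell_to_tf(**params)
        return _m.simulate_lti(tf, kin.eps, kin.t).y
    if model in ("model1", "model1_neohookean"):
        if not isinstance(params, _m.Model1Params):
            params = _m.Model1Params(**params)
        if model == "model1_neohookean" and params.C2 != 0.0:
            raise ValueError("Neo Hookean variant requires C2 = 0")
        return _m.simulate_model1(params, kin).y
    if model == "hammerstein":
        if not isinstance(params, _m.Model2Params):
            params = _m.Model2Params(**params)
        return _m.simulate_hammerstein(params, kin).y
    raise ValueError(f"unknown model {model!r}")


def generate_dataset(
    model: str,
    params,
    spec: ProtocolSpec,
    noise_sd: Optional[float] = None,
    relative_noise: Optional[float] = None,
    seed: Optional[int] = None,
    label: str = "",
) -> TimeSeriesDataset:
    """Simulate ``model`` on the protocol signal and add Gaussian load noise.

    Exactly one of noise_sd (absolute, N) or relative_noise (fraction of the
    clean peak |y|) may be given; omitting both means a noise-free record.
    Noise is i.i.d. zero-mean on the load only — the strain is machine-
    commanded and treated as exact.  The same seed reproduces the dataset
    bit for bit.
    """
    if noise_sd is not None and relative_noise is not None:
        raise ValueError("give either noise_sd or relative_noise, not both")
    kin = make_signal(spec)
    y_clean = _simulate(model, params, kin)
    if relative_noise is not None:
        noise_sd = relative_noise * float(np.max(np.abs(y_clean)))
    if noise_sd is None:
        noise_sd = 0.0
    if noise_sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    y = y_clean.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y_clean + rng.normal(0.0, noise_sd, size=y_clean.shape)
    params_dict = asdict(params) if hasattr(params, "__dataclass_fields__") else dict(params)
    meta = {
        "label": label,
        "model": model,
        "params": params_dict,
        "protocol": asdict(spec),
        "noise_sd": float(noise_sd),
        "seed": seed,
        "e0": spec.e0,
        "A0": spec.A0,
    }
    return TimeSeriesDataset(t=kin.t, eps=kin.eps, y=y, meta=meta)


# ---------------------------------------------------------------------------
# CSV round trip: '# key = value' metadata header, columns time_s,strain,load_N
# ---------------------------------------------------------------------------


class DatasetParseError(ValueError):
    """Malformed dataset file; message names the offending line/column."""


def write_dataset(dataset: TimeSeriesDataset, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for key, value in dataset.meta.items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        fh.write("time_s,strain,load_N\n")
        for ti, ei, yi in zip(dataset.t, dataset.eps, dataset.y):
            fh.write(f"{float(ti)!r},{float(ei)!r},{float(yi)!r}\n")


def read_dataset(path) -> TimeSeriesDataset:
    meta: dict = {}
    t, eps, y = [], [], []
    with open(path, "r", newline="") as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise DatasetParseError(f"line {lineno}: metadata line without '='")
            key, _, value = body.partition("=")
            try:
                meta[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["time_s", "strain", "load_N"]:
                raise DatasetParseError(
                    f"line {lineno}: expected header 'time_s,strain,load_N', got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise DatasetParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        row = []
        for col, part in enumerate(parts, start=1):
            try:
                row.append(float(part))
            except ValueError:
                raise DatasetParseError(
                    f"line {lineno}, column {col}: not a number: {part!r}"
                ) from None
        t.append(row[0])
        eps.append(row[1])
        y.append(row[2])
    if not header_seen:
        raise DatasetParseError("missing column header 'time_s,strain,load_N'")
    return TimeSeriesDataset(t=np.array(t), eps=np.array(eps), y=np.array(y), meta=meta)
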