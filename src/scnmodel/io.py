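"""File formats: trace files (text and binary), parameter files, ABF import, run configs.

Canonical units everywhere: mV / pA / nS / pF / ms (self-consistent:
pF*mV/ms = pA = nS*mV).  Importers normalize at the boundary.  The text
trace format is comment-headed delimited text for human diffability; the
binary container (.npz) is the exact-precision alternative.  Every column
name carries its unit.
"""

from __future__ import annotations

import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model_core import GateKinetics, ModelParameters, GATE_NAMES
from .simulation import SimulatedTrace, StimulusProtocol

__all__ = [
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "read_params",
    "write_params",
    "import_abf",
    "RunConfig",
]


class TraceFormatError(ValueError):
    """Malformed trace file; message carries a line number where known."""


# ---------------------------------------------------------------------------
# Trace files
# ---------------------------------------------------------------------------

_TRACE_MAGIC = "# scnmodel-trace v1"


def _protocol_to_str(proto: StimulusProtocol) -> str:
    segs = ";".join(f"{float(o)!r}:{float(d)!r}:{float(a)!r}" for o, d, a in proto.segments)
    return (f"name={proto.name}|baseline_pA={float(proto.baseline_pA)!r}"
            f"|total_ms={float(proto.total_duration_ms)!r}|segments={segs}")


def _protocol_from_str(s: str) -> StimulusProtocol:
    fields = dict(part.split("=", 1) for part in s.split("|"))
    segs = tuple(tuple(float(x) for x in seg.split(":"))
                 for seg in fields["segments"].split(";") if seg)
    return StimulusProtocol(fields["name"], float(fields["baseline_pA"]),
                            segs, float(fields["total_ms"]))


def write_trace(path: str | Path, trace: SimulatedTrace,
                fmt: Optional[str] = None) -> None:
    """Write a trace as delimited text (.txt/.tsv) or binary (.npz).

    Text is value-preserving to <= 1e-9 relative (repr floats); the binary
    container round-trips exactly.
    """
    path = Path(path)
    fmt = fmt or ("npz" if path.suffix == ".npz" else "text")
    extra = {}
    if trace.gates:
        extra.update({f"gate_{k}": v for k, v in trace.gates.items()})
    if trace.currents:
        extra.update({f"{k}_{'nS' if k.startswith('G_') else 'pA'}": v
                      for k, v in trace.currents.items()})
    if fmt == "npz":
        payload = {"time_ms": trace.t_ms, "voltage_mV": trace.V_mV,
                   "current_pA": trace.I_app_pA, **extra}
        meta = {k: v for k, v in trace.meta.items() if isinstance(v, (str, int, float))}
        if trace.protocol is not None:
            meta["protocol"] = _protocol_to_str(trace.protocol)
        np.savez(path, __meta__=np.array(yaml.safe_dump(meta)), **payload)
        return
    with open(path, "w") as fh:
        fh.write(_TRACE_MAGIC + "\n")
        dt = trace.dt_ms
        fh.write(f"# dt_ms: {dt!r}\n")
        if trace.protocol is not None:
            fh.write(f"# protocol: {_protocol_to_str(trace.protocol)}\n")
        for k, v in trace.meta.items():
            if isinstance(v, (str, int, float)):
                fh.write(f"# meta {k}={v}\n")
        cols = ["time_ms", "voltage_mV", "current_pA"] + list(extra)
        fh.write("\t".join(cols) + "\n")
        arrays = [trace.t_ms, trace.V_mV, trace.I_app_pA] + list(extra.values())
        for row in zip(*arrays):
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_trace(path: str | Path) -> SimulatedTrace:
    """Read a trace file written by :func:`write_trace` (text or .npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            meta = yaml.safe_load(str(z["__meta__"])) or {}
            proto = None
            if "protocol" in meta:
                proto = _protocol_from_str(meta.pop("protocol"))
            gates = {k[5:]: z[k] for k in z.files if k.startswith("gate_")}
            currents = {k.rsplit("_", 1)[0]: z[k] for k in z.files
                        if k.startswith(("I_", "G_"))}
            return _build_trace(z["time_ms"], z["voltage_mV"], z["current_pA"],
                                gates or None, currents or None, meta, proto, path)
    meta: dict = {}
    proto = None
    cols: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _TRACE_MAGIC:
            raise TraceFormatError(f"{path}:1: not a scnmodel trace file")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# protocol: "):
                proto = _protocol_from_str(line[len("# protocol: "):])
            elif line.startswith("# meta "):
                k, v = line[len("# meta "):].split("=", 1)
                meta[k] = yaml.safe_load(v)
            elif line.startswith("#"):
                continue
            elif not cols:
                cols = line.split("\t")
                for req in ("time_ms", "voltage_mV", "current_pA"):
                    if req not in cols:
                        raise TraceFormatError(f"{path}:{ln}: missing column {req}")
            else:
                try:
                    rows.append([float(x) for x in line.split("\t")])
                except ValueError as err:
                    raise TraceFormatError(f"{path}:{ln}: {err}") from None
                if len(rows[-1]) != len(cols):
                    raise TraceFormatError(f"{path}:{ln}: expected {len(cols)} columns")
    if not cols or not rows:
        raise TraceFormatError(f"{path}: no data rows")
    data = np.array(rows)
    by = {c: data[:, i] for i, c in enumerate(cols)}
    gates = {c[5:]: by[c] for c in cols if c.startswith("gate_")}
    currents = {c.rsplit("_", 1)[0]: by[c] for c in cols if c.startswith(("I_", "G_"))}
    return _build_trace(by["time_ms"], by["voltage_mV"], by["current_pA"],
                        gates or None, currents or None, meta, proto, path)


def _build_trace(t, V, I, gates, currents, meta, proto, path) -> SimulatedTrace:
    t = np.asarray(t, dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceFormatError(f"{path}: time column not strictly increasing")
        if np.ptp(dt) > 1e-6 * dt[0]:
            raise TraceFormatError(f"{path}: sampling interval inconsistent beyond 1 ppm")
    return SimulatedTrace(t, np.asarray(V, float), np.asarray(I, float),
                          gates, currents, meta, proto)


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

_PARAMS_MAGIC = "# scnmodel-params v1"

_SCALAR_KEYS = {
    "C_pF": "C",
    "gNa_nS": "g_Na", "gK_nS": "g_K", "gCa_nS": "g_Ca",
    "gLNa_nS": "g_LNa", "gLK_nS": "g_LK", "gH_nS": "g_H", "gA_nS": "g_A",
    "gsynE_nS": "g_synE", "gsynI_nS": "g_synI",
    "ENa_mV": "E_Na", "EK_mV": "E_K", "ECa_mV": "E_Ca", "EH_mV": "E_H",
    "EsynE_mV": "E_synE", "EsynI_mV": "E_synI",
    "sf_gA": "sf_gA", "sf_tau_hA": "sf_tau_hA", "sf_leak": "sf_leak",
}


def write_params(path: str | Path, p: ModelParameters,
                 header_comment: str = "") -> None:
    """Serialize a parameter set to key-value text with units in field names.

    Values are written with repr() so the round trip is value-exact.
    """
    with open(path, "w") as fh:
        fh.write(_PARAMS_MAGIC + "\n")
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        for key, attr in _SCALAR_KEYS.items():
            fh.write(f"{key} = {float(getattr(p, attr))!r}\n")
        for gate in GATE_NAMES:
            k = p.kinetics[gate]
            fh.write(f"{gate}_vhalf_mV = {float(k.v_half)!r}\n")
            fh.write(f"{gate}_dv_mV = {float(k.dv)!r}\n")
            if k.instantaneous:
                fh.write(f"{gate}_instantaneous = true\n")
            else:
                fh.write(f"{gate}_tau0_ms = {float(k.tau0)!r}\n")
                fh.write(f"{gate}_tau1_ms = {float(k.tau1)!r}\n")
                if k.v_half_tau is not None:
                    fh.write(f"{gate}_vhalf_tau_mV = {float(k.v_half_tau)!r}\n")
                    fh.write(f"{gate}_dv_tau_mV = {float(k.dv_tau)!r}\n")


def read_params(path: str | Path) -> ModelParameters:
    """Read a parameter file written by :func:`write_params`."""
    path = Path(path)
    raw: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _PARAMS_MAGIC:
            raise TraceFormatError(f"{path}:1: not a scnmodel parameter file")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise TraceFormatError(f"{path}:{ln}: expected 'key = value'")
            k, v = (part.strip() for part in line.split("=", 1))
            raw[k] = v
    scalars = {}
    for key, attr in _SCALAR_KEYS.items():
        if key in raw:
            scalars[attr] = float(raw.pop(key))
    kinetics = {}
    for gate in GATE_NAMES:
        inst = raw.pop(f"{gate}_instantaneous", "false").lower() == "true"
        kw = dict(
            v_half=float(raw.pop(f"{gate}_vhalf_mV")),
            dv=float(raw.pop(f"{gate}_dv_mV")),
            instantaneous=inst,
        )
        if not inst:
            kw["tau0"] = float(raw.pop(f"{gate}_tau0_ms"))
            kw["tau1"] = float(raw.pop(f"{gate}_tau1_ms"))
            if f"{gate}_vhalf_tau_mV" in raw:
                kw["v_half_tau"] = float(raw.pop(f"{gate}_vhalf_tau_mV"))
                kw["dv_tau"] = float(raw.pop(f"{gate}_dv_tau_mV"))
        kinetics[gate] = GateKinetics(**kw)
    if raw:
        raise TraceFormatError(f"{path}: unknown keys {sorted(raw)}")
    return ModelParameters(kinetics=kinetics, **scalars)


# ---------------------------------------------------------------------------
# Axon Binary Format (ABF v1) import
# ---------------------------------------------------------------------------

class UnsupportedABFError(ValueError):
    """ABF variant outside the supported v1 subset (never a silent misread)."""


_ABF1_HEADER = 2048


def import_abf(path: str | Path) -> SimulatedTrace:
    """Import an Axon Binary Format v1 file (gap-free or episodic).

    Reads the fixed 2048-byte ABF1 header at the documented offsets,
    applies the per-channel instrument scaling, and normalizes units to
    mV / pA / ms.  Requires one voltage channel (units mV) and one current
    channel (units pA or nA); gap-free files map to a single zero-segment
    protocol.  ABF2 (signature 'ABF2') and unusual variants raise
    :class:`UnsupportedABFError` rather than risking a misread.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _ABF1_HEADER:
        raise UnsupportedABFError(f"{path}: too short for an ABF header")
    sig = blob[0:4]
    if sig == b"ABF2":
        raise UnsupportedABFError(f"{path}: ABF2 files are not supported (v1 subset only)")
    if sig != b"ABF ":
        raise UnsupportedABFError(f"{path}: not an ABF file (signature {sig!r})")

    def u(fmt: str, off: int):
        return struct.unpack_from("<" + fmt, blob, off)

    n_op_mode = u("h", 8)[0]
    n_samples = u("i", 10)[0]
    data_ptr = u("i", 40)[0]
    n_fmt = u("h", 100)[0]
    n_chan = u("h", 120)[0]
    sample_us = u("f", 122)[0]          # per-channel sample interval, us
    adc_range = u("f", 244)[0]
    adc_res = u("i", 252)[0]
    if n_op_mode not in (3, 5):
        raise UnsupportedABFError(f"{path}: operation mode {n_op_mode} unsupported")
    if n_fmt not in (0, 1):
        raise UnsupportedABFError(f"{path}: data format {n_fmt} unsupported")
    if n_chan < 1 or n_chan > 16:
        raise UnsupportedABFError(f"{path}: {n_chan} ADC channels out of range")

    sampling_seq = u("16h", 410)
    units = []
    for i in range(16):
        units.append(blob[602 + 8 * i: 602 + 8 * (i + 1)].decode("ascii", "ignore").strip("\x00 "))
    prog_gain = u("16f", 730)
    inst_scale = u("16f", 922)
    inst_offset = u("16f", 986)
    sig_gain = u("16f", 1050)
    sig_offset = u("16f", 1114)

    start = data_ptr * 512
    if n_fmt == 0:
        raw = np.frombuffer(blob, dtype="<i2", count=n_samples, offset=start).astype(float)
    else:
        raw = np.frombuffer(blob, dtype="<f4", count=n_samples, offset=start).astype(float)
    if n_samples % n_chan:
        raise UnsupportedABFError(f"{path}: sample count not divisible by channel count")
    raw = raw.reshape(-1, n_chan)

    channels = {}
    for pos in range(n_chan):
        ch = sampling_seq[pos]
        vals = raw[:, pos]
        if n_fmt == 0:
            scale = adc_range / adc_res / (inst_scale[ch] * sig_gain[ch] * prog_gain[ch])
            vals = vals * scale + inst_offset[ch] - sig_offset[ch]
        channels[units[ch]] = vals

    if "mV" not in channels:
        raise TraceFormatError(f"{path}: no voltage channel (units 'mV') present")
    V = channels["mV"]
    if "pA" in channels:
        I = channels["pA"]
    elif "nA" in channels:
        I = channels["nA"] * 1000.0
    else:
        raise TraceFormatError(f"{path}: no current channel (units 'pA' or 'nA') present")

    dt_ms = sample_us / 1000.0
    t = np.arange(V.size) * dt_ms
    proto = None
    if n_op_mode == 3:  # gap-free
        proto = StimulusProtocol("gap-free", float(I[0]) if I.size else 0.0, (),
                                 float(t[-1]) if t.size else 0.0)
    meta = {"source": str(path), "abf_version": u("f", 4)[0],
            "operation_mode": {3: "gap-free", 5: "episodic"}[n_op_mode]}
    return SimulatedTrace(t, V, I, None, None, meta, proto)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seeds, solver options, and thresholds shared across CLI commands.

    Any stochastic operation takes either an explicit seed from ``seeds``
    or one derived deterministically from ``master_seed`` and its name.
    """

    master_seed: int = 0
    seeds: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)
    output_dir: str = "."
    verbosity: int = 1

    def seed_for(self, name: str) -> int:
        if name in self.seeds:
            return int(self.seeds[name])
        # stable small-integer derivation from the master seed
        h = 2166136261
        for c in f"{self.master_seed}:{name}".encode():
            h = ((h ^ c) * 16777619) & 0xFFFFFFFF
        return h % (2 ** 31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
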