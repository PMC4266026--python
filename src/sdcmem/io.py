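"""Trace and report serialization.

Traces are JSON-lines: one record per (sequence, frame, mac) with the
chosen code, familiarity G, hypothesis count zeta and the back-off variant
used.  Reports are the metrics module's AccuracyReport as JSON or CSV.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional

from .architecture import MacId
from .engine import FrameRecord, Trace


def trace_records(trace: Trace, seq_index: int = 0) -> Iterable[dict]:
    for frame in trace:
        for mid, rec in frame.items():
            yield {
                "seq": seq_index,
                "t": rec.t,
                "mac": list(mid),
                "active": rec.active,
                "persisted": rec.persisted,
                "code": rec.code,
                "G": None if rec.G is None else round(rec.G, 6),
                "zeta": rec.zeta,
                "variant": rec.variant,
                "mode": rec.mode,
            }


def write_traces(traces: list[Trace], path: str) -> None:
    with open(path, "w") as fh:
        for i, trace in enumerate(traces):
            for rec in trace_records(trace, i):
                fh.write(json.dumps(rec) + "\n")


def read_traces(path: str) -> list[Trace]:
    """Rebuild traces (lists of per-frame mac->record dicts) from JSONL."""
    by_seq: dict[int, dict[int, dict[MacId, FrameRecord]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            mid = tuple(d["mac"])
            rec = FrameRecord(
                t=d["t"], mac_id=mid, active=d["active"],
                persisted=d.get("persisted", False), code=d.get("code"),
                G=d.get("G"), zeta=d.get("zeta", 0),
                variant=d.get("variant", ""), mode=d.get("mode", ""))
            by_seq.setdefault(d.get("seq", 0), {}).setdefault(
                d["t"], {})[mid] = rec
    traces = []
    for seq in sorted(by_seq):
        frames = by_seq[seq]
        traces.append([frames[t] for t in sorted(frames)])
    return traces


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")
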