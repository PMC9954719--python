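"""Plain-text readers/writers for spike events, waveforms and summaries.

Everything is diff-able text: spike events and result tables are
tab-separated with a header row; waveforms are two-column TSV
(``time_us``, ``current_uA``) with a JSON sidecar carrying the pulse spec,
target and realised charge and quantisation settings.  The protocol grid
(20 levels x 32 repetitions) is small enough that no binary container is
warranted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import InputFormatError
from .pulses import Family, Polarity, PulseShapeSpec, Waveform
from .simulate import SPIKE_COLUMNS

__all__ = [
    "read_spike_events",
    "write_spike_events",
    "write_waveform",
    "read_waveform",
    "render_summary_markdown",
]


def write_spike_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write a spike-event table as TSV (columns: recording_id, shape_id,
    level_index, trial_index, spike_time_ms)."""
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, columns=SPIKE_COLUMNS)
    return path


def read_spike_events(path: str | Path, max_time_ms: float = 250.0) -> pd.DataFrame:
    """Read and validate a TSV spike-event table.

    Malformed rows (non-numeric indices or times, times outside
    ``[0, max_time_ms)``, non-positive indices) are reported with their
    1-based file line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise InputFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing columns {missing}")

    lines = df.index.to_numpy() + 2  # 1-based, after the header line
    bad = np.zeros(len(df), dtype=bool)
    out = pd.DataFrame({"recording_id": df["recording_id"], "shape_id": df["shape_id"]})
    for col in ("level_index", "trial_index"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna().to_numpy() | (vals.fillna(0) < 1).to_numpy()
        bad |= (vals.fillna(0) % 1 != 0).to_numpy()
        out[col] = vals
    times = pd.to_numeric(df["spike_time_ms"], errors="coerce")
    bad |= times.isna().to_numpy()
    bad |= ((times < 0) | (times >= max_time_ms)).fillna(False).to_numpy()
    out["spike_time_ms"] = times
    if bad.any():
        where = ", ".join(str(n) for n in lines[bad][:10])
        more = "" if bad.sum() <= 10 else f" (+{int(bad.sum()) - 10} more)"
        raise InputFormatError(f"{path}: malformed rows at lines {where}{more}")
    out["level_index"] = out["level_index"].astype(np.int64)
    out["trial_index"] = out["trial_index"].astype(np.int64)
    return out


def write_waveform(w: Waveform, path: str | Path) -> tuple[Path, Path]:
    """Write a waveform as TSV plus a JSON metadata sidecar.

    Returns ``(tsv_path, json_path)``; the sidecar is ``<path>.json`` next
    to the TSV and records the shape spec, target/realised charge, the
    charge imbalance and the quantisation settings.
    """
    path = Path(path)
    pd.DataFrame({"time_us": w.times_us, "current_uA": w.samples_uA}).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "sample_period_us": w.sample_period_us,
        "n_samples": int(len(w.samples_uA)),
        "realized_charge_nC": w.realized_charge_nC,
        "charge_imbalance_nC": w.charge_imbalance_nC,
        "target_charge_nC": w.target_charge_nC,
        "quantized": w.quantized,
        "current_step_uA": w.current_step_uA,
        "constraint_violation": w.constraint_violation,
        "n_staircase_levels": w.n_staircase_levels,
        "spec": None
        if w.spec is None
        else {
            "family": w.spec.family.value,
            "polarity_first": w.spec.polarity_first.value,
            "slope_angle_deg": w.spec.slope_angle_deg,
            "peak_amplitude_uA": w.spec.peak_amplitude_uA,
            "rect_phase_duration_us": w.spec.rect_phase_duration_us,
        },
    }
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(meta, indent=2) + "\n")
    return path, side


def read_waveform(path: str | Path) -> Waveform:
    """Read a waveform TSV and its JSON sidecar back into a :class:`Waveform`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = None
    if meta.get("spec"):
        s = meta["spec"]
        spec = PulseShapeSpec(
            family=Family(s["family"]),
            polarity_first=Polarity(s["polarity_first"]),
            slope_angle_deg=s["slope_angle_deg"],
            peak_amplitude_uA=s["peak_amplitude_uA"],
            rect_phase_duration_us=s["rect_phase_duration_us"],
        )
    return Waveform(
        sample_period_us=meta["sample_period_us"],
        samples_uA=df["current_uA"].to_numpy(dtype=float),
        realized_charge_nC=meta["realized_charge_nC"],
        charge_imbalance_nC=meta["charge_imbalance_nC"],
        current_step_uA=meta["current_step_uA"],
        quantized=meta["quantized"],
        constraint_violation=meta["constraint_violation"],
        n_staircase_levels=meta["n_staircase_levels"],
        spec=spec,
        target_charge_nC=meta["target_charge_nC"],
    )


def render_summary_markdown(summary: pd.DataFrame) -> str:
    """Render comparison summaries as a Markdown table.

    Layout mirrors the reference cohort tables: one column per shape
    comparison, one "mean (±sem) vs. mean (±sem)" row plus a p-value row
    per parameter.  Parameters absent from the printed reference tables
    (DynRange80) are marked.
    """
    pairs = summary[["ref_shape", "comp_shape"]].drop_duplicates().itertuples(index=False)
    headers, columns = [""], []
    blocks: dict[tuple[str, str], pd.DataFrame] = {}
    for ref, comp in pairs:
        sub = summary[(summary["ref_shape"] == ref) & (summary["comp_shape"] == comp)]
        n = int(sub["n"].iloc[0]) if len(sub) else 0
        headers.append(f"{ref} vs. {comp} (n = {n})")
        blocks[(ref, comp)] = sub.set_index("parameter")
        columns.append((ref, comp))

    params = list(dict.fromkeys(summary["parameter"]))
    lines = ["| " + " | ".join(headers) + " |", "|" + "---|" * len(headers)]
    for p in params:
        label = summary.loc[summary["parameter"] == p, "label"].iloc[0]
        if not summary.loc[summary["parameter"] == p, "in_reference_tables"].iloc[0]:
            label += " (not in reference tables)"
        vals, pvals = [], []
        for key in columns:
            row = blocks[key].loc[p]
            vals.append(
                f"{row['ref_mean']:.2f} (±{row['ref_sem']:.2f}) vs. "
                f"{row['comp_mean']:.2f} (±{row['comp_sem']:.2f})"
            )
            pv = row["p_value"]
            if np.isnan(pv):
                pvals.append(row["test_note"] or "n/a")
            else:
                pvals.append("< 0.0001" if pv < 1e-4 else f"{pv:.4f}")
        lines.append(f"| {label} | " + " | ".join(vals) + " |")
        lines.append("| *p* value | " + " | ".join(pvals) + " |")
    return "\n".join(lines) + "\n"
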