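"""CSV/JSON interchange for trials, geometry, curves and results.

File conventions: angles in degrees on disk and radians in memory; lengths in
mm; one row per time sample.  All formats are plain text so that generated
datasets remain portable and diffable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import TrialSeries
from .hill_model import MuscleParams, SeeDefinition, SeeKind
from .signals import ActivationParams
from .ta_characterization import CurveKind, ForceStrainCurve, MuscleId, RestGeometry

__all__ = [
    "write_rest_geometry", "read_rest_geometry",
    "write_ramp_trial", "read_ramp_trial",
    "write_trial", "read_trial",
    "write_curves", "read_curves",
    "write_muscle_params", "read_muscle_params",
    "write_tracks_csv",
]


def write_rest_geometry(path, geometries: dict) -> None:
    rows = []
    for m, g in geometries.items():
        rows.append({
            "muscle": MuscleId(m).value,
            "fascicle_length_mm": g.fascicle_length_rest,
            "pennation_deg": (math.degrees(g.pennation_rest)
                              if g.pennation_rest is not None else None),
            "tendon_length_mm": g.tendon_length_rest,
            "aponeurosis_length_mm": g.aponeurosis_length_rest,
            "ratio": g.ratio,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rest_geometry(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        m = MuscleId(row["muscle"])
        def val(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        pen = val("pennation_deg")
        out[m] = RestGeometry(
            muscle_id=m,
            fascicle_length_rest=val("fascicle_length_mm"),
            pennation_rest=math.radians(pen) if pen is not None else None,
            tendon_length_rest=val("tendon_length_mm"),
            aponeurosis_length_rest=val("aponeurosis_length_mm"),
            ratio=val("ratio"),
        )
    return out


def write_ramp_trial(path, trial) -> None:
    """Isometric-ramp measurement table for the imaged muscle."""
    pd.DataFrame({
        "time_s": trial.series.time,
        "moment_Nm": trial.series.net_moment,
        "tendon_length_mm": trial.tendon_length_mm,
        "mt_length_mm": trial.mt_length_mm,
        "fascicle_length_mm": trial.fascicle_length_mm,
        "pennation_deg": np.degrees(trial.pennation_rad),
    }).to_csv(path, index=False)


def read_ramp_trial(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["pennation_rad"] = np.radians(df["pennation_deg"])
    return df


def write_trial(path, series: TrialSeries) -> None:
    """Dynamic-trial table: envelopes, MT lengths, moment arms, net moment."""
    data = {"time_s": series.time}
    for m, v in series.envelopes.items():
        data[f"env_{MuscleId(m).value}"] = v
    for m, v in series.mt_lengths.items():
        data[f"mt_length_mm_{MuscleId(m).value}"] = v
    for m, v in series.moment_arms.items():
        data[f"moment_arm_mm_{MuscleId(m).value}"] = v
    data["net_moment_Nm"] = series.net_moment
    pd.DataFrame(data).to_csv(path, index=False)


def read_trial(path, signs=None, task: str = "") -> TrialSeries:
    df = pd.read_csv(path)
    muscles = [c[len("env_"):] for c in df.columns if c.startswith("env_")]
    env, mt, arm = {}, {}, {}
    for name in muscles:
        m = MuscleId(name)
        env[m] = df[f"env_{name}"].to_numpy()
        mt[m] = df[f"mt_length_mm_{name}"].to_numpy()
        arm[m] = df[f"moment_arm_mm_{name}"].to_numpy()
    if signs is None:
        signs = {m: (-1.0 if m is MuscleId.TA else 1.0) for m in env}
    return TrialSeries(time=df["time_s"].to_numpy(), envelopes=env,
                       mt_lengths=mt, moment_arms=arm,
                       net_moment=df["net_moment_Nm"].to_numpy(),
                       signs=signs, task=task)


def _curve_dict(curve: ForceStrainCurve) -> dict:
    return {"kind": curve.kind.value, "c2": curve.c2, "c1": curve.c1,
            "eps_max": curve.eps_max, "extrapolation": curve.extrapolation}


def write_curves(path, curves: dict) -> None:
    """Serialize a {label: ForceStrainCurve} mapping (labels may nest
    muscle/kind, e.g. "GM/tendon")."""
    payload = {str(k): _curve_dict(c) for k, c in curves.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_curves(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {k: ForceStrainCurve(kind=CurveKind(v["kind"]), c2=v["c2"],
                                c1=v["c1"], eps_max=v["eps_max"],
                                extrapolation=v["extrapolation"])
            for k, v in payload.items()}


def write_muscle_params(path, params: dict) -> None:
    payload = {}
    for m, p in params.items():
        d = asdict(p)
        d["muscle_id"] = MuscleId(m).value
        d["pennation_opt_deg"] = math.degrees(d.pop("pennation_opt"))
        payload[MuscleId(m).value] = d
    Path(path).write_text(json.dumps(payload, indent=2))


def read_muscle_params(path) -> dict:
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, d in payload.items():
        m = MuscleId(name)
        act = ActivationParams(**d.pop("activation"))
        d.pop("muscle_id", None)
        pen = math.radians(d.pop("pennation_opt_deg"))
        out[m] = MuscleParams(muscle_id=m, pennation_opt=pen, activation=act, **d)
    return out


def write_tracks_csv(path, tracks: dict) -> None:
    """Landmark tracks as long-format CSV (frame, name, row_px, col_px,
    confidence)."""
    rows = []
    for name, tr in tracks.items():
        label = getattr(tr.name, "value", tr.name)
        for i, (r, c) in enumerate(np.asarray(tr.positions)):
            rows.append({"frame": i, "name": label, "row_px": int(r),
                         "col_px": int(c),
                         "confidence": float(tr.confidence[i])})
    pd.DataFrame(rows).to_csv(path, index=False)


def see_to_dict(see: SeeDefinition) -> dict:
    d = {"kind": SeeKind(see.kind).value, "strain_at_fmax": see.strain_at_fmax}
    if see.curve is not None:
        d["curve"] = _curve_dict(see.curve)
    return d
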