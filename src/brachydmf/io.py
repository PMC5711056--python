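"""Configuration parsing and result/report writers.

Configs are flat ``key = value`` text with dotted namespaces (greppable and
diffable); results go to CSV with a header row and '#'-prefixed provenance
comments; the study report is a deterministic plain-text summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .planning import (
    Plan,
    PlanMetrics,
    V150_LIMIT_CC,
    V200_LIMIT_CC,
)

_KNOWN_KEYS = {
    "phantom.kind": str,
    "phantom.depth_cm": float,
    "applicator.balloon_radius_cm": float,
    "wire.enabled": bool,
    "wire.radius_cm": float,
    "engine.n_histories": int,
    "engine.seed": int,
    "engine.estimator": str,
    "engine.coherent": bool,
    "plan.prescription_cgy": float,
    "plan.label": str,
}


def _parse_value(raw: str, typ):
    raw = raw.strip()
    if typ is bool:
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"not a boolean: '{raw}'")
    return typ(raw)


def load_config(path) -> dict:
    """Parse and validate a flat key=value run config.

    Unknown keys or malformed values raise with the offending key named.
    """
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key.startswith("scenario.") or key in ("master_seed", "scale"):
            out[key] = raw.strip()
            continue
        if key not in _KNOWN_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown config key '{key}'")
        try:
            out[key] = _parse_value(raw, _KNOWN_KEYS[key])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: key '{key}': {exc}") from None
    return out


def write_csv(df: pd.DataFrame, path, provenance: dict | None = None):
    """CSV with '#'-prefixed provenance comment lines before the header."""
    with open(path, "w") as f:
        for k, v in (provenance or {}).items():
            f.write(f"# {k}: {v}\n")
        df.to_csv(f, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_plan(plan: Plan, applicator, path):
    """Plan as CSV (dwell index, lumen, weight) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "dwell_index": [d.index for d in applicator.dwells],
            "lumen": [d.lumen_id for d in applicator.dwells],
            "weight": plan.weights,
        }
    )
    write_csv(df, path, {"plan": plan.label})
    sidecar = {
        "label": plan.label,
        "prescription_cgy": plan.prescription,
        "normalization": plan.normalization,
        "active_lumens": list(plan.active_lumens),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_plan(path) -> Plan:
    path = Path(path)
    df = read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Plan(
        weights=df.sort_values("dwell_index")["weight"].to_numpy(),
        active_lumens=tuple(sidecar["active_lumens"]),
        prescription=sidecar["prescription_cgy"],
        normalization=sidecar["normalization"],
        label=sidecar["label"],
    )


def write_report(
    dmf: pd.DataFrame | None = None,
    comparison: pd.DataFrame | None = None,
    wire: pd.DataFrame | None = None,
    metrics: dict[str, PlanMetrics] | None = None,
) -> str:
    """Render the study summary as deterministic plain text.

    Raises if no input table at all is present, listing what is missing.
    """
    if dmf is None and comparison is None and wire is None and metrics is None:
        raise ValueError(
            "nothing to report: missing tables "
            "[dmf, comparison, wire, metrics]"
        )
    lines = ["# multilumen balloon backscatter study report", ""]
    if dmf is not None and len(dmf):
        for (phantom, plan, wire_flag), grp in dmf.groupby(
            ["phantom", "plan", "wire"], sort=True
        ):
            tag = " (steel wire)" if wire_flag else ""
            lines.append(f"## DMF vs tissue depth: {phantom}, {plan} plan{tag}")
            lines.append("depth_cm  dmf      underdose_percent  rse")
            for _, row in grp.sort_values("depth_cm").iterrows():
                lines.append(
                    f"{row.depth_cm:8.1f}  {row.dmf:.4f}  "
                    f"{row.underdose_percent:17.2f}  {row.rse:.4f}"
                )
            lines.append("")
    if comparison is not None and len(comparison):
        lines.append("## symmetric vs asymmetric DMF (paired seeds)")
        lines.append("depth_cm  dmf_difference  sigma")
        for _, row in comparison.sort_values("depth_cm").iterrows():
            lines.append(
                f"{row.depth_cm:8.1f}  {row.dmf_difference:14.5f}  "
                f"{row.sigma:.5f}"
            )
        mx = comparison.dmf_difference.abs().max()
        lines.append(f"max |difference| = {mx:.5f}")
        lines.append("")
    if wire is not None and len(wire):
        lines.append("## steel-wire effect on DMF (paired seeds)")
        lines.append("depth_cm  dmf_difference  sigma")
        for _, row in wire.sort_values("depth_cm").iterrows():
            lines.append(
                f"{row.depth_cm:8.1f}  {row.dmf_difference:14.5f}  "
                f"{row.sigma:.5f}"
            )
        lines.append(
            f"most negative ddmf = {wire.dmf_difference.min():.5f}"
        )
        lines.append("")
    if metrics:
        lines.append("## plan metrics (RTOG limits: "
                     f"V150 <= {V150_LIMIT_CC:g} cc, V200 <= {V200_LIMIT_CC:g} cc)")
        lines.append("plan          asymmetry%  V150_cc  V200_cc  V150  V200")
        for label in sorted(metrics):
            m = metrics[label]
            p150 = "pass" if m.v150_cc <= V150_LIMIT_CC else "FAIL"
            p200 = "pass" if m.v200_cc <= V200_LIMIT_CC else "FAIL"
            lines.append(
                f"{label:13s} {m.asymmetry_percent:10.2f}  "
                f"{m.v150_cc:7.2f}  {m.v200_cc:7.2f}  {p150}  {p200}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
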