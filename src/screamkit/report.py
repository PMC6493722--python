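"""Human- and machine-readable summaries of a full study analysis."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

__all__ = ["build_report", "render_markdown", "to_json"]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def build_report(
    dfa_results: dict[str, object] | None = None,
    effect_ledger: pd.DataFrame | None = None,
    support_effects: list | None = None,
    kappa: dict[str, object] | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble a structured report; absent stages are marked explicitly."""
    report: dict = {"seed": seed, "config": _jsonable(config) if config else None}
    if dfa_results:
        report["dfa"] = {
            name: (res.as_dict() if hasattr(res, "as_dict") else _jsonable(res))
            for name, res in dfa_results.items()
        }
    else:
        report["dfa"] = "absent"
    report["effects"] = _jsonable(effect_ledger) if effect_ledger is not None else "absent"
    report["support"] = (
        [_jsonable(e.as_dict() if hasattr(e, "as_dict") else e) for e in support_effects]
        if support_effects
        else "absent"
    )
    report["reliability"] = _jsonable(kappa) if kappa else "absent"
    return report


def render_markdown(report: dict) -> str:
    lines = ["# Scream-study analysis report", ""]
    if report.get("seed") is not None:
        lines += [f"Seed: {report['seed']}", ""]
    lines.append("## Discriminant analyses")
    dfa = report.get("dfa", "absent")
    if dfa == "absent":
        lines.append("*absent*")
    else:
        for name, res in dfa.items():
            lines.append(f"### {name}")
            for k, v in res.items():
                if isinstance(v, float):
                    v = f"{v:.3f}"
                lines.append(f"- {k}: {v}")
    lines += ["", "## Fixed-effect ledger (12 models x 3 effects)"]
    eff = report.get("effects", "absent")
    if eff == "absent" or not eff:
        lines.append("*absent*")
    else:
        header = ["response", "effect", "estimate", "se", "p", "p_adjusted", "r2_marginal", "r2_conditional"]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for row in eff:
            cells = [
                f"{row.get(h):.3g}" if isinstance(row.get(h), float) and row.get(h) is not None else str(row.get(h))
                for h in header
            ]
            lines.append("| " + " | ".join(cells) + " |")
    lines += ["", "## Support model"]
    sup = report.get("support", "absent")
    if sup == "absent" or not sup:
        lines.append("*absent*")
    else:
        for row in sup:
            lines.append(
                f"- {row['effect']}: estimate {row['estimate']:.3f} "
                f"(se {row['se']:.3f}, p {row['p']:.4f})"
            )
    lines += ["", "## Inter-observer reliability"]
    rel = report.get("reliability", "absent")
    if rel == "absent" or not rel:
        lines.append("*absent*")
    else:
        for k, v in rel.items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"


def to_json(report: dict) -> str:
    return json.dumps(_jsonable(report), indent=2, sort_keys=True)
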