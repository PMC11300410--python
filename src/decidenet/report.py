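"""Human-readable report generation.

The report mirrors the tool's final outputs: the two resource-allocation
tables (the pie-chart data), the focal user's expected satisfaction per
option, the stakeholder-aggregate expected satisfaction per option, and the
recommendation — plus a full record of the scale mappings and policies that
produced the numbers, and a content hash that is stable across runs of the
same session and configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .config import RunConfig
from .network import ComparisonResult
from .session import Session, session_to_dict

__all__ = ["content_hash", "render_markdown", "render_json", "render_plots"]


def content_hash(session: Session, config: RunConfig) -> str:
    """Deterministic sha256 over the canonical JSON of session + config."""
    blob = json.dumps(
        {"session": session_to_dict(session), "config": config.to_dict()},
        sort_keys=True,
    ).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


def _alloc_table(session: Session, index: int) -> list[str]:
    opt = session.options[index]
    lines = [
        f"### Option {index + 1}: {opt.option_label} ({opt.resource_type})",
        "",
        "| action | allocation (%) |",
        "| --- | ---: |",
    ]
    for aid, pct in opt.allocations.items():
        lines.append(f"| {aid} | {pct:g} |")
    lines.append("")
    return lines


def render_markdown(
    session: Session, result: ComparisonResult, config: RunConfig
) -> str:
    lines = [
        f"# Decision comparison — {session.management_unit}",
        "",
        f"Time frame: {session.time_frame}  ",
        f"Focal user group: {session.focal_user_group}  ",
        f"Content hash: `{content_hash(session, config)}`",
        "",
        "## Validation",
        "",
        "Session passed all validation checks.",
        "",
        "## Resource allocations",
        "",
    ]
    for idx in (0, 1):
        lines.extend(_alloc_table(session, idx))
    lines += [
        "## Expected satisfaction (0–100)",
        "",
        "| group | weight | E(U) option 1 | E(U) option 2 |",
        "| --- | ---: | ---: | ---: |",
    ]
    for gid, vals in result.per_stakeholder.items():
        tag = f"{gid} (focal)" if gid == result.focal_group else gid
        lines.append(
            f"| {tag} | {result.weights[gid]:.3f} | {vals[1]:.2f} | {vals[2]:.2f} |"
        )
    lines.append(
        f"| **aggregate** | | **{result.aggregate[1]:.2f}** | **{result.aggregate[2]:.2f}** |"
    )
    rec_f = result.recommended_focal or "no preference"
    rec_a = result.recommended_aggregate or "no preference"
    lines += [
        "",
        f"Recommendation (focal user): **{rec_f}**  ",
        f"Recommendation (stakeholder aggregate): **{rec_a}**",
        "",
        "## Settings",
        "",
        "The 5-point-scale probability conversions below are package",
        "conventions (the original tool does not publish its constants):",
        "",
        "```json",
        json.dumps(result.settings, indent=2, sort_keys=True),
        "```",
        "",
    ]
    return "\n".join(lines)


def render_json(session: Session, result: ComparisonResult, config: RunConfig) -> str:
    return json.dumps(
        {
            "management_unit": session.management_unit,
            "time_frame": session.time_frame,
            "content_hash": content_hash(session, config),
            "result": result.to_dict(),
        },
        indent=2,
        sort_keys=True,
    )


def render_plots(
    session: Session, result: ComparisonResult, out_dir: str | Path
) -> list[Path]:
    """Write the two bar charts (focal / aggregate expected satisfaction) and
    the two allocation pies.  Requires matplotlib; kept out of the core path
    so the package stays headless."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, series in (("focal", result.focal), ("aggregate", result.aggregate)):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar([result.options[0], result.options[1]], [series[1], series[2]],
               color=["#4c72b0", "#dd8452"])
        ax.set_ylim(0, 100)
        ax.set_ylabel("expected satisfaction")
        ax.set_title(f"{name} comparison")
        path = out_dir / f"satisfaction_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    for idx, opt in enumerate(session.options, start=1):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.pie(list(opt.allocations.values()), labels=list(opt.allocations.keys()),
               autopct="%1.0f%%")
        ax.set_title(f"option {idx}: {opt.option_label} ({opt.resource_type})")
        path = out_dir / f"allocation_option{idx}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
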