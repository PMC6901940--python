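"""Plain-text rendering of deviation reports and repertoire statistics."""

from __future__ import annotations

import pandas as pd

from .reference_model import REFERENCE_POPULATIONS, DeviationReport

__all__ = ["render_report"]


def render_report(
    deviations: list[DeviationReport] | DeviationReport | None = None,
    stats: pd.DataFrame | None = None,
) -> str:
    """Render a human-readable summary with deterministic ordering."""
    if isinstance(deviations, DeviationReport):
        deviations = [deviations]
    lines: list[str] = []
    for rep in deviations or []:
        lines.append(f"== Sample {rep.sample_id} ==")
        lines.append("BCP composition (% of precursor compartment):")
        for pop in REFERENCE_POPULATIONS:
            flag = "" if rep.composition_in_reference.get(pop, True) else "  [outside reference range]"
            lines.append(f"  {pop:<9} {rep.composition[pop]:6.2f}%{flag}")
        lines.append(
            f"BCP outside both pre-BI and pre-BII 2SD contours: "
            f"{100.0 * rep.outside_preB_fraction:.2f}%"
        )
        lines.append("Fraction inside own population contour:")
        for pop in REFERENCE_POPULATIONS:
            val = rep.inside_fraction.get(pop, float("nan"))
            shown = "   n/a" if val != val else f"{val:6.3f}"
            lines.append(f"  {pop:<9} {shown}")
        lines.append(f"Maturation blockade call: {rep.blockade}")
        lines.append("")
    if stats is not None and len(stats):
        lines.append("== Repertoire productivity (collapsed clones) ==")
        header = f"{'compartment':<12} {'clones':>7} {'in-frame':>9} {'ratio':>7} {'CDR3 aa':>8}"
        lines.append(header)
        for _, row in stats.sort_values("compartment").iterrows():
            ratio = row["in_frame_to_unproductive_ratio"]
            ratio_s = "inf" if ratio == float("inf") else f"{ratio:.2f}"
            lines.append(
                f"{row['compartment']:<12} {int(row['n_clones']):>7d} "
                f"{100.0 * row['in_frame_fraction']:>8.1f}% {ratio_s:>7} "
                f"{row['cdr3_aa_mean_length']:>8.1f}"
            )
        lines.append("")
    return "\n".join(lines)
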