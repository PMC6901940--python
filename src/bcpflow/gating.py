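"""Deterministic gating of B-cell precursor stages from 10-marker events.

Events are transformed channel-wise with an inverse hyperbolic sine
(``arcsinh(x / cofactor)``), positivity cutoffs are either configured or
estimated at the deepest density valley between the two largest modes of a
kernel-density estimate, and stages are assigned by the BCR-associated
marker hierarchy:

* cyCD79a- events are non-B;
* among cyCD79a+ events, CD19- TdT+ cells are pro-B;
* among CD19+ cells, surface IgM takes precedence: smIgM+ IgD- is immature,
  smIgM+ IgD+ is mature; smIgM- cells split on cytoplasmic Igmu into pre-BI
  (cyIgM-) and pre-BII (cyIgM+);
* cyCD79a+ CD19- TdT- events have no stage under this hierarchy and are
  assigned non-B while being tallied as unclassified B-lineage QC events.

Within pre-BI and pre-BII, CD34/TdT subdivide cells into +/+ ("pp"),
-/- ("nn"), or intermediate phenotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "MARKERS",
    "BCP_STAGES",
    "GATE_MARKERS",
    "ThresholdSet",
    "GatingResult",
    "read_event_table",
    "transform_intensities",
    "estimate_thresholds",
    "classify_stage",
    "subdivide_preB",
    "compartment_composition",
    "gate_sample",
    "DEFAULT_COFACTOR",
    "DEFAULT_FALLBACK_CUTOFF",
]

MARKERS = ("CD20", "smIgM", "CD38", "TdT", "cyCD79a", "IgD", "cyIgM", "CD19", "CD34", "CD10")
BCP_STAGES = ("pro-B", "pre-BI", "pre-BII", "immature")
GATE_MARKERS = ("cyCD79a", "CD19", "TdT", "cyIgM", "smIgM", "IgD", "CD34")

DEFAULT_COFACTOR = 150.0
# Midpoint between the generator's staining modes on the arcsinh scale; used
# as the configured fallback when a channel is unimodal in a sample (e.g.
# cyIgM in a RAG-deficient marrow, which has no positive cells).
DEFAULT_FALLBACK_CUTOFF = 2.6

SCHEMA_VERSION = 1


def read_event_table(path) -> pd.DataFrame:
    """Read an event CSV and validate the required channels."""
    events = pd.read_csv(path)
    _require_channels(events, MARKERS)
    if events[list(MARKERS)].isna().any().any():
        raise ValueError("event table contains missing marker values")
    return events


def _require_channels(events: pd.DataFrame, markers) -> None:
    missing = [m for m in markers if m not in events.columns]
    if missing:
        raise KeyError(f"event table is missing channel(s): {', '.join(missing)}")


def transform_intensities(
    events: pd.DataFrame, cofactors: float | dict[str, float] = DEFAULT_COFACTOR
) -> pd.DataFrame:
    """arcsinh-transform raw intensities channel-wise (order preserving)."""
    _require_channels(events, MARKERS)
    if isinstance(cofactors, (int, float)):
        cofactors = {m: float(cofactors) for m in MARKERS}
    out = events.copy()
    for m in MARKERS:
        c = cofactors.get(m)
        if c is None or c <= 0:
            raise ValueError(f"cofactor for {m} must be a positive number")
        out[m] = np.arcsinh(events[m].to_numpy(dtype=float) / c)
    return out


@dataclass
class ThresholdSet:
    """Per-marker positivity cutoffs on the transformed scale."""

    cutoffs: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, marker: str) -> float:
        return self.cutoffs[marker]

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "cutoffs": dict(self.cutoffs),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ThresholdSet":
        if obj.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported thresholds schema version: {obj.get('schema_version')}")
        return cls(cutoffs=dict(obj["cutoffs"]), provenance=dict(obj.get("provenance", {})))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _density_valley(values: np.ndarray, grid_size: int = 512) -> float | None:
    """Deepest valley between the two largest KDE modes, or None if unimodal."""
    if len(values) > 20_000:  # KDE cost is O(n * grid); thin deterministically
        values = values[:: len(values) // 20_000 + 1]
    kde = gaussian_kde(values)
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    a, b = int(top2.min()), int(top2.max())
    between = dens[a : b + 1]
    dmin = between.min()
    # Require a real dip between the modes, not a KDE ripple.
    if dmin > 0.9 * min(dens[a], dens[b]):
        return None
    # The inter-modal basin can be wide and flat; its raw argmin wanders, so
    # place the cutoff at the midpoint of the near-minimal region.
    basin_level = dmin + 0.10 * (min(dens[a], dens[b]) - dmin)
    basin = np.flatnonzero(between <= basin_level)
    mid = a + int(round(0.5 * (basin.min() + basin.max())))
    return float(grid[mid])


def estimate_thresholds(
    transformed: pd.DataFrame,
    markers=GATE_MARKERS,
    configured: dict[str, float] | None = None,
    min_events: int = 200,
) -> ThresholdSet:
    """Estimate per-marker cutoffs by KDE density valley.

    A configured value (``configured[marker]``) is returned verbatim with
    provenance "configured".  Markers that appear unimodal fall back to the
    configured value; with no configured value to fall back on this is an
    error.
    """
    if len(transformed) < min_events:
        raise ValueError(f"need at least {min_events} events to estimate thresholds")
    configured = configured or {}
    cutoffs: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for m in markers:
        if m in configured:
            cutoffs[m] = float(configured[m])
            provenance[m] = "configured"
            continue
        valley = _density_valley(transformed[m].to_numpy(dtype=float))
        if valley is None:
            raise ValueError(
                f"channel {m} appears unimodal and no configured cutoff was supplied"
            )
        cutoffs[m] = valley
        provenance[m] = "estimated"
    return ThresholdSet(cutoffs=cutoffs, provenance=provenance)


@dataclass
class GatingResult:
    stage: pd.Series
    subdivision: pd.Series
    thresholds: ThresholdSet
    qc: dict[str, int] = field(default_factory=dict)

    def labels_frame(self, cell_ids: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"stage": self.stage, "subdivision": self.subdivision})
        if cell_ids is not None:
            df.insert(0, "cell_id", cell_ids.to_numpy())
        return df


def classify_stage(transformed: pd.DataFrame, thresholds: ThresholdSet) -> GatingResult:
    """Assign one of {non-B, pro-B, pre-BI, pre-BII, immature, mature} per event."""
    _require_channels(transformed, ("cyCD79a", "CD19", "TdT", "cyIgM", "smIgM", "IgD"))
    pos = {m: transformed[m].to_numpy(dtype=float) > thresholds[m]
           for m in ("cyCD79a", "CD19", "TdT", "cyIgM", "smIgM", "IgD")}

    n = len(transformed)
    stage = np.full(n, "non-B", dtype=object)
    b_lineage = pos["cyCD79a"]
    pro_b = b_lineage & ~pos["CD19"] & pos["TdT"]
    cd19p = b_lineage & pos["CD19"]
    mature = cd19p & pos["smIgM"] & pos["IgD"]
    immature = cd19p & pos["smIgM"] & ~pos["IgD"]
    pre_bii = cd19p & ~pos["smIgM"] & pos["cyIgM"]
    pre_bi = cd19p & ~pos["smIgM"] & ~pos["cyIgM"]
    stage[pro_b] = "pro-B"
    stage[pre_bi] = "pre-BI"
    stage[pre_bii] = "pre-BII"
    stage[immature] = "immature"
    stage[mature] = "mature"
    unclassified = int((b_lineage & ~pos["CD19"] & ~pos["TdT"]).sum())

    result = GatingResult(
        stage=pd.Series(stage, index=transformed.index, name="stage"),
        subdivision=pd.Series("not-applicable", index=transformed.index, name="subdivision", dtype=object),
        thresholds=thresholds,
        qc={"unclassified_b_lineage": unclassified, "n_events": n},
    )
    return result


def subdivide_preB(
    transformed: pd.DataFrame, stage: pd.Series, thresholds: ThresholdSet
) -> pd.Series:
    """CD34/TdT subdivision of pre-BI and pre-BII cells (pp / nn / intermediate)."""
    _require_channels(transformed, ("CD34", "TdT"))
    cd34 = transformed["CD34"].to_numpy(dtype=float) > thresholds["CD34"]
    tdt = transformed["TdT"].to_numpy(dtype=float) > thresholds["TdT"]
    sub = np.full(len(transformed), "not-applicable", dtype=object)
    pre_b = stage.isin(["pre-BI", "pre-BII"]).to_numpy()
    sub[pre_b & cd34 & tdt] = "pp"
    sub[pre_b & ~cd34 & ~tdt] = "nn"
    sub[pre_b & (cd34 ^ tdt)] = "intermediate"
    return pd.Series(sub, index=transformed.index, name="subdivision")


def compartment_composition(stage: pd.Series) -> dict[str, float]:
    """Stage percentages of the precursor compartment.

    Mature B cells are excluded from the denominator because they can derive
    from peripheral-blood contamination; non-B events are excluded as well.
    """
    counts = stage.value_counts()
    total = sum(int(counts.get(s, 0)) for s in BCP_STAGES)
    if total == 0:
        raise ValueError("no precursor B cells present; composition undefined")
    return {s: 100.0 * int(counts.get(s, 0)) / total for s in BCP_STAGES}


def gate_sample(
    events: pd.DataFrame,
    cofactors: float | dict[str, float] = DEFAULT_COFACTOR,
    thresholds: ThresholdSet | None = None,
    fallback_cutoff: float = DEFAULT_FALLBACK_CUTOFF,
) -> tuple[pd.DataFrame, GatingResult]:
    """Transform, threshold, and gate one event table.

    When ``thresholds`` is None they are estimated per channel with the
    density-valley rule, falling back to ``fallback_cutoff`` for unimodal
    channels.  Returns ``(transformed_events, gating_result)``.
    """
    transformed = transform_intensities(events, cofactors)
    if thresholds is None:
        cutoffs: dict[str, float] = {}
        provenance: dict[str, str] = {}
        for m in GATE_MARKERS:
            valley = _density_valley(transformed[m].to_numpy(dtype=float))
            if valley is None:
                cutoffs[m] = fallback_cutoff
                provenance[m] = "configured"
            else:
                cutoffs[m] = valley
                provenance[m] = "estimated"
        thresholds = ThresholdSet(cutoffs=cutoffs, provenance=provenance)
    result = classify_stage(transformed, thresholds)
    result.subdivision = subdivide_preB(transformed, result.stage, thresholds)
    return transformed, result
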