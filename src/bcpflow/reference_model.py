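"""Pooled-control PCA reference ("APS" view) with 2SD population contours.

A reference profile is fitted on the pooled, gated BCP events of several
healthy control samples: markers are standardized with the pooled mean/SD,
the first two principal components are extracted, and each reference
population (pro-B, pre-BI, pre-BII, immature) receives a Gaussian contour at
Mahalanobis distance ``k`` (default 2, i.e. the "2SD" ellipse) in PC1-PC2.
Test samples are projected with the model's standardization and loadings;
cells gated as pre-BI or pre-BII that fall outside both pre-B contours are
counted as transitioning/aberrant, and the sample's composition is compared
with the controls' min-max reference intervals to call maturation blockades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .gating import BCP_STAGES, MARKERS, GatingResult, compartment_composition

__all__ = [
    "ReferenceModel",
    "DeviationReport",
    "build_reference",
    "project_events",
    "outside_fraction",
    "deviation_report",
]

SCHEMA_VERSION = 1

REFERENCE_POPULATIONS = BCP_STAGES  # pro-B, pre-BI, pre-BII, immature

# Composition thresholds (percent of BCP) for the blockade heuristic.
_BLOCK_THRESHOLD_PCT = 2.0


@dataclass
class ReferenceModel:
    markers: tuple[str, ...]
    standardize_mean: np.ndarray  # (m,)
    standardize_sd: np.ndarray  # (m,)
    loadings: np.ndarray  # (2, m), orthonormal rows
    explained_variance: np.ndarray  # (2,)
    population_means: dict[str, np.ndarray]  # name -> (2,)
    population_covs: dict[str, np.ndarray]  # name -> (2, 2)
    k: float = 2.0
    composition_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "markers": list(self.markers),
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "population_means": {p: m.tolist() for p, m in self.population_means.items()},
            "population_covs": {p: c.tolist() for p, c in self.population_covs.items()},
            "k": self.k,
            "composition_intervals": {p: list(v) for p, v in self.composition_intervals.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ReferenceModel":
        if obj.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version: {obj.get('schema_version')}")
        return cls(
            markers=tuple(obj["markers"]),
            standardize_mean=np.asarray(obj["standardize_mean"], dtype=float),
            standardize_sd=np.asarray(obj["standardize_sd"], dtype=float),
            loadings=np.asarray(obj["loadings"], dtype=float),
            explained_variance=np.asarray(obj["explained_variance"], dtype=float),
            population_means={p: np.asarray(m, dtype=float) for p, m in obj["population_means"].items()},
            population_covs={p: np.asarray(c, dtype=float) for p, c in obj["population_covs"].items()},
            k=float(obj["k"]),
            composition_intervals={p: (float(v[0]), float(v[1])) for p, v in obj["composition_intervals"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def build_reference(
    controls: list[tuple[pd.DataFrame, GatingResult]],
    markers=None,
    k: float = 2.0,
    min_population_events: int = 50,
) -> ReferenceModel:
    """Fit the pooled-control PCA reference.

    ``controls`` pairs each control's *transformed* event table with its
    gating result.  PCA is fitted on all pooled BCP events (non-B and mature
    excluded) after per-marker standardization; each reference population
    then receives its PC-space mean and covariance, and per-control
    composition vectors provide min-max reference intervals.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples to build a reference")
    markers = tuple(markers) if markers is not None else MARKERS  # all 10 panel markers by default

    pooled = []
    pooled_stage = []
    for transformed, gates in controls:
        mask = gates.stage.isin(BCP_STAGES).to_numpy()
        pooled.append(transformed.loc[mask, list(markers)].to_numpy(dtype=float))
        pooled_stage.append(gates.stage.to_numpy()[mask])
    x = np.vstack(pooled)
    stages = np.concatenate(pooled_stage)

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise ValueError("a marker has zero variance across pooled controls")
    z = (x - mean) / sd

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.copy()
    explained = pca.explained_variance_.copy()

    # Deterministic sign convention: PC1 positive toward the immature
    # population; PC2 sign fixed by its largest-magnitude loading.
    imm = scores[stages == "immature"]
    if len(imm) and imm[:, 0].mean() < 0:
        loadings[0] = -loadings[0]
        scores[:, 0] = -scores[:, 0]
    j = int(np.argmax(np.abs(loadings[1])))
    if loadings[1, j] < 0:
        loadings[1] = -loadings[1]
        scores[:, 1] = -scores[:, 1]

    population_means: dict[str, np.ndarray] = {}
    population_covs: dict[str, np.ndarray] = {}
    for pop in REFERENCE_POPULATIONS:
        sel = scores[stages == pop]
        if len(sel) < min_population_events:
            raise ValueError(
                f"population {pop} has only {len(sel)} pooled events "
                f"(need >= {min_population_events})"
            )
        population_means[pop] = sel.mean(axis=0)
        cov = np.cov(sel, rowvar=False)
        population_covs[pop] = 0.5 * (cov + cov.T)  # enforce symmetry

    intervals: dict[str, tuple[float, float]] = {}
    per_control = [compartment_composition(g.stage) for _, g in controls]
    for pop in REFERENCE_POPULATIONS:
        vals = [c[pop] for c in per_control]
        intervals[pop] = (min(vals), max(vals))

    return ReferenceModel(
        markers=markers,
        standardize_mean=mean,
        standardize_sd=sd,
        loadings=loadings,
        explained_variance=explained,
        population_means=population_means,
        population_covs=population_covs,
        k=float(k),
        composition_intervals=intervals,
    )


def project_events(transformed: pd.DataFrame, model: ReferenceModel) -> np.ndarray:
    """Project events into the reference PC1-PC2 plane.

    Standardization uses the *model's* pooled-control means and SDs, so a
    test sample is placed in the controls' coordinate system rather than its
    own.
    """
    missing = [m for m in model.markers if m not in transformed.columns]
    if missing:
        raise KeyError(f"sample is missing model marker(s): {', '.join(missing)}")
    x = transformed[list(model.markers)].to_numpy(dtype=float)
    z = (x - model.standardize_mean) / model.standardize_sd
    return z @ model.loadings.T


def mahalanobis_distances(scores: np.ndarray, model: ReferenceModel, population: str) -> np.ndarray:
    mu = model.population_means[population]
    cov = model.population_covs[population]
    delta = scores - mu
    sol = np.linalg.solve(cov, delta.T)
    return np.sqrt(np.einsum("ij,ji->i", delta, sol))


def outside_fraction(
    transformed: pd.DataFrame,
    gates: GatingResult,
    model: ReferenceModel,
    populations=("pre-BI", "pre-BII"),
    k: float | None = None,
) -> float:
    """Fraction of BCP events outside *all* of the listed population contours.

    The numerator counts events gated into one of ``populations`` whose
    Mahalanobis distance exceeds ``k`` for every listed population; the
    denominator is all BCP events (pro-B + pre-BI + pre-BII + immature).
    """
    if k is None:
        k = model.k
    stage = gates.stage.to_numpy()
    bcp_mask = np.isin(stage, BCP_STAGES)
    n_bcp = int(bcp_mask.sum())
    if n_bcp == 0:
        raise ValueError("sample contains no BCP events")
    cand = np.isin(stage, list(populations))
    if not cand.any():
        return 0.0
    scores = project_events(transformed.loc[cand], model)
    outside = np.ones(len(scores), dtype=bool)
    for pop in populations:
        outside &= mahalanobis_distances(scores, model, pop) > k
    return float(outside.sum()) / n_bcp


@dataclass
class DeviationReport:
    sample_id: str
    inside_fraction: dict[str, float]
    outside_preB_fraction: float
    composition: dict[str, float]
    composition_in_reference: dict[str, bool]
    blockade: str  # none | complete_block_preBI | partial_block_preBII

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "sample_id": self.sample_id,
            "inside_fraction": dict(self.inside_fraction),
            "outside_preB_fraction": self.outside_preB_fraction,
            "composition": dict(self.composition),
            "composition_in_reference": dict(self.composition_in_reference),
            "blockade": self.blockade,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DeviationReport":
        if obj.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported report schema version: {obj.get('schema_version')}")
        return cls(
            sample_id=obj["sample_id"],
            inside_fraction=dict(obj["inside_fraction"]),
            outside_preB_fraction=float(obj["outside_preB_fraction"]),
            composition=dict(obj["composition"]),
            composition_in_reference=dict(obj["composition_in_reference"]),
            blockade=obj["blockade"],
        )


def deviation_report(
    transformed: pd.DataFrame,
    gates: GatingResult,
    model: ReferenceModel,
    sample_id: str = "sample",
) -> DeviationReport:
    """Superimpose a test sample on the reference and summarise deviations."""
    composition = compartment_composition(gates.stage)
    stage = gates.stage.to_numpy()

    inside: dict[str, float] = {}
    for pop in REFERENCE_POPULATIONS:
        sel = stage == pop
        if not sel.any():
            inside[pop] = float("nan")
            continue
        scores = project_events(transformed.loc[sel], model)
        d = mahalanobis_distances(scores, model, pop)
        inside[pop] = float((d <= model.k).mean())

    outside = outside_fraction(transformed, gates, model)

    in_ref = {
        pop: bool(lo <= composition[pop] <= hi)
        for pop, (lo, hi) in model.composition_intervals.items()
    }

    pre_bii = composition["pre-BII"]
    immature = composition["immature"]
    if pre_bii + immature < _BLOCK_THRESHOLD_PCT:
        blockade = "complete_block_preBI"
    elif pre_bii >= _BLOCK_THRESHOLD_PCT and immature < _BLOCK_THRESHOLD_PCT:
        blockade = "partial_block_preBII"
    else:
        blockade = "none"

    return DeviationReport(
        sample_id=sample_id,
        inside_fraction=inside,
        outside_preB_fraction=outside,
        composition=composition,
        composition_in_reference=in_ref,
        blockade=blockade,
    )
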