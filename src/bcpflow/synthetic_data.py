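"""Synthetic bone-marrow cytometry samples and IGH rearrangement repertoires.

Two generators with known ground truth back the whole pipeline:

* :func:`simulate_bm_sample` draws per-cell 10-marker intensity events for a
  donor with a given maturation profile (healthy, RAG-deficient, or
  BTK-deficient), including within-stage CD34/TdT heterogeneity, a small
  fraction of asynchronous "transitioning" cells placed between the pre-BI
  and pre-BII centroids, donor-level batch shifts, and non-B contaminants.

* :func:`simulate_rearrangement` assembles V(D)J junctions mechanistically
  (exonucleolytic trimming + non-templated N additions) and rejection-samples
  junctions so that each sorted pre-B compartment realises its configured
  in-frame clone fraction exactly in expectation, while the frame/stop truth
  is always recomputed from the assembled nucleotide sequence.

Truth labels are emitted as sidecar tables, never embedded in the FASTA or
event CSV consumed by the analysis modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .germline import STOP_CODONS, GermlineDB, make_germline_db

__all__ = [
    "MARKERS",
    "STAGES",
    "COMPARTMENTS",
    "CompartmentRepertoireConfig",
    "RearrangementTruth",
    "DonorProfile",
    "default_repertoire_config",
    "simulate_rearrangement",
    "simulate_compartment_repertoire",
    "healthy_profile",
    "rag_deficient_profile",
    "btk_deficient_profile",
    "get_profile",
    "simulate_bm_sample",
    "write_fasta",
    "truth_anchor_positions",
]

MARKERS = ("CD20", "smIgM", "CD38", "TdT", "cyCD79a", "IgD", "cyIgM", "CD19", "CD34", "CD10")
STAGES = ("non-B", "pro-B", "pre-BI", "pre-BII", "immature", "mature")
COMPARTMENTS = ("preBI_pp", "preBI_nn", "preBII_nn", "preBII_pp")

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


# ---------------------------------------------------------------------------
# IGH rearrangement simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentRepertoireConfig:
    """Junction-sampling parameters for one sorted pre-B compartment.

    ``in_frame_fraction`` is the marginal probability that a simulated clone
    is productive (in frame, stop-free).  Deletion counts at the four
    junction ends follow truncated geometric distributions with mean
    ``deletion_mean``; N1/N2 insert lengths are Poisson with means
    ``n1_mean``/``n2_mean`` (a proxy for TdT activity at sampling time).
    """

    compartment: str
    in_frame_fraction: float
    deletion_mean: float = 2.5
    n1_mean: float = 5.0
    n2_mean: float = 5.0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.in_frame_fraction <= 1.0:
            raise ValueError("in_frame_fraction must lie in [0, 1]")
        if self.deletion_mean < 0 or self.n1_mean < 0 or self.n2_mean < 0:
            raise ValueError("junction distribution means must be non-negative")


# In-frame clone fractions per sorted compartment.  The pre-BI-/- compartment
# additionally gets a lower deletion mean, which lengthens its junctions.
_DEFAULT_IN_FRAME = {
    "preBI_pp": 0.10,
    "preBI_nn": 0.75,
    "preBII_nn": 0.80,
    "preBII_pp": 0.75,
}
_DEFAULT_DELETION_MEAN = {
    "preBI_pp": 2.5,
    "preBI_nn": 1.0,
    "preBII_nn": 2.5,
    "preBII_pp": 2.5,
}


def default_repertoire_config(compartment: str) -> CompartmentRepertoireConfig:
    if compartment not in _DEFAULT_IN_FRAME:
        raise ValueError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    return CompartmentRepertoireConfig(
        compartment=compartment,
        in_frame_fraction=_DEFAULT_IN_FRAME[compartment],
        deletion_mean=_DEFAULT_DELETION_MEAN[compartment],
    )


@dataclass(frozen=True)
class RearrangementTruth:
    clone_id: str
    v_name: str
    d_name: str
    j_name: str
    del_v3: int
    del_d5: int
    del_d3: int
    del_j5: int
    n1: str
    n2: str
    frame: str  # "in-frame" | "out-of-frame"
    stop: bool
    productivity: str  # "in_frame" | "unproductive_out_of_frame" | "unproductive_stop"
    compartment: str


_GEOM_CDF_CACHE: dict[tuple[float, int], np.ndarray] = {}


def _truncated_geometric(rng: np.random.Generator, mean: float, cap: int) -> int:
    """Sample a deletion count in {0..cap} with geometric decay of mean ``mean``."""
    if cap <= 0 or mean <= 0:
        return 0
    cdf = _GEOM_CDF_CACHE.get((mean, cap))
    if cdf is None:
        q = mean / (1.0 + mean)  # success ratio of Geometric(p) - 1 with p = 1/(1+mean)
        pmf = q ** np.arange(cap + 1)
        cdf = np.cumsum(pmf / pmf.sum())
        _GEOM_CDF_CACHE[(mean, cap)] = cdf
    return int(np.searchsorted(cdf, rng.random(), side="right"))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    if length == 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _classify_assembled(seq: str, frame_origin: int, j_trp_start: int) -> tuple[str, bool, str]:
    """Recompute frame/stop/productivity from an assembled sequence."""
    in_frame = (j_trp_start - frame_origin) % 3 == 0
    stop = False
    pos = frame_origin
    while pos <= j_trp_start and pos + 3 <= len(seq):
        if seq[pos : pos + 3] in STOP_CODONS:
            stop = True
            break
        pos += 3
    frame = "in-frame" if in_frame else "out-of-frame"
    if in_frame and not stop:
        productivity = "in_frame"
    elif not in_frame:
        productivity = "unproductive_out_of_frame"
    else:
        productivity = "unproductive_stop"
    return frame, stop, productivity


def simulate_rearrangement(
    db: GermlineDB,
    cfg: CompartmentRepertoireConfig,
    rng: np.random.Generator,
    clone_id: str = "clone",
) -> tuple[str, RearrangementTruth]:
    """Assemble one V(D)J rearrangement matching the configured class mix.

    The productivity class is sampled first (in-frame with probability
    ``cfg.in_frame_fraction``); junctions are then rejection-sampled until the
    class recomputed from the assembled sequence matches.  Conserved anchor
    codons always survive trimming because deletions are capped at the
    erodible tail lengths.
    """
    want_in_frame = rng.random() < cfg.in_frame_fraction
    for _ in range(cfg.max_attempts):
        v = db.v_segments[rng.integers(len(db.v_segments))]
        d = db.d_segments[rng.integers(len(db.d_segments))]
        j = db.j_segments[rng.integers(len(db.j_segments))]
        del_v3 = _truncated_geometric(rng, cfg.deletion_mean, v.tail_len)
        del_d5 = _truncated_geometric(rng, cfg.deletion_mean, len(d.seq))
        del_d3 = _truncated_geometric(rng, cfg.deletion_mean, len(d.seq) - del_d5)
        del_j5 = _truncated_geometric(rng, cfg.deletion_mean, j.trp_start)
        n1 = _random_nt(rng, int(rng.poisson(cfg.n1_mean)))
        n2 = _random_nt(rng, int(rng.poisson(cfg.n2_mean)))

        v_part = v.seq[: len(v.seq) - del_v3]
        d_part = d.seq[del_d5 : len(d.seq) - del_d3]
        j_part = j.seq[del_j5:]
        seq = v_part + n1 + d_part + n2 + j_part
        j_trp_start = len(v_part) + len(n1) + len(d_part) + len(n2) + (j.trp_start - del_j5)
        frame, stop, productivity = _classify_assembled(seq, v.frame_offset, j_trp_start)
        if (productivity == "in_frame") == want_in_frame:
            truth = RearrangementTruth(
                clone_id=clone_id,
                v_name=v.name,
                d_name=d.name,
                j_name=j.name,
                del_v3=del_v3,
                del_d5=del_d5,
                del_d3=del_d3,
                del_j5=del_j5,
                n1=n1,
                n2=n2,
                frame=frame,
                stop=stop,
                productivity=productivity,
                compartment=cfg.compartment,
            )
            return seq, truth
    raise RuntimeError(
        f"rejection cap ({cfg.max_attempts}) exceeded for {cfg.compartment}: "
        "the junction configuration cannot realise the requested class"
    )


def truth_anchor_positions(db: GermlineDB, truth: RearrangementTruth) -> tuple[int, int]:
    """Ground-truth (V-Cys, J-Trp) codon start positions in query coordinates."""
    v = db.v_by_name(truth.v_name)
    d = db.d_by_name(truth.d_name)
    j = db.j_by_name(truth.j_name)
    v_kept = len(v.seq) - truth.del_v3
    d_kept = len(d.seq) - truth.del_d5 - truth.del_d3
    trp = v_kept + len(truth.n1) + d_kept + len(truth.n2) + (j.trp_start - truth.del_j5)
    return v.cys_start, trp


def simulate_compartment_repertoire(
    compartment: str,
    n_clones: int,
    cfg: CompartmentRepertoireConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    duplicate_mean: float = 0.0,
    db: GermlineDB | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a sorted-compartment repertoire.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` pairs (possibly with duplicate reads per clone to
    exercise clone collapsing; extra copies per clone are Poisson with mean
    ``duplicate_mean``) and ``truth`` has one row per clone.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if cfg is None:
        cfg = default_repertoire_config(compartment)
    elif cfg.compartment != compartment:
        raise ValueError("config compartment does not match requested compartment")
    if db is None:
        db = make_germline_db()
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    rows = []
    read_no = 0
    for i in range(n_clones):
        clone_id = f"{compartment}_c{i:06d}"
        seq, truth = simulate_rearrangement(db, cfg, rng, clone_id=clone_id)
        copies = 1 + (int(rng.poisson(duplicate_mean)) if duplicate_mean > 0 else 0)
        for _ in range(copies):
            reads.append((f"read{read_no:07d}", seq))
            read_no += 1
        rows.append(truth.__dict__.copy())
    truth_df = pd.DataFrame(rows)
    return reads, truth_df


def write_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# Bone-marrow cytometry simulation
# ---------------------------------------------------------------------------

# Transformed-scale (arcsinh) intensity model.
#
# Each stage is a bounded two-dimensional sheet in marker space rather than a
# Gaussian blob: every cell carries a latent (pseudotime, size) pair drawn
# uniformly from the unit disk.  Pseudotime moves the cell through the stage
# at its own pace - CD20 rises, CD10/CD38 fall with stage-specific
# amplitudes, and within the pre-B stages CD34 and TdT descend from their
# positive to their negative plateau through a steep S-shaped ramp at a
# profile-specific point of pseudotime.  The CD34/TdT subdivisions (+/+,
# intermediate, -/-) are therefore regions of pseudotime, not separate
# populations, mirroring the asynchronous marker continuum of real BCP
# differentiation.  The size/activation factor modulates most channels
# weakly.  A small Gaussian measurement noise (SD 0.10) is added per channel.
_NEG = 0.5
_POS = 4.7

_TEMPLATES: dict[str, dict[str, float]] = {
    "non-B": dict(CD20=_NEG, smIgM=_NEG, CD38=2.5, TdT=_NEG, cyCD79a=_NEG,
                  IgD=_NEG, cyIgM=_NEG, CD19=_NEG, CD34=_NEG, CD10=_NEG),
    "pro-B": dict(CD20=_NEG, smIgM=_NEG, CD38=4.2, TdT=_POS, cyCD79a=4.5,
                  IgD=_NEG, cyIgM=_NEG, CD19=_NEG, CD34=_POS, CD10=4.5),
    "pre-BI": dict(CD20=1.0, smIgM=_NEG, CD38=4.2, TdT=_POS, cyCD79a=4.5,
                   IgD=_NEG, cyIgM=_NEG, CD19=_POS, CD34=_POS, CD10=4.5),
    "pre-BII": dict(CD20=1.8, smIgM=_NEG, CD38=4.2, TdT=_POS, cyCD79a=4.5,
                    IgD=_NEG, cyIgM=_POS, CD19=_POS, CD34=_POS, CD10=4.2),
    "immature": dict(CD20=3.0, smIgM=_POS, CD38=4.0, TdT=_NEG, cyCD79a=4.5,
                     IgD=_NEG, cyIgM=_POS, CD19=_POS, CD34=_NEG, CD10=3.5),
    "mature": dict(CD20=4.5, smIgM=_POS, CD38=1.5, TdT=_NEG, cyCD79a=4.5,
                   IgD=4.5, cyIgM=4.5, CD19=_POS, CD34=_NEG, CD10=_NEG),
}

_MARKER_SD = {m: 0.10 for m in MARKERS}

# Positivity level separating the CD34/TdT plateaus; the midpoint of the
# S-ramp, where the marginal density of the channel is lowest.
SUBDIVISION_CUTOFF = 2.6

# Signed pseudotime drift amplitudes per stage (transformed units).  CD34 and
# TdT within the pre-B stages are governed by the descent ramps instead.
_DRIFT_PSEUDOTIME: dict[str, dict[str, float]] = {
    "non-B": dict(CD20=0.2, smIgM=0.2, CD38=0.3, TdT=0.1, cyCD79a=0.1,
                  IgD=0.2, cyIgM=0.1, CD19=0.1, CD34=0.1, CD10=0.1),
    "pro-B": dict(CD20=0.25, smIgM=0.2, CD38=0.3, TdT=0.3, cyCD79a=0.3,
                  IgD=0.2, cyIgM=0.3, CD19=0.25, CD34=0.3, CD10=0.3),
    "pre-BI": dict(CD20=0.8, smIgM=0.3, CD38=-0.25, TdT=0.0, cyCD79a=0.3,
                   IgD=0.2, cyIgM=0.4, CD19=0.3, CD34=0.0, CD10=-0.6),
    "pre-BII": dict(CD20=1.0, smIgM=0.3, CD38=-0.25, TdT=0.0, cyCD79a=0.3,
                    IgD=0.2, cyIgM=0.5, CD19=0.3, CD34=0.0, CD10=-0.6),
    "immature": dict(CD20=0.8, smIgM=0.5, CD38=-0.3, TdT=-0.1, cyCD79a=0.3,
                     IgD=0.3, cyIgM=0.4, CD19=0.3, CD34=-0.1, CD10=-0.6),
    "mature": dict(CD20=0.3, smIgM=0.4, CD38=-0.3, TdT=-0.1, cyCD79a=0.3,
                   IgD=0.4, cyIgM=0.3, CD19=0.3, CD34=-0.1, CD10=-0.2),
}

# Cell size/activation factor: one loading pattern for all B-lineage stages.
_DRIFT_SIZE: dict[str, float] = dict(
    CD20=0.20, smIgM=0.20, CD38=0.60, TdT=0.20, cyCD79a=0.55,
    IgD=0.25, cyIgM=0.20, CD19=0.35, CD34=0.20, CD10=0.25,
)

# Pseudotime windows (start, end) over which CD34/TdT descend in each pre-B
# stage of the healthy profile; patients move these windows (e.g. RAG
# deficiency: CD34 is lost early while TdT persists).
_HEALTHY_DESCENTS = {
    "pre-BI": {"CD34": (0.05, 0.20), "TdT": (0.28, 0.43)},
    "pre-BII": {"CD34": (-0.40, -0.25), "TdT": (-0.12, 0.03)},
}


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _descent_level(u: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    a, b = window
    return _POS - (_POS - _NEG) * _smoothstep((u - a) / (b - a))


@dataclass(frozen=True)
class DonorProfile:
    """Mixture structure of one donor's bone-marrow sample.

    ``stage_weights`` are fractions of all acquired events (including the
    cyCD79a- non-B contaminants); ``descents`` places each pre-B stage's
    CD34/TdT downregulation window in pseudotime (which implies the +/+,
    intermediate, and -/- subdivision proportions); ``transitioning_fraction``
    is the fraction of BCP events drawn along the pre-BI -> pre-BII centroid
    segment; ``donor_shift_scale`` scales per-donor marker shifts in units of
    the within-population SD.
    """

    name: str
    stage_weights: dict[str, float]
    descents: dict[str, dict[str, tuple[float, float]]]
    transitioning_fraction: float = 0.02
    donor_shift_scale: float = 0.3
    drift_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    marker_sd: dict[str, float] = field(default_factory=lambda: dict(_MARKER_SD))

    def __post_init__(self) -> None:
        total = sum(self.stage_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"stage weights must sum to 1 (got {total})")
        for stage, windows in self.descents.items():
            for marker, (a, b) in windows.items():
                if not b > a:
                    raise ValueError(f"{stage}/{marker}: descent window must have end > start")

    def bcp_weight(self) -> float:
        return sum(self.stage_weights[s] for s in ("pro-B", "pre-BI", "pre-BII", "immature"))


def healthy_profile() -> DonorProfile:
    # 20% non-B contaminants; mature B 10% of the B lineage; BCP composition
    # pro-B 5 / pre-BI 30 / pre-BII 40 / immature 25 (% of BCP).
    b = 0.80
    bcp = b * 0.90
    return DonorProfile(
        name="healthy",
        stage_weights={
            "non-B": 0.20,
            "pro-B": bcp * 0.05,
            "pre-BI": bcp * 0.30,
            "pre-BII": bcp * 0.40,
            "immature": bcp * 0.25,
            "mature": b * 0.10,
        },
        descents={stage: dict(win) for stage, win in _HEALTHY_DESCENTS.items()},
    )


def rag_deficient_profile() -> DonorProfile:
    # No IGH rearrangement: development arrests before cyIgM expression, so
    # every cyIgM+ stage (pre-BII, immature, mature) has zero weight.  CD34 is
    # nevertheless lost early in pseudotime while TdT persists.
    bcp = 0.80
    return DonorProfile(
        name="rag_deficient",
        stage_weights={
            "non-B": 0.20,
            "pro-B": bcp * 0.35,
            "pre-BI": bcp * 0.65,
            "pre-BII": 0.0,
            "immature": 0.0,
            "mature": 0.0,
        },
        descents={
            "pre-BI": {"CD34": (-0.20, -0.05), "TdT": (0.70, 0.85)},
            "pre-BII": dict(_HEALTHY_DESCENTS["pre-BII"]),
        },
        drift_overrides={"pre-BI": {"CD20": 1.4, "CD10": -0.9}},
        transitioning_fraction=0.0,
    )


def btk_deficient_profile() -> DonorProfile:
    # Pre-BCR signalling defect: a small but nonzero pre-BII fraction and
    # essentially no immature/mature output.
    bcp = 0.80
    return DonorProfile(
        name="btk_deficient",
        stage_weights={
            "non-B": 0.20,
            "pro-B": bcp * 0.25,
            "pre-BI": bcp * 0.69,
            "pre-BII": bcp * 0.06,
            "immature": 0.0,
            "mature": 0.0,
        },
        descents={
            "pre-BI": {"CD34": (0.00, 0.15), "TdT": (0.25, 0.40)},
            "pre-BII": {"CD34": (-0.30, -0.15), "TdT": (0.00, 0.15)},
        },
        drift_overrides={"pre-BI": {"CD20": 1.2, "CD10": -0.8}},
        transitioning_fraction=0.01,
    )


_PROFILES = {
    "healthy": healthy_profile,
    "rag_deficient": rag_deficient_profile,
    "btk_deficient": btk_deficient_profile,
}


def get_profile(name: str) -> DonorProfile:
    try:
        return _PROFILES[name]()
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; expected one of {sorted(_PROFILES)}") from None


def _latent_disk(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample the (pseudotime, size) latent pair uniformly on the unit disk.

    A radially bounded joint keeps every linear projection of a population
    free of corner mass, so elliptical 2SD contours cover it cleanly.
    """
    r = np.sqrt(rng.uniform(0.0, 1.0, size=(n, 1)))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n, 1))
    return r * np.cos(theta), r * np.sin(theta)


def _drift_vectors(stage: str) -> tuple[np.ndarray, np.ndarray]:
    d1 = np.array([_DRIFT_PSEUDOTIME[stage][m] for m in MARKERS])
    d2 = np.array([_DRIFT_SIZE[m] for m in MARKERS])
    return d1, d2


def effective_marker_sd(stage: str = "pre-BI") -> np.ndarray:
    """Within-population SD per marker (latent cell-state + Gaussian noise)."""
    noise = np.array([_MARKER_SD[m] for m in MARKERS])
    d1, d2 = _drift_vectors(stage)
    return np.sqrt(d1**2 / 4.0 + d2**2 / 4.0 + noise**2)


def _stage_means(profile: DonorProfile, stage: str, u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Deterministic (noise-free) marker means for cells of one stage."""
    tpl = np.array([_TEMPLATES[stage][m] for m in MARKERS])
    d1, d2 = _drift_vectors(stage)
    for marker, amp in profile.drift_overrides.get(stage, {}).items():
        d1 = d1.copy()
        d1[MARKERS.index(marker)] = amp
    means = tpl + u * d1 + w * d2
    for marker, window in profile.descents.get(stage, {}).items():
        idx = MARKERS.index(marker)
        means[:, idx] = _descent_level(u[:, 0], window) + w[:, 0] * _DRIFT_SIZE[marker]
    return means


def _stage_centroid(profile: DonorProfile, stage: str, grid: int = 201) -> np.ndarray:
    """Latent-averaged stage centroid on the transformed scale."""
    u = np.linspace(-0.999, 0.999, grid)[:, None]
    dens = 2.0 / np.pi * np.sqrt(1.0 - u[:, 0] ** 2)  # pseudotime marginal on the disk
    dens = dens / dens.sum()
    means = _stage_means(profile, stage, u, np.zeros_like(u))
    return dens @ means


def simulate_bm_sample(
    profile: DonorProfile | str,
    n_cells: int,
    donor_id: str = "donor",
    seed: int | np.random.SeedSequence = 0,
    cofactor: float = 150.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one donor's event table.

    Returns ``(events, truth)``: ``events`` holds raw-scale intensities
    (the inverse of the arcsinh transform used for gating) for the ten
    panel markers; ``truth`` holds the generator's per-cell stage and
    CD34/TdT subdivision labels.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)

    # Per-donor variation is a bounded multiplicative staining/instrument
    # gain (raw-scale scaling, i.e. a constant offset on the arcsinh scale
    # for bright channels and almost none for negative ones, amounting to
    # ``donor_shift_scale`` within-population SDs at full gain) plus a small
    # independent per-channel residual.  EuroFlow-style instrument
    # standardization keeps real inter-donor offsets of this correlated,
    # bounded kind.
    eff_sd = effective_marker_sd()
    log_gain = profile.donor_shift_scale * 0.25 * rng.triangular(-1.0, 0.0, 1.0)
    shift = rng.normal(0.0, 0.03 * eff_sd)

    stages = list(profile.stage_weights)
    weights = np.array([profile.stage_weights[s] for s in stages], dtype=float)
    bcp = profile.bcp_weight()
    # Transitioning cells replace a fraction of the canonical BCP mass.
    cats = stages + ["transitioning"]
    trans_w = profile.transitioning_fraction * bcp
    w = np.array(
        [weights[i] * (1 - profile.transitioning_fraction)
         if stages[i] in ("pro-B", "pre-BI", "pre-BII", "immature") else weights[i]
         for i in range(len(stages))] + [trans_w]
    )
    w /= w.sum()
    draw = rng.choice(len(cats), size=n_cells, p=w)

    pre_bi_c = _stage_centroid(profile, "pre-BI")
    pre_bii_c = _stage_centroid(profile, "pre-BII")

    means = np.empty((n_cells, len(MARKERS)))
    true_stage = np.empty(n_cells, dtype=object)
    true_sub = np.full(n_cells, "not-applicable", dtype=object)
    noise_sd = np.array([_MARKER_SD[m] for m in MARKERS])
    cd34_idx, tdt_idx = MARKERS.index("CD34"), MARKERS.index("TdT")

    for ci, cat in enumerate(cats):
        mask = draw == ci
        n_cat = int(mask.sum())
        if n_cat == 0:
            continue
        if cat == "transitioning":
            t = rng.uniform(0.15, 0.85, size=n_cat)[:, None]
            means[mask] = (1 - t) * pre_bi_c + t * pre_bii_c
            _, w2 = _latent_disk(rng, n_cat)
            means[mask] += w2 * np.array([_DRIFT_SIZE[m] for m in MARKERS])
            true_stage[mask] = "transitioning"
            continue
        true_stage[mask] = cat
        u, w2 = _latent_disk(rng, n_cat)
        m_cat = _stage_means(profile, cat, u, w2)
        means[mask] = m_cat
        if cat in profile.descents:
            cd34_pos = m_cat[:, cd34_idx] > SUBDIVISION_CUTOFF
            tdt_pos = m_cat[:, tdt_idx] > SUBDIVISION_CUTOFF
            labels = np.where(cd34_pos & tdt_pos, "pp",
                              np.where(~cd34_pos & ~tdt_pos, "nn", "intermediate"))
            true_sub[mask] = labels.astype(object)

    values = rng.normal(means + shift, noise_sd)

    raw = np.sinh(values) * cofactor * np.exp(log_gain)
    events = pd.DataFrame(raw, columns=list(MARKERS))
    cell_ids = [f"{donor_id}-{i:06d}" for i in range(n_cells)]
    events.insert(0, "donor_id", donor_id)
    events.insert(0, "cell_id", cell_ids)
    truth = pd.DataFrame({"cell_id": cell_ids, "true_stage": true_stage, "true_subdivision": true_sub})
    return events, truth
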