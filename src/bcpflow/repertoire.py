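"""IGH rearrangement analysis: V/J assignment, CDR3, productivity, clones.

The assigner performs ungapped semi-global alignment (match +1, mismatch -1)
of every germline V (3'-anchored suffix region against the query start) and
J (prefix region sliding over the query) and maps the conserved anchors —
the V 2nd-CYS codon and the J-TRP codon — through the best placement.  The
CDR3 is the query substring strictly between the two anchor codons; a
rearrangement is in frame when the J-TRP codon start is a multiple of three
from the V reading-frame origin, and productive ("in_frame") when it is in
frame and stop-free through the J anchor.  Clones are collapsed on the
(V gene, J gene, CDR3 nucleotide sequence) triple, and all repertoire
statistics are computed over collapsed clones, not reads.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import CYS_CODONS, STOP_CODONS, TRP_CODON, GermlineDB

__all__ = [
    "VJAssignment",
    "RearrangementRecord",
    "Clone",
    "CloneSet",
    "assign_vj",
    "assign_vj_many",
    "extract_junction",
    "classify_productivity",
    "analyze_reads",
    "collapse_clones",
    "repertoire_stats",
    "read_fasta",
    "POSITIVE_RESIDUES",
]

MIN_QUERY_LENGTH = 60
DEFAULT_MIN_SCORE = 20
_MIN_OVERLAP = 12
# V placements may start at most this far into the query (tolerates a few
# untrimmed bases 5' of the amplified V region).
_MAX_V_START = 12

POSITIVE_RESIDUES = frozenset("RKH")  # arginine, lysine, histidine

_ENC = np.zeros(256, dtype=np.uint8)
for i, b in enumerate(b"ACGT", start=1):
    _ENC[b] = i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class VJAssignment:
    query_id: str
    v_name: str
    v_score: int
    v_start: int  # germline V start in query coordinates (may be negative)
    j_name: str
    j_score: int
    j_start: int  # germline J start in query coordinates
    cys_start: int  # V 2nd-CYS codon start in query coordinates
    trp_start: int  # J-TRP codon start in query coordinates
    frame_origin: int  # V codon-1 position in query coordinates


@dataclass
class RearrangementRecord:
    query_id: str
    sequence: str
    assignment: VJAssignment | None
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    frame: str | None = None  # "in-frame" | "out-of-frame"
    stop: bool | None = None
    productivity: str | None = None
    flag: str = "ok"  # ok | unassigned | junction-unresolved


def _best_placements(
    queries: np.ndarray,
    lens: np.ndarray,
    germline: np.ndarray,
    shifts: range,
) -> tuple[np.ndarray, np.ndarray]:
    """Best ungapped score and shift of one germline against padded queries."""
    n, lmax = queries.shape
    lg = len(germline)
    best_score = np.full(n, -(10 ** 9), dtype=np.int64)
    best_shift = np.zeros(n, dtype=np.int64)
    for s in shifts:
        a = max(0, s)
        b = min(lmax, s + lg)
        if b - a < _MIN_OVERLAP:
            continue
        eq = queries[:, a:b] == germline[a - s : b - s]
        matches = eq.sum(axis=1)
        overlap = np.clip(np.minimum(lens, s + lg) - a, 0, None)
        score = 2 * matches - overlap
        score[overlap < _MIN_OVERLAP] = -(10 ** 9)
        better = score > best_score
        best_score[better] = score[better]
        best_shift[better] = s
    return best_score, best_shift


def assign_vj_many(
    reads: list[tuple[str, str]],
    db: GermlineDB,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[VJAssignment | None]:
    """Vectorised V/J assignment for a batch of reads.

    Returns one :class:`VJAssignment` per read, or None when the read is
    shorter than 60 nt, no V or J germline reaches ``min_score``, or the J
    placement does not follow the V placement.  Score ties are broken by
    database order.
    """
    n = len(reads)
    if n == 0:
        return []
    lens = np.array([len(seq) for _, seq in reads], dtype=np.int64)
    lmax = int(lens.max())
    queries = np.zeros((n, lmax), dtype=np.uint8)
    for i, (_, seq) in enumerate(reads):
        queries[i, : lens[i]] = _encode(seq)

    v_score = np.full(n, -(10 ** 9), dtype=np.int64)
    v_shift = np.zeros(n, dtype=np.int64)
    v_idx = np.zeros(n, dtype=np.int64)
    for gi, v in enumerate(db.v_segments):
        g = _encode(v.seq)
        shifts = range(-(len(g) - _MIN_OVERLAP), _MAX_V_START + 1)
        score, shift = _best_placements(queries, lens, g, shifts)
        better = score > v_score  # strict: earlier DB entries win ties
        v_score[better] = score[better]
        v_shift[better] = shift[better]
        v_idx[better] = gi

    j_score = np.full(n, -(10 ** 9), dtype=np.int64)
    j_shift = np.zeros(n, dtype=np.int64)
    j_idx = np.zeros(n, dtype=np.int64)
    for gi, j in enumerate(db.j_segments):
        g = _encode(j.seq)
        shifts = range(0, lmax - _MIN_OVERLAP + 1)
        score, shift = _best_placements(queries, lens, g, shifts)
        better = score > j_score
        j_score[better] = score[better]
        j_shift[better] = shift[better]
        j_idx[better] = gi

    out: list[VJAssignment | None] = []
    for i, (read_id, seq) in enumerate(reads):
        if lens[i] < MIN_QUERY_LENGTH or v_score[i] < min_score or j_score[i] < min_score:
            out.append(None)
            continue
        v = db.v_segments[int(v_idx[i])]
        j = db.j_segments[int(j_idx[i])]
        cys = int(v_shift[i]) + v.cys_start
        trp = int(j_shift[i]) + j.trp_start
        if trp < cys + 3:  # V alignment must precede J alignment
            out.append(None)
            continue
        out.append(
            VJAssignment(
                query_id=read_id,
                v_name=v.name,
                v_score=int(v_score[i]),
                v_start=int(v_shift[i]),
                j_name=j.name,
                j_score=int(j_score[i]),
                j_start=int(j_shift[i]),
                cys_start=cys,
                trp_start=trp,
                frame_origin=int(v_shift[i]) + v.frame_offset,
            )
        )
    return out


def assign_vj(
    sequence: str,
    db: GermlineDB,
    min_score: int = DEFAULT_MIN_SCORE,
    query_id: str = "query",
) -> VJAssignment | None:
    """Assign the best V and J germline to a single sequence (None = unassigned)."""
    return assign_vj_many([(query_id, sequence)], db, min_score=min_score)[0]


def extract_junction(record: RearrangementRecord) -> RearrangementRecord:
    """Extract the CDR3 (strictly between the Cys and Trp anchor codons).

    The anchor codons themselves are excluded from the CDR3.  When either
    anchor falls outside the query or its codon content does not match the
    conserved residue (anchor lost to trimming), the record is flagged
    ``junction-unresolved``.
    """
    asg = record.assignment
    if asg is None:
        record.flag = "unassigned"
        return record
    seq = record.sequence
    cys, trp = asg.cys_start, asg.trp_start
    if cys < 0 or trp + 3 > len(seq):
        record.flag = "junction-unresolved"
        return record
    if seq[cys : cys + 3] not in CYS_CODONS or seq[trp : trp + 3] != TRP_CODON:
        record.flag = "junction-unresolved"
        return record
    record.cdr3_nt = seq[cys + 3 : trp]
    return record


def classify_productivity(record: RearrangementRecord) -> RearrangementRecord:
    """Classify frame and stop status from the assigned reading frame.

    In frame means the J-TRP codon start is congruent to the V codon-1
    position modulo 3; a stop anywhere in the translation from the V frame
    origin through the J anchor makes an in-frame rearrangement
    ``unproductive_stop``.
    """
    if record.flag != "ok" or record.assignment is None:
        return record
    asg = record.assignment
    seq = record.sequence
    origin = asg.frame_origin
    while origin < 0:
        origin += 3
    in_frame = (asg.trp_start - origin) % 3 == 0
    stop = False
    pos = origin
    while pos <= asg.trp_start and pos + 3 <= len(seq):
        if seq[pos : pos + 3] in STOP_CODONS:
            stop = True
            break
        pos += 3
    record.frame = "in-frame" if in_frame else "out-of-frame"
    record.stop = stop
    if in_frame and not stop:
        record.productivity = "in_frame"
        if record.cdr3_nt is not None and len(record.cdr3_nt) % 3 == 0:
            record.cdr3_aa = str(Seq(record.cdr3_nt).translate())
    elif not in_frame:
        record.productivity = "unproductive_out_of_frame"
    else:
        record.productivity = "unproductive_stop"
    return record


def analyze_reads(
    reads: list[tuple[str, str]],
    db: GermlineDB,
    min_score: int = DEFAULT_MIN_SCORE,
) -> tuple[list[RearrangementRecord], dict[str, int]]:
    """Run assignment, junction extraction, and productivity on a batch.

    Returns the records plus a QC tally of unassigned and junction-unresolved
    reads (which are excluded from downstream statistics).
    """
    assignments = assign_vj_many(reads, db, min_score=min_score)
    records = []
    qc = {"n_reads": len(reads), "unassigned": 0, "junction_unresolved": 0}
    for (read_id, seq), asg in zip(reads, assignments):
        rec = RearrangementRecord(query_id=read_id, sequence=seq, assignment=asg)
        if asg is None:
            rec.flag = "unassigned"
            qc["unassigned"] += 1
            records.append(rec)
            continue
        extract_junction(rec)
        if rec.flag != "ok":
            qc["junction_unresolved"] += 1
            records.append(rec)
            continue
        classify_productivity(rec)
        records.append(rec)
    return records, qc


@dataclass
class Clone:
    v_name: str
    j_name: str
    cdr3_nt: str
    representative: RearrangementRecord
    multiplicity: int = 1

    @property
    def productivity(self) -> str:
        return self.representative.productivity

    @property
    def cdr3_aa(self) -> str | None:
        return self.representative.cdr3_aa


@dataclass
class CloneSet:
    clones: "OrderedDict[tuple[str, str, str], Clone]" = field(default_factory=OrderedDict)

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones.values())


def collapse_clones(records: list[RearrangementRecord]) -> CloneSet:
    """Collapse reads to clones keyed by (V gene, J gene, CDR3 nucleotides).

    The first-seen read of each clone is kept as representative; flagged
    (unassigned / junction-unresolved) records are skipped.  Idempotent:
    collapsing the representatives of a clone set reproduces it.
    """
    out = CloneSet()
    for rec in records:
        if rec.flag != "ok" or rec.assignment is None or rec.cdr3_nt is None:
            continue
        key = (rec.assignment.v_name, rec.assignment.j_name, rec.cdr3_nt)
        clone = out.clones.get(key)
        if clone is None:
            out.clones[key] = Clone(
                v_name=key[0], j_name=key[1], cdr3_nt=key[2], representative=rec
            )
        else:
            clone.multiplicity += 1
    return out


def positive_charge_count(cdr3_aa: str) -> int:
    return sum(1 for a in cdr3_aa if a in POSITIVE_RESIDUES)


def _charge_class(count: int) -> str:
    return ">=3" if count >= 3 else str(count)


def repertoire_stats(clone_sets: dict[str, CloneSet]) -> pd.DataFrame:
    """Per-compartment clone-level productivity and CDR3 statistics.

    Returns one row per compartment with the clone count, in-frame clone
    fraction, in-frame:unproductive ratio, mean/median CDR3 amino-acid
    length (in-frame clones only), and the proportions of CDR3s carrying
    0 / 1 / 2 / >=3 positively charged residues (R, K, H).
    """
    rows = []
    for compartment, clones in clone_sets.items():
        if len(clones) == 0:
            raise ValueError(f"empty clone set for compartment {compartment!r}")
        n = len(clones)
        in_frame = sum(1 for c in clones if c.productivity == "in_frame")
        unproductive = n - in_frame
        aa_lengths = [len(c.cdr3_aa) for c in clones if c.cdr3_aa is not None]
        charges = [positive_charge_count(c.cdr3_aa) for c in clones if c.cdr3_aa is not None]
        charge_props = {f"charge_{lbl}": 0.0 for lbl in ("0", "1", "2", ">=3")}
        for cnt in charges:
            charge_props[f"charge_{_charge_class(cnt)}"] += 1
        if charges:
            for key in charge_props:
                charge_props[key] /= len(charges)
        rows.append(
            {
                "compartment": compartment,
                "n_clones": n,
                "in_frame_fraction": in_frame / n,
                "in_frame_to_unproductive_ratio": (in_frame / unproductive) if unproductive else float("inf"),
                "cdr3_aa_mean_length": float(np.mean(aa_lengths)) if aa_lengths else float("nan"),
                "cdr3_aa_median_length": float(np.median(aa_lengths)) if aa_lengths else float("nan"),
                **charge_props,
            }
        )
    return pd.DataFrame(rows)


def clones_table(clone_sets: dict[str, CloneSet]) -> pd.DataFrame:
    rows = []
    for compartment, clones in clone_sets.items():
        for c in clones:
            rows.append(
                {
                    "compartment": compartment,
                    "v": c.v_name,
                    "j": c.j_name,
                    "cdr3_nt": c.cdr3_nt,
                    "cdr3_aa": c.cdr3_aa if c.cdr3_aa is not None else "",
                    "productivity": c.productivity,
                    "multiplicity": c.multiplicity,
                }
            )
    return pd.DataFrame(rows)


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def save_stats(stats: pd.DataFrame, path) -> None:
    payload = {"schema_version": 1, "stats": stats.to_dict(orient="records")}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
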