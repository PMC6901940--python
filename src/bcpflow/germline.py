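"""Built-in miniature IGH germline segment database.

The database holds a small set of synthetic V, D, and J segments shaped like
the amplifiable part of the human IGH locus: each V segment is an open
reading frame ending in the conserved second cysteine (2nd-CYS) followed by
a short 3' tail that junctional exonucleases may erode; each J segment
carries the conserved tryptophan (J-TRP, codon TGG) of the WGxG motif at a
known offset, preceded by a 5' region that may likewise be trimmed.  The
sequences themselves are invented, but the anchor bookkeeping (codon offsets,
reading frames) follows the IMGT numbering conventions so that junction and
frame arithmetic behave exactly as for real alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "VSegment",
    "DSegment",
    "JSegment",
    "GermlineDB",
    "make_germline_db",
    "STOP_CODONS",
    "CYS_CODONS",
    "TRP_CODON",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
CYS_CODONS = frozenset({"TGT", "TGC"})
TRP_CODON = "TGG"

# One codon per amino acid; deterministic reverse translation for segment
# construction.  Cys is TGC so every V anchor satisfies the TGT/TGC contract.
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def _nt(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


@dataclass(frozen=True)
class VSegment:
    """V gene segment; ``cys_start`` is the 0-based offset of the 2nd-CYS codon."""

    name: str
    seq: str
    cys_start: int
    frame_offset: int = 0

    @property
    def tail_len(self) -> int:
        """Number of nucleotides 3' of the Cys codon (erodible by trimming)."""
        return len(self.seq) - (self.cys_start + 3)


@dataclass(frozen=True)
class DSegment:
    name: str
    seq: str


@dataclass(frozen=True)
class JSegment:
    """J gene segment; ``trp_start`` is the 0-based offset of the J-TRP codon."""

    name: str
    seq: str
    trp_start: int


@dataclass(frozen=True)
class GermlineDB:
    v_segments: tuple[VSegment, ...]
    d_segments: tuple[DSegment, ...]
    j_segments: tuple[JSegment, ...]

    def validate(self) -> None:
        if len(self.v_segments) < 5 or len(self.d_segments) < 3 or len(self.j_segments) < 4:
            raise ValueError("germline DB needs >=5 V, >=3 D, >=4 J segments")
        for v in self.v_segments:
            _check_alphabet(v.name, v.seq)
            anchor = v.seq[v.cys_start : v.cys_start + 3]
            if anchor not in CYS_CODONS:
                raise ValueError(f"{v.name}: Cys anchor codon is {anchor!r}, expected TGT/TGC")
            if (v.cys_start - v.frame_offset) % 3 != 0:
                raise ValueError(f"{v.name}: Cys anchor not in the declared reading frame")
            for pos in range(v.frame_offset, v.cys_start + 1, 3):
                if v.seq[pos : pos + 3] in STOP_CODONS:
                    raise ValueError(f"{v.name}: stop codon upstream of the Cys anchor")
        for d in self.d_segments:
            _check_alphabet(d.name, d.seq)
        for j in self.j_segments:
            _check_alphabet(j.name, j.seq)
            anchor = j.seq[j.trp_start : j.trp_start + 3]
            if anchor != TRP_CODON:
                raise ValueError(f"{j.name}: Trp anchor codon is {anchor!r}, expected TGG")

    def v_by_name(self, name: str) -> VSegment:
        return _by_name(self.v_segments, name)

    def d_by_name(self, name: str) -> DSegment:
        return _by_name(self.d_segments, name)

    def j_by_name(self, name: str) -> JSegment:
        return _by_name(self.j_segments, name)


def _by_name(segments, name: str):
    for s in segments:
        if s.name == name:
            return s
    raise KeyError(name)


def _check_alphabet(name: str, seq: str) -> None:
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"{name}: sequence must be non-empty uppercase ACGT")


# Framework amino-acid bodies for the six V segments.  Each ends with the
# 2nd-CYS; the trailing nucleotides after the Cys codon are the erodible tail
# (the germline start of CDR3).
_V_DEFS = [
    ("IGHV1-S1", "WVRQAPGKGLEWVSAISGSGGSTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC", "GCGAGA"),
    ("IGHV2-S2", "WIRQPPGKGLEWIGYIYYSGSTNYNPSLKSRVTISVDTSKNQFSLKLSSVTAADTAVYYC", "GCGAAA"),
    ("IGHV3-S3", "WVRQAPGKGLEWVGRIKSKTDGGTTDYAAPVKGRFTISRDDSKNTLYLQMNSLKTEDTAVYYC", "GCGCGT"),
    ("IGHV4-S4", "WVRQAPGQGLEWMGWINPNSGGTNYAQKFQGRVTMTRDTSISTAYMELSRLRSDDTAVYYC", "GCTAGG"),
    ("IGHV5-S5", "WVRQMPGKGLEWMGIIYPGDSDTRYSPSFQGQVTISADKSISTAYLQWSSLKASDTAMYYC", "GCCAGA"),
    ("IGHV6-S6", "WIRQSPSRGLEWLGRTYYRSKWYNDYAVSVKSRITINPDTSKNQFSLQLNSVTPEDTAVYYC", "GCAAGG"),
]

_D_DEFS = [
    ("IGHD1-S1", "GGTATAACTGGAACGAT"),
    ("IGHD2-S2", "AGGATATTGTAGTAGTACCAGCTGC"),
    ("IGHD3-S3", "GTATTACGATTTTTGGAGTGGTTAT"),
    ("IGHD4-S4", "GACTACAGTAACTAC"),
]

# (name, 5' erodible region before J-TRP, FR4 after the TGG anchor)
_J_DEFS = [
    ("IGHJ1-S1", "GCTTTTGATATC", "GGCCAAGGGACAATGGTCACCGTCTCTTCA"),
    ("IGHJ2-S2", "TACTACGGT", "GGTCAAGGAACCCTGGTCACCGTCTCCTCA"),
    ("IGHJ3-S3", "TACTACTACATGGACGTC", "GGCCAAGGGACCACGGTCACCGTCTCCTCA"),
    ("IGHJ4-S4", "ACTACTTTGACTAC", "GGCCAGGGAACCCTGGTCACTGTCTCCTCA"),
    ("IGHJ5-S5", "AACTGGTTC", "GGCCCTGGAACCCTGGTCACCGTCTCTTCA"),
]


def make_germline_db() -> GermlineDB:
    """Return the deterministic built-in mini germline database."""
    vs = []
    for name, aa, tail in _V_DEFS:
        seq = _nt(aa) + tail
        vs.append(VSegment(name=name, seq=seq, cys_start=3 * (len(aa) - 1), frame_offset=0))
    ds = [DSegment(name=n, seq=s) for n, s in _D_DEFS]
    js = [JSegment(name=n, seq=pre + TRP_CODON + fr4, trp_start=len(pre)) for n, pre, fr4 in _J_DEFS]
    db = GermlineDB(v_segments=tuple(vs), d_segments=tuple(ds), j_segments=tuple(js))
    db.validate()
    return db
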